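"""Synthetic EOG/IMU recordings for the 16 driving-activity classes.

The real dataset is private, so this module generates labeled recordings
with the qualitative structure the downstream analysis assumes: saccadic
eye movements around turns and mirror checks, blinks, head/trunk
accelerations, and the usual nuisance components (powerline hum, baseline
drift, sparse spikes, wideband sensor noise).

Signal morphology per class is driven by a fixed event grammar
(:func:`class_events`): e.g. left-turn classes contain leftward saccade
sequences plus a lateral head-acceleration lobe, parking classes contain
repeated back-and-forth maneuver lobes whose count depends on the parking
subtype, and secondary (distracting) activities are dominated by
common-mode (vertical) EOG excursions that primary activities lack.

Channel conventions
-------------------
Horizontal events are differential: a rightward saccade raises ``eog_l``
and lowers ``eog_r`` so ``eog_h = eog_l - eog_r`` swings positive.
Vertical events (blinks, gaze up/down, bending) are common mode: both
electrodes move together so ``eog_v = -(eog_l + eog_r)/2`` carries them.
The derived channels are computed from the final electrode signals, so the
defining identities hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .jins_io import (
    ACC_RATE_HZ,
    EOG_RATE_HZ,
    LABELS,
    ActivityLabel,
    RawRecording,
    label_map,
    write_jins_csv,
)

__all__ = [
    "SyntheticConfig",
    "make_event_template",
    "synthesize_recording",
    "generate_dataset",
    "class_events",
    "allocate_counts",
]

EVENT_KINDS = ("saccade", "blink", "head_turn", "reach")

#: shortest/longest recording the generator produces by default, seconds
DEFAULT_DURATION_RANGE = (2.06, 60.26)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic dataset generator."""

    n_primary: int = 1200
    n_secondary: int = 700
    duration_range_s: tuple[float, float] = DEFAULT_DURATION_RANGE
    saccade_amplitude: float = 100.0  # arbitrary EOG units
    blink_amplitude: float = 60.0
    blink_rate: float = 0.1  # events / s
    head_motion_amplitude: float = 0.35  # g
    powerline_freq_Hz: float = 50.0
    powerline_amp: float = 2.0
    drift_amp: float = 25.0
    spike_rate: float = 0.1  # events / s
    sensor_noise_eog: float = 2.0
    sensor_noise_acc: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_primary < 0 or self.n_secondary < 0:
            raise ValueError("sample counts must be non-negative")
        lo, hi = self.duration_range_s
        if not (0 < lo <= hi):
            raise ValueError("invalid duration range")
        if self.powerline_freq_Hz not in (50.0, 60.0):
            raise ValueError("powerline frequency must be 50 or 60 Hz")

    def noiseless(self) -> "SyntheticConfig":
        """Copy with every nuisance component switched off (for separability checks)."""
        return replace(
            self,
            blink_rate=0.0,
            powerline_amp=0.0,
            drift_amp=0.0,
            spike_rate=0.0,
            sensor_noise_eog=0.0,
            sensor_noise_acc=0.0,
        )


# ---------------------------------------------------------------------------
# event primitives
# ---------------------------------------------------------------------------

def make_event_template(
    kind: str,
    amplitude: float,
    duration_s: float,
    rate_Hz: float,
    *,
    cycles: float = 1.0,
) -> np.ndarray:
    """Return a single-event waveform of ``round(duration_s * rate_Hz)`` samples.

    All templates start and end at baseline 0 and have peak magnitude exactly
    ``|amplitude|`` (templates are normalized to unit peak before scaling).

    Kinds
    -----
    ``saccade``
        Smooth sigmoidal step up followed by an exponential-like return.
    ``blink``
        Biphasic pulse: a dominant lobe with a small opposite rebound.
    ``head_turn``
        Taper-windowed sinusoid with ``cycles`` full oscillations.
    ``reach``
        Slow biphasic push/return lobe (trunk or arm motion).
    """
    if duration_s <= 0 or rate_Hz <= 0:
        raise ValueError("duration_s and rate_Hz must be positive")
    if kind not in EVENT_KINDS:
        raise ValueError(f"unknown event kind {kind!r}; expected one of {EVENT_KINDS}")
    n = int(round(duration_s * rate_Hz))
    if n < 3:
        n = 3
    t = np.linspace(0.0, 1.0, n)

    if kind == "saccade":
        t_rise = 0.3
        rise = 0.5 * (1.0 - np.cos(np.pi * np.clip(t / t_rise, 0.0, 1.0)))
        s = np.clip((t - t_rise) / (1.0 - t_rise), 0.0, 1.0)
        a = 4.0
        decay = (np.exp(-a * s) - np.exp(-a)) / (1.0 - np.exp(-a))
        wave = np.where(t < t_rise, rise, decay)
        wave[0] = 0.0
        wave[-1] = 0.0
    elif kind == "blink":
        main = np.sin(np.pi * np.clip(t / 0.7, 0.0, 1.0)) ** 3
        rebound = -0.3 * np.sin(np.pi * np.clip((t - 0.6) / 0.4, 0.0, 1.0)) ** 2
        wave = main + rebound
    elif kind == "head_turn":
        wave = np.sin(2.0 * np.pi * cycles * t) * np.sin(np.pi * t) ** 2
    else:  # reach
        wave = np.sin(2.0 * np.pi * t) * np.sin(np.pi * t)

    peak = np.max(np.abs(wave))
    if peak == 0.0:
        return np.zeros(n)
    return (amplitude / peak) * wave


# ---------------------------------------------------------------------------
# per-class event grammar
# ---------------------------------------------------------------------------

def _direction(name: str) -> float:
    if name.endswith("Left"):
        return -1.0
    if name.endswith("Right"):
        return +1.0
    return 0.0


def class_events(label: ActivityLabel, config: SyntheticConfig) -> list[dict]:
    """Fixed event grammar: which primitives, at which relative times, per class.

    Each event dict has keys ``target`` (one of h/v/accx/accy/accz),
    ``kind``, ``amp``, ``center`` (fraction of the recording), ``dur``
    (fraction of the recording duration) and optional ``cycles``.
    """
    S = config.saccade_amplitude
    H = config.head_motion_amplitude
    name = label.name
    d = _direction(name)
    ev: list[dict] = []

    def add(target, kind, amp, center, dur, cycles=1.0):
        ev.append(dict(target=target, kind=kind, amp=amp, center=center, dur=dur, cycles=cycles))

    if label.type_group == "Crossroad":
        if d != 0.0:
            add("h", "saccade", 0.5 * S * d, 0.15, 0.08)
            add("h", "saccade", 1.0 * S * d, 0.45, 0.12)
            add("h", "saccade", -0.7 * S * d, 0.75, 0.10)
            add("accx", "head_turn", d * H, 0.50, 0.40, cycles=1.0)
        else:
            add("h", "saccade", 0.6 * S, 0.30, 0.08)
            add("h", "saccade", -0.6 * S, 0.60, 0.08)
        add("accy", "reach", 0.5 * H, 0.40, 0.30)
    elif label.type_group == "Roundabout":
        # time spent circulating (and hence the number of lateral sway cycles
        # and mirror scans) grows with the exit taken: right = 1st exit,
        # straight = 2nd, left = 3rd
        cycles, sway_dur, n_scans = {
            "Right": (1.5, 0.35, 2),
            "Straight": (2.5, 0.50, 3),
            "Left": (3.5, 0.65, 4),
        }[name.split("_")[2]]
        add("accx", "head_turn", H, 0.50, sway_dur, cycles=cycles)
        for c in np.linspace(0.18, 0.62, n_scans):
            add("h", "saccade", -0.8 * S, c, 0.08)
        if d != 0.0:
            add("h", "saccade", 1.2 * S * d, 0.80, 0.12)
        add("accy", "reach", 0.4 * H, 0.15, 0.25)
    elif label.type_group == "Parking":
        # maneuver count and steering-sway rhythm depend on the parking style
        subtype = name.split("_")[2]
        n_maneuvers = {"Diagonal": 2, "Parallel": 5, "Perpendicular": 3}[subtype]
        sway_cycles = {"Diagonal": 0.5, "Parallel": 2.5, "Perpendicular": 1.0}[subtype]
        centers = np.linspace(0.2, 0.85, n_maneuvers)
        for i, c in enumerate(centers):
            sign = 1.0 if i % 2 == 0 else -1.0
            add("accy", "reach", 0.8 * H * sign, c, 0.8 / (n_maneuvers + 1))
            add("h", "saccade", 0.9 * S * d, c - 0.04, 0.07)
            add("h", "saccade", -0.4 * S * d, c + 0.04, 0.06)
        add("accx", "head_turn", 0.5 * H * d, 0.5, 0.55, cycles=sway_cycles)
        add("v", "blink", 0.8 * config.blink_amplitude, 0.1, 0.05)
    elif name == "S_Bending":
        add("v", "reach", 3.0 * S, 0.45, 0.50)
        add("accz", "reach", -1.4 * H, 0.45, 0.45)
        add("accy", "reach", 0.8 * H, 0.50, 0.40)
    elif name == "S_Drinking":
        add("v", "saccade", -2.0 * S, 0.50, 0.55)
        add("accz", "head_turn", 0.9 * H, 0.50, 0.50, cycles=0.5)
    elif name == "S_Eating":
        for c in np.linspace(0.15, 0.85, 5):
            add("v", "blink", 1.2 * S, c, 0.08)
        add("accx", "head_turn", 0.25 * H, 0.5, 0.80, cycles=8.0)
        add("accz", "head_turn", 0.25 * H, 0.5, 0.80, cycles=8.0)
    elif name == "S_Turning_Back":
        # looking back over the shoulder: large horizontal AND vertical gaze
        # shift plus a sustained trunk twist no primary maneuver produces
        add("h", "saccade", 2.2 * S, 0.40, 0.45)
        add("v", "saccade", 1.8 * S, 0.42, 0.45)
        add("accx", "reach", 1.4 * H, 0.45, 0.50)
        add("accy", "head_turn", 1.2 * H, 0.50, 0.55, cycles=1.0)
    else:  # pragma: no cover - vocabulary is closed
        raise ValueError(f"no grammar for label {name}")
    return ev


# ---------------------------------------------------------------------------
# recording synthesis
# ---------------------------------------------------------------------------

def _place(stream: np.ndarray, wave: np.ndarray, center_idx: int) -> None:
    """Add *wave* into *stream* centered at *center_idx*, clipping at edges."""
    n = len(stream)
    half = len(wave) // 2
    lo = center_idx - half
    hi = lo + len(wave)
    w_lo = max(0, -lo)
    w_hi = len(wave) - max(0, hi - n)
    if w_hi <= w_lo:
        return
    stream[max(0, lo) : max(0, lo) + (w_hi - w_lo)] += wave[w_lo:w_hi]


def synthesize_recording(
    label: Union[ActivityLabel, int, str],
    duration_s: float,
    config: Optional[SyntheticConfig] = None,
    seed: int = 0,
) -> RawRecording:
    """Generate one labeled recording, deterministic in (label, duration, config, seed)."""
    if config is None:
        config = SyntheticConfig()
    if not isinstance(label, ActivityLabel):
        label = label_map(label)
    lo, hi = config.duration_range_s
    if not (lo - 1e-9 <= duration_s <= hi + 1e-9):
        raise ValueError(f"duration {duration_s} s outside configured range [{lo}, {hi}] s")

    n_acc = int(round(duration_s * ACC_RATE_HZ))
    n_eog = 2 * n_acc
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0xFFFFFFFF, label.code]))

    eog_l = np.zeros(n_eog)
    eog_r = np.zeros(n_eog)
    acc = {"accx": np.zeros(n_acc), "accy": np.zeros(n_acc), "accz": np.zeros(n_acc)}

    def add_eog_event(target: str, wave: np.ndarray, center_idx: int) -> None:
        if target == "h":  # differential
            _place(eog_l, wave / 2.0, center_idx)
            _place(eog_r, -wave / 2.0, center_idx)
        else:  # common mode; eog_v = -(l+r)/2 so negate to make amp the v-swing
            _place(eog_l, -wave, center_idx)
            _place(eog_r, -wave, center_idx)

    for event in class_events(label, config):
        center = event["center"] + rng.uniform(-0.03, 0.03)
        amp = event["amp"] * rng.uniform(0.85, 1.15)
        dur = max(event["dur"] * duration_s, 0.05)
        if event["target"] in ("h", "v"):
            wave = make_event_template(event["kind"], amp, dur, EOG_RATE_HZ, cycles=event["cycles"])
            add_eog_event(event["target"], wave, int(center * n_eog))
        else:
            wave = make_event_template(event["kind"], amp, dur, ACC_RATE_HZ, cycles=event["cycles"])
            _place(acc[event["target"]], wave, int(center * n_acc))

    # background blinks (common-mode vertical pulses)
    n_blinks = rng.poisson(config.blink_rate * duration_s)
    for _ in range(n_blinks):
        wave = make_event_template(
            "blink", config.blink_amplitude * rng.uniform(0.8, 1.2), 0.3, EOG_RATE_HZ
        )
        add_eog_event("v", wave, int(rng.uniform(0.05, 0.95) * n_eog))

    # nuisance components on the electrode signals
    t = np.arange(n_eog) / EOG_RATE_HZ
    for electrode in (eog_l, eog_r):
        electrode += config.powerline_amp * np.sin(
            2 * np.pi * config.powerline_freq_Hz * t + rng.uniform(0, 2 * np.pi)
        )
        for _ in range(3):  # slow baseline drift
            period = rng.uniform(5.0, 30.0)
            electrode += (
                config.drift_amp
                * rng.uniform(0.3, 1.0)
                * np.sin(2 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
            )
        n_spikes = rng.poisson(config.spike_rate * duration_s)
        for idx in rng.integers(0, n_eog, size=n_spikes):
            electrode[idx] += rng.choice([-1.0, 1.0]) * rng.uniform(3.0, 6.0) * config.sensor_noise_eog * 10
        if config.sensor_noise_eog > 0:
            electrode += rng.normal(0.0, config.sensor_noise_eog, size=n_eog)

    acc["accz"] += 1.0  # gravity along the vertical axis of the glasses frame
    for key in ("accx", "accy", "accz"):
        n_spikes = rng.poisson(config.spike_rate * duration_s)
        for idx in rng.integers(0, n_acc, size=max(n_spikes, 0)):
            acc[key][idx] += rng.choice([-1.0, 1.0]) * rng.uniform(5.0, 15.0) * config.sensor_noise_acc
        if config.sensor_noise_acc > 0:
            acc[key] += rng.normal(0.0, config.sensor_noise_acc, size=n_acc)

    # +/- 2 g sensor range
    n_clipped = int(sum(np.count_nonzero(np.abs(a) > 2.0) for a in acc.values()))
    for key in acc:
        np.clip(acc[key], -2.0, 2.0, out=acc[key])

    return RawRecording(
        label=label,
        eog_l=eog_l,
        eog_r=eog_r,
        eog_h=eog_l - eog_r,
        eog_v=-(eog_l + eog_r) / 2.0,
        acc_x=acc["accx"],
        acc_y=acc["accy"],
        acc_z=acc["accz"],
        meta={"seed": int(seed), "n_clipped": n_clipped},
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def allocate_counts(total: int, n_classes: int) -> list[int]:
    """Split *total* over *n_classes*, distributing any remainder round-robin
    by ascending class position."""
    base, rem = divmod(total, n_classes)
    return [base + (1 if i < rem else 0) for i in range(n_classes)]


def generate_dataset(
    config: Optional[SyntheticConfig] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> tuple[list[RawRecording], pd.DataFrame]:
    """Generate the full labeled dataset and its manifest.

    ``config.n_primary`` recordings are spread over the 12 primary classes and
    ``config.n_secondary`` over the 4 secondary classes (remainders
    round-robin by ascending label code).  If *out_dir* is given, each
    recording is written as a JINS CSV and the manifest as ``manifest.tsv``.

    Returns the recordings and a manifest with one row per recording
    (path, label code/name, duration, per-recording seed, clipped-sample
    count).
    """
    if config is None:
        config = SyntheticConfig()
    primary = [lab for lab in LABELS if lab.is_primary]
    secondary = [lab for lab in LABELS if not lab.is_primary]
    counts = dict(zip(primary, allocate_counts(config.n_primary, len(primary))))
    counts.update(zip(secondary, allocate_counts(config.n_secondary, len(secondary))))

    master = np.random.default_rng(config.seed)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    recordings: list[RawRecording] = []
    rows = []
    lo, hi = config.duration_range_s
    for lab in LABELS:
        for k in range(counts[lab]):
            duration = float(master.uniform(lo, hi))
            rec_seed = int(master.integers(0, 2**31 - 1))
            rec = synthesize_recording(lab, duration, config, seed=rec_seed)
            path_str = ""
            if out_path is not None:
                path_str = str(out_path / f"{lab.name}_{k:04d}.csv")
                write_jins_csv(rec, path_str)
            recordings.append(rec)
            rows.append(
                dict(
                    path=path_str,
                    label_code=lab.code,
                    label_name=lab.name,
                    duration_s=round(rec.duration_s, 6),
                    seed=rec_seed,
                    n_clipped=rec.meta.get("n_clipped", 0),
                )
            )
    manifest = pd.DataFrame(
        rows, columns=["path", "label_code", "label_name", "duration_s", "seed", "n_clipped"]
    )
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.tsv", sep="\t", index=False)
    return recordings, manifest
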