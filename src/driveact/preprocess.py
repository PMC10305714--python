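"""Signal cleaning, synchronization, normalization and segmentation.

The chain applied by :func:`preprocess_recording`:

* EOG channels (200 Hz): zero-phase low-pass Butterworth, then detrending by
  first differencing (removes baseline drift);
* accelerometer channels (100 Hz): median filter followed by a linear-phase
  Hamming-window FIR low-pass (removes short irregular peaks, then smooths);
* all channels decimated to a common 50 Hz rate;
* per-channel z-score normalization;
* segmentation: either the whole recording resampled to a fixed model input
  length, or fixed-length sliding windows with 50% stride.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import scipy.ndimage
import scipy.signal

from .jins_io import ACC_RATE_HZ, EOG_RATE_HZ, ActivityLabel, RawRecording

__all__ = [
    "PreprocConfig",
    "ModelInput",
    "CHANNEL_NAMES",
    "lowpass_zerophase",
    "detrend_diff",
    "acc_clean",
    "synchronize",
    "zscore",
    "sliding_windows",
    "resample_to_length",
    "preprocess_recording",
    "samples_to_seconds",
    "seconds_to_samples",
]

logger = logging.getLogger(__name__)

#: model-input channel order
CHANNEL_NAMES = ("ACCX", "ACCY", "ACCZ", "EOGL", "EOGR", "EOGH", "EOGV")


@dataclass(frozen=True)
class PreprocConfig:
    """Parameters of the preprocessing chain."""

    eog_lowpass_cutoff_Hz: float = 20.0
    butterworth_order: int = 2
    acc_median_kernel: int = 5
    acc_lowpass_cutoff_Hz: float = 20.0
    fir_length: int = 31
    sync_rate_Hz: float = 50.0
    window_s: float = 5.6
    stride_s: float = 2.8
    model_input_len: int = 3000
    segmentation_mode: str = "whole_resampled"
    highpass_corner_Hz: Optional[float] = None  # optional DC-removal corner instead of differencing

    def __post_init__(self) -> None:
        if self.acc_median_kernel % 2 == 0:
            raise ValueError("median kernel must be odd")
        if self.window_len_samples != 2 * self.stride_samples:
            raise ValueError("window length must equal twice the stride (50% overlap)")
        if self.segmentation_mode not in ("whole_resampled", "windows"):
            raise ValueError(f"unknown segmentation mode {self.segmentation_mode!r}")
        if not 0 < self.eog_lowpass_cutoff_Hz < EOG_RATE_HZ / 2:
            raise ValueError("EOG cutoff must lie in (0, Nyquist)")
        if not 0 < self.acc_lowpass_cutoff_Hz < ACC_RATE_HZ / 2:
            raise ValueError("ACC cutoff must lie in (0, Nyquist)")

    @property
    def window_len_samples(self) -> int:
        """Sliding-window length in samples at the synchronized rate (5.6 s -> 280)."""
        return seconds_to_samples(self.window_s, self.sync_rate_Hz)

    @property
    def stride_samples(self) -> int:
        return seconds_to_samples(self.stride_s, self.sync_rate_Hz)


@dataclass
class ModelInput:
    """Fixed-length normalized multichannel array ready for the network."""

    values: np.ndarray  # (length, n_channels) float
    label: ActivityLabel
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("ModelInput values must be 2-D (length x channels)")


def seconds_to_samples(seconds: float, rate_Hz: float) -> int:
    """Duration -> sample count at *rate_Hz* (5.6 s at 50 Hz -> 280)."""
    return int(round(seconds * rate_Hz))


def samples_to_seconds(n_samples: int, rate_Hz: float) -> float:
    """Sample count -> duration at *rate_Hz* (3013 at 50 Hz -> 60.26 s)."""
    return n_samples / rate_Hz


# ---------------------------------------------------------------------------
# per-channel stages
# ---------------------------------------------------------------------------

def lowpass_zerophase(
    x: np.ndarray, cutoff_Hz: float, rate_Hz: float, order: int = 2
) -> np.ndarray:
    """Zero-phase low-pass: an order-*order* Butterworth applied forward and
    backward, so the net phase is zero and the effective magnitude response is
    the squared single-pass response."""
    x = np.asarray(x, dtype=np.float64)
    if cutoff_Hz >= rate_Hz / 2:
        raise ValueError(f"cutoff {cutoff_Hz} Hz must be below Nyquist ({rate_Hz / 2} Hz)")
    if len(x) <= 3 * order:
        raise ValueError(f"series too short for order-{order} zero-phase filtering: {len(x)}")
    sos = scipy.signal.butter(order, cutoff_Hz, btype="low", fs=rate_Hz, output="sos")
    padlen = min(len(x) - 1, 3 * (2 * order + 1))
    return scipy.signal.sosfiltfilt(sos, x, padlen=padlen)


def detrend_diff(x: np.ndarray) -> np.ndarray:
    """Detrend by first differencing; the first difference is repeated so the
    output keeps the input length.  Constant offsets vanish and linear drift
    becomes a constant."""
    x = np.asarray(x, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("need at least 2 samples to difference")
    d = np.diff(x)
    return np.concatenate(([d[0]], d))


def acc_clean(x: np.ndarray, config: Optional[PreprocConfig] = None) -> np.ndarray:
    """Accelerometer cleaning: edge-replicated median filter (suppresses short
    irregular peaks) followed by a linear-phase Hamming FIR low-pass with the
    group delay compensated (edge-padded, centered convolution)."""
    if config is None:
        config = PreprocConfig()
    x = np.asarray(x, dtype=np.float64)
    if len(x) <= config.fir_length:
        raise ValueError(f"series of length {len(x)} too short for FIR length {config.fir_length}")
    med = scipy.ndimage.median_filter(x, size=config.acc_median_kernel, mode="nearest")
    taps = scipy.signal.firwin(
        config.fir_length, config.acc_lowpass_cutoff_Hz, fs=ACC_RATE_HZ, window="hamming"
    )
    pad = config.fir_length // 2
    padded = np.concatenate((np.full(pad, med[0]), med, np.full(pad, med[-1])))
    return np.convolve(padded, taps, mode="same")[pad:-pad]


def median_stage(x: np.ndarray, kernel: int) -> np.ndarray:
    """The median-filter stage of :func:`acc_clean` alone (edge-replicated)."""
    return scipy.ndimage.median_filter(np.asarray(x, dtype=np.float64), size=kernel, mode="nearest")


def zscore(x: np.ndarray) -> np.ndarray:
    """Z-score with the population standard deviation: ``(x - mean) / sd``.

    A constant series has sd 0; it is mapped to all zeros and a warning is
    logged rather than raising.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot z-score an empty series")
    mu = x.mean()
    sigma = x.std()
    if sigma == 0.0:
        logger.warning("z-score of a constant series: returning zeros")
        return np.zeros_like(x)
    return (x - mu) / sigma


# ---------------------------------------------------------------------------
# synchronization and segmentation
# ---------------------------------------------------------------------------

def _decimate(x: np.ndarray, factor: int, rate_Hz: float, antialias: bool) -> np.ndarray:
    if factor == 1:
        return np.asarray(x, dtype=np.float64)
    if antialias:
        x = lowpass_zerophase(x, 0.45 * rate_Hz / factor, rate_Hz)
    return np.asarray(x, dtype=np.float64)[::factor]


def synchronize(
    recording: RawRecording, sync_rate_Hz: float = 50.0, antialias: bool = True
) -> np.ndarray:
    """Decimate all channels to the common *sync_rate_Hz* and stack them as a
    (n_samples, 7) array in :data:`CHANNEL_NAMES` order.

    Native rates must be integer multiples of the sync rate (EOG 200 -> 50 is
    factor 4, ACC 100 -> 50 is factor 2).  When *antialias* is set, a
    zero-phase low-pass at 0.45x the target Nyquist precedes subsampling.
    """
    for native in (EOG_RATE_HZ, ACC_RATE_HZ):
        if abs(native / sync_rate_Hz - round(native / sync_rate_Hz)) > 1e-9:
            raise ValueError(f"native rate {native} Hz is not an integer multiple of {sync_rate_Hz} Hz")
    f_eog = int(round(EOG_RATE_HZ / sync_rate_Hz))
    f_acc = int(round(ACC_RATE_HZ / sync_rate_Hz))
    channels = [
        _decimate(recording.acc_x, f_acc, ACC_RATE_HZ, antialias),
        _decimate(recording.acc_y, f_acc, ACC_RATE_HZ, antialias),
        _decimate(recording.acc_z, f_acc, ACC_RATE_HZ, antialias),
        _decimate(recording.eog_l, f_eog, EOG_RATE_HZ, antialias),
        _decimate(recording.eog_r, f_eog, EOG_RATE_HZ, antialias),
        _decimate(recording.eog_h, f_eog, EOG_RATE_HZ, antialias),
        _decimate(recording.eog_v, f_eog, EOG_RATE_HZ, antialias),
    ]
    n = min(len(c) for c in channels)
    return np.stack([c[:n] for c in channels], axis=1)


def sliding_windows(x: np.ndarray, window_len: int = 280, stride: int = 140) -> list[np.ndarray]:
    """Fixed-length windows with the stated truncation rule: the series is
    first truncated (from the end) to the largest multiple of *stride*, then
    windows start at 0, stride, 2*stride, ... while ``start + window_len``
    fits.  Short inputs yield zero windows."""
    if window_len <= 0 or stride <= 0:
        raise ValueError("window length and stride must be positive")
    x = np.asarray(x)
    n = (len(x) // stride) * stride
    out = []
    start = 0
    while start + window_len <= n:
        out.append(x[start : start + window_len])
        start += stride
    return out


def resample_to_length(x: np.ndarray, length: int = 3000) -> np.ndarray:
    """Resample each channel to exactly *length* samples by linear
    interpolation; first/last samples are preserved and monotone inputs stay
    monotone."""
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to resample")
    old_t = np.linspace(0.0, 1.0, n)
    new_t = np.linspace(0.0, 1.0, length)
    out = np.empty((length, x.shape[1]))
    for c in range(x.shape[1]):
        out[:, c] = np.interp(new_t, old_t, x[:, c])
    return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"preprocessing stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def preprocess_recording(
    recording: RawRecording,
    config: Optional[PreprocConfig] = None,
    source_id: str = "",
) -> Union[ModelInput, list[ModelInput]]:
    """Run the full chain on one recording.

    Returns one :class:`ModelInput` of shape ``(model_input_len, 7)`` in
    ``whole_resampled`` mode, or a list of window-sized inputs in ``windows``
    mode.  Each emitted input is re-normalized so its per-channel mean is 0
    and population sd 1 (constant channels become all-zero).
    """
    if config is None:
        config = PreprocConfig()

    with _stage("eog_filter"):
        eog = {}
        for name in ("eog_l", "eog_r", "eog_h", "eog_v"):
            y = lowpass_zerophase(
                getattr(recording, name),
                config.eog_lowpass_cutoff_Hz,
                EOG_RATE_HZ,
                config.butterworth_order,
            )
            if config.highpass_corner_Hz is not None:
                sos = scipy.signal.butter(
                    config.butterworth_order,
                    config.highpass_corner_Hz,
                    btype="high",
                    fs=EOG_RATE_HZ,
                    output="sos",
                )
                eog[name] = scipy.signal.sosfiltfilt(sos, y)
            else:
                eog[name] = detrend_diff(y)

    with _stage("acc_clean"):
        acc = {
            name: acc_clean(getattr(recording, name), config)
            for name in ("acc_x", "acc_y", "acc_z")
        }

    with _stage("synchronize"):
        cleaned = RawRecording(
            label=recording.label,
            eog_l=eog["eog_l"],
            eog_r=eog["eog_r"],
            eog_h=eog["eog_h"],
            eog_v=eog["eog_v"],
            acc_x=acc["acc_x"],
            acc_y=acc["acc_y"],
            acc_z=acc["acc_z"],
            start_time=recording.start_time,
        )
        # EOG channels were already low-passed well below the target Nyquist,
        # so no extra anti-alias pass is needed before subsampling.
        synced = synchronize(cleaned, config.sync_rate_Hz, antialias=False)

    with _stage("normalize"):
        normed = np.stack([zscore(synced[:, c]) for c in range(synced.shape[1])], axis=1)

    def _final(arr: np.ndarray) -> np.ndarray:
        return np.stack([zscore(arr[:, c]) for c in range(arr.shape[1])], axis=1)

    if config.segmentation_mode == "whole_resampled":
        with _stage("resample"):
            out = resample_to_length(normed, config.model_input_len)
        return ModelInput(values=_final(out), label=recording.label, source_id=source_id)
    with _stage("windows"):
        wins = sliding_windows(normed, config.window_len_samples, config.stride_samples)
    return [
        ModelInput(values=_final(w), label=recording.label, source_id=f"{source_id}[{i}]")
        for i, w in enumerate(wins)
    ]
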