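"""Reader/writer for the JINS MEME ES_R CSV dialect and the activity-label vocabulary.

The dialect is a plain comma-separated file with three parts:

1. parameter rows — ``# key=value`` lines holding acquisition parameters;
2. one header row naming the data columns in fixed order
   ``SampleNo,Date,ACCX,ACCY,ACCZ,EOGL,EOGR,EOGH,EOGV`` (optionally followed
   by ``GYROX,GYROY,GYROZ``, which this pipeline ignores);
3. data rows, one per EOG sample (200 Hz native).  The accelerometer runs at
   100 Hz, so ACC cells are populated on every second row and left empty
   otherwise, as the device does.

Dates use the format ``dd.mm.rrrr:hh:mm:ss`` where ``rrrr`` is the 4-digit
year.
"""

from __future__ import annotations

import csv
import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "ActivityLabel",
    "RawRecording",
    "JinsFileDialect",
    "LABELS",
    "label_map",
    "read_jins_csv",
    "write_jins_csv",
    "JinsFormatError",
    "EOG_RATE_HZ",
    "ACC_RATE_HZ",
]

EOG_RATE_HZ = 200.0
ACC_RATE_HZ = 100.0

DATE_FORMAT = "%d.%m.%Y:%H:%M:%S"

_COLUMNS = ["SampleNo", "Date", "ACCX", "ACCY", "ACCZ", "EOGL", "EOGR", "EOGH", "EOGV"]
_GYRO_COLUMNS = ["GYROX", "GYROY", "GYROZ"]


class JinsFormatError(ValueError):
    """Raised when a file does not conform to the JINS CSV dialect."""


@dataclass(frozen=True)
class ActivityLabel:
    """One of the 16 driving-activity classes.

    Codes 0-11 are primary (maneuvering) activities, 12-15 secondary
    (distracting) activities.  ``type_group`` is the coarse 4-way grouping
    derived from the name prefix.
    """

    code: int
    name: str
    type_group: str
    is_primary: bool


def _make_labels() -> tuple[ActivityLabel, ...]:
    names = [
        "P_Crossroad_Left",
        "P_Crossroad_Right",
        "P_Crossroad_Straight",
        "P_Parking_Diagonal_Left",
        "P_Parking_Diagonal_Right",
        "P_Parking_Parallel_Left",
        "P_Parking_Parallel_Right",
        "P_Parking_Perpendicular_Left",
        "P_Parking_Perpendicular_Right",
        "P_Roundabout_Left",
        "P_Roundabout_Right",
        "P_Roundabout_Straight",
        "S_Bending",
        "S_Drinking",
        "S_Eating",
        "S_Turning_Back",
    ]
    labels = []
    for code, name in enumerate(names):
        primary = name.startswith("P_")
        group = "Secondary" if not primary else name.split("_")[1]
        labels.append(ActivityLabel(code=code, name=name, type_group=group, is_primary=primary))
    return tuple(labels)


LABELS: tuple[ActivityLabel, ...] = _make_labels()
TYPE_GROUPS = ("Crossroad", "Parking", "Roundabout", "Secondary")

_BY_CODE = {lab.code: lab for lab in LABELS}
_BY_NAME = {lab.name: lab for lab in LABELS}


def label_map(code_or_name: Union[int, str]) -> ActivityLabel:
    """Resolve an integer code (0-15) or canonical name to an :class:`ActivityLabel`.

    Raises
    ------
    KeyError
        If the code or name is not in the vocabulary.
    """
    if isinstance(code_or_name, str):
        try:
            return _BY_NAME[code_or_name]
        except KeyError:
            raise KeyError(f"unknown activity name: {code_or_name!r}") from None
    code = int(code_or_name)
    try:
        return _BY_CODE[code]
    except KeyError:
        raise KeyError(f"unknown activity code: {code} (expected 0-15)") from None


@dataclass
class RawRecording:
    """A labeled multichannel recording at native device rates.

    EOG channels are sampled at 200 Hz, accelerometer channels at 100 Hz
    (half as many samples).  The derived channels satisfy, exactly for
    synthetic data::

        eog_h = eog_l - eog_r
        eog_v = -(eog_l + eog_r) / 2
    """

    label: ActivityLabel
    eog_l: np.ndarray
    eog_r: np.ndarray
    eog_h: np.ndarray
    eog_v: np.ndarray
    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    start_time: _dt.datetime = field(default_factory=lambda: _dt.datetime(2022, 3, 1, 12, 0, 0))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("eog_l", "eog_r", "eog_h", "eog_v", "acc_x", "acc_y", "acc_z"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = self.n_eog_samples
        for name in ("eog_r", "eog_h", "eog_v"):
            if len(getattr(self, name)) != n:
                raise ValueError("all EOG channels must have equal length")
        n_acc = len(self.acc_x)
        if len(self.acc_y) != n_acc or len(self.acc_z) != n_acc:
            raise ValueError("all ACC channels must have equal length")
        expected_acc = n * ACC_RATE_HZ / EOG_RATE_HZ
        if n > 0 and n_acc != int(expected_acc):
            raise ValueError(
                f"ACC length {n_acc} inconsistent with EOG length {n} "
                f"(expected {expected_acc:g} at {ACC_RATE_HZ:g}/{EOG_RATE_HZ:g} Hz)"
            )

    @property
    def n_eog_samples(self) -> int:
        return len(self.eog_l)

    @property
    def duration_s(self) -> float:
        return self.n_eog_samples / EOG_RATE_HZ

    @property
    def sample_index(self) -> np.ndarray:
        return np.arange(self.n_eog_samples)

    @property
    def timestamps(self) -> list[str]:
        """Per-EOG-sample date strings in ``dd.mm.rrrr:hh:mm:ss`` (1 s resolution)."""
        out = []
        for i in range(self.n_eog_samples):
            t = self.start_time + _dt.timedelta(seconds=int(i / EOG_RATE_HZ))
            out.append(t.strftime(DATE_FORMAT))
        return out


@dataclass(frozen=True)
class JinsFileDialect:
    """Structural description of the CSV dialect (see module docstring)."""

    delimiter: str = ","
    param_prefix: str = "#"
    column_order: tuple[str, ...] = tuple(_COLUMNS)
    date_format: str = DATE_FORMAT


DIALECT = JinsFileDialect()

# ratio of EOG to ACC sampling rates; ACC cells appear on every k-th row
_ACC_EVERY = int(EOG_RATE_HZ / ACC_RATE_HZ)


def write_jins_csv(recording: RawRecording, path: Union[str, Path]) -> Path:
    """Write *recording* to *path* in the JINS CSV dialect.

    Parameter rows record the label and acquisition settings; they are
    prefixed with ``#`` so readers can strip them unambiguously.
    """
    path = Path(path)
    params = {
        "device": "JINS MEME ES_R",
        "eog_rate_hz": f"{EOG_RATE_HZ:g}",
        "acc_rate_hz": f"{ACC_RATE_HZ:g}",
        "acc_range_g": "2",
        "label_code": str(recording.label.code),
        "label_name": recording.label.name,
    }
    timestamps = recording.timestamps
    with path.open("w", newline="") as fh:
        for key, value in params.items():
            fh.write(f"{DIALECT.param_prefix} {key}={value}\n")
        writer = csv.writer(fh, delimiter=DIALECT.delimiter)
        writer.writerow(_COLUMNS)
        for i in range(recording.n_eog_samples):
            if i % _ACC_EVERY == 0:
                j = i // _ACC_EVERY
                acc = [
                    repr(float(recording.acc_x[j])),
                    repr(float(recording.acc_y[j])),
                    repr(float(recording.acc_z[j])),
                ]
            else:
                acc = ["", "", ""]
            writer.writerow(
                [i, timestamps[i]]
                + acc
                + [
                    repr(float(recording.eog_l[i])),
                    repr(float(recording.eog_r[i])),
                    repr(float(recording.eog_h[i])),
                    repr(float(recording.eog_v[i])),
                ]
            )
    return path


def read_jins_csv(path: Union[str, Path], identity_tol: float = 1e-6) -> RawRecording:
    """Read a JINS CSV file back into a :class:`RawRecording`.

    Parameter rows are stripped.  Deviations of the derived channels from
    their defining identities (``eog_h = eog_l - eog_r``) beyond
    *identity_tol* are reported as a :class:`UserWarning`, not an error.

    Raises
    ------
    JinsFormatError
        On missing/misordered columns or unparseable dates; the message names
        the offending row.
    """
    path = Path(path)
    params: dict[str, str] = {}
    header: list[str] | None = None
    data_rows: list[list[str]] = []
    with path.open(newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(DIALECT.param_prefix):
                body = line.lstrip(DIALECT.param_prefix).strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    params[key.strip()] = value.strip()
                continue
            cells = next(csv.reader([line], delimiter=DIALECT.delimiter))
            if header is None:
                header = [c.strip() for c in cells]
                base = header[: len(_COLUMNS)]
                extra = header[len(_COLUMNS) :]
                if base != _COLUMNS or any(c not in _GYRO_COLUMNS for c in extra):
                    raise JinsFormatError(
                        f"{path}: row {lineno}: bad header {header!r}; "
                        f"expected {_COLUMNS!r} (optionally + {_GYRO_COLUMNS!r})"
                    )
                continue
            if len(cells) < len(_COLUMNS):
                raise JinsFormatError(f"{path}: row {lineno}: expected >= {len(_COLUMNS)} cells, got {len(cells)}")
            try:
                _dt.datetime.strptime(cells[1], DATE_FORMAT)
            except ValueError:
                raise JinsFormatError(f"{path}: row {lineno}: unparseable date {cells[1]!r}") from None
            data_rows.append(cells)
    if header is None:
        raise JinsFormatError(f"{path}: no header row found")

    n = len(data_rows)
    eog = np.empty((n, 4))
    acc_rows: list[list[float]] = []
    start_time = None
    for k, cells in enumerate(data_rows):
        if start_time is None:
            start_time = _dt.datetime.strptime(cells[1], DATE_FORMAT)
        if cells[2] != "":
            acc_rows.append([float(cells[2]), float(cells[3]), float(cells[4])])
        eog[k] = [float(c) for c in cells[5:9]]

    acc = np.asarray(acc_rows, dtype=np.float64).reshape(-1, 3)
    code = int(params.get("label_code", 0))
    rec = RawRecording(
        label=label_map(code),
        eog_l=eog[:, 0],
        eog_r=eog[:, 1],
        eog_h=eog[:, 2],
        eog_v=eog[:, 3],
        acc_x=acc[:, 0],
        acc_y=acc[:, 1],
        acc_z=acc[:, 2],
        start_time=start_time or _dt.datetime(2022, 3, 1, 12, 0, 0),
    )
    if n:
        dev_h = float(np.max(np.abs(rec.eog_h - (rec.eog_l - rec.eog_r))))
        dev_v = float(np.max(np.abs(rec.eog_v + (rec.eog_l + rec.eog_r) / 2)))
        if dev_h > identity_tol or dev_v > identity_tol:
            warnings.warn(
                f"{path}: derived-channel identity deviation (eog_h: {dev_h:.3g}, eog_v: {dev_v:.3g})",
                UserWarning,
                stacklevel=2,
            )
    return rec
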