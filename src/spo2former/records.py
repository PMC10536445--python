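"""Reading, cleaning, normalizing and windowing overnight SpO2 records.

A :class:`PatientRecord` is one patient's 1 Hz oxygen-saturation series with
aligned per-second binary labels (0 = normal breathing, 1 = apnea) and,
optionally, the list of annotated respiratory events. Records travel on disk
as plain per-patient CSV files with columns ``t_s`` (integer seconds,
strictly increasing), ``spo2`` (percent, empty cell = missing sample) and
``label`` (0/1); the filename stem is the patient id.

Model input is a :class:`Segment`: a fixed-length window of the record whose
values are min–max rescaled to [0, 1] independently of all other windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupShuffleSplit, train_test_split


class RecordParseError(ValueError):
    """A record file violates the CSV contract (bad value, bad label...)."""


class EmptyRecordError(ValueError):
    """An operation would leave or received a record with no samples."""


class SplitError(ValueError):
    """A requested train/test split is impossible."""


@dataclass(frozen=True)
class EventAnnotation:
    """A scored respiratory event: ``[start_s, start_s + duration_s)``."""

    start_s: int
    duration_s: int
    kind: str = "apnea"

    def __post_init__(self):
        if self.start_s < 0 or self.duration_s <= 0:
            raise ValueError("event must have start_s >= 0 and positive duration")


@dataclass
class PatientRecord:
    """One patient's 1 Hz SpO2 series with per-second apnea labels."""

    patient_id: str
    spo2: np.ndarray
    labels: np.ndarray
    sampling_rate_hz: float = 1.0
    events: list[EventAnnotation] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.spo2 = np.asarray(self.spo2, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.spo2.shape != self.labels.shape or self.spo2.ndim != 1:
            raise ValueError("spo2 and labels must be 1-D arrays of equal length")
        finite = self.spo2[~np.isnan(self.spo2)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("SpO2 values must lie in [0, 100]")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        if self.events is not None:
            for ev in self.events:
                if ev.start_s + ev.duration_s > len(self.spo2):
                    raise ValueError("event extends past the end of the record")

    def __len__(self) -> int:
        return len(self.spo2)

    @property
    def duration_hours(self) -> float:
        return len(self.spo2) / self.sampling_rate_hz / 3600.0


@dataclass
class Segment:
    """A normalized fixed-length window of a record, the model's input unit."""

    values: np.ndarray
    labels: np.ndarray
    patient_id: str
    start_s: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.shape != self.labels.shape:
            raise ValueError("segment values and labels must align")

    @property
    def length_s(self) -> int:
        return len(self.values)


# -- CSV I/O ------------------------------------------------------------------

_COLUMNS = ("t_s", "spo2", "label")


def write_record(record: PatientRecord, path: str | Path) -> Path:
    """Write a record as ``<patient_id>.csv`` into ``path`` (or to ``path``
    itself when it ends in ``.csv``). Missing SpO2 samples become empty cells."""
    path = Path(path)
    if path.suffix != ".csv":
        path.mkdir(parents=True, exist_ok=True)
        path = path / f"{record.patient_id}.csv"
    df = pd.DataFrame(
        {
            "t_s": np.arange(len(record), dtype=np.int64),
            "spo2": record.spo2,
            "label": record.labels,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def read_record(path: str | Path) -> PatientRecord:
    """Parse one per-patient CSV into a :class:`PatientRecord`."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV structure
        raise RecordParseError(f"{path}: unreadable record file ({exc})") from exc
    missing_cols = set(_COLUMNS) - set(df.columns)
    if missing_cols:
        raise RecordParseError(f"{path}: missing columns {sorted(missing_cols)}")
    spo2 = pd.to_numeric(df["spo2"], errors="coerce").to_numpy(dtype=np.float64)
    bad = np.isnan(spo2) & df["spo2"].notna().to_numpy() & (df["spo2"].astype(str).str.strip() != "").to_numpy()
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
        raise RecordParseError(f"{path}: non-numeric spo2 value at line {line}")
    labels_raw = pd.to_numeric(df["label"], errors="coerce")
    invalid = ~labels_raw.isin((0, 1))
    if invalid.any():
        line = int(np.flatnonzero(invalid.to_numpy())[0]) + 2
        raise RecordParseError(f"{path}: label outside {{0,1}} at line {line}")
    t = pd.to_numeric(df["t_s"], errors="coerce").to_numpy()
    if np.isnan(t).any() or (np.diff(t) <= 0).any():
        raise RecordParseError(f"{path}: t_s must be strictly increasing integers")
    finite = spo2[~np.isnan(spo2)]
    if finite.size and (finite.min() < 0 or finite.max() > 100):
        line = int(np.flatnonzero((spo2 < 0) | (spo2 > 100))[0]) + 2
        raise RecordParseError(f"{path}: spo2 outside [0, 100] at line {line}")
    return PatientRecord(
        patient_id=path.stem,
        spo2=spo2,
        labels=labels_raw.to_numpy(dtype=np.int64),
    )


def read_records(path: str | Path) -> list[PatientRecord]:
    """Read a cohort: a directory of record CSVs, a single CSV, or a
    manifest file listing one record path per line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
    elif path.suffix == ".csv":
        files = [path]
    else:
        base = path.parent
        files = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if line:
                p = Path(line)
                files.append(p if p.is_absolute() else base / p)
    if not files:
        raise RecordParseError(f"{path}: no record files found")
    return [read_record(f) for f in files]


# -- cleaning and normalization ----------------------------------------------


def drop_missing(record: PatientRecord) -> tuple[PatientRecord, int]:
    """Remove missing (NaN) SpO2 samples with their aligned labels.

    Returns the cleaned record and the number of samples removed. Order of
    surviving samples is preserved; an all-missing record is an error.
    """
    keep = ~np.isnan(record.spo2)
    removed = int((~keep).sum())
    if not keep.any():
        raise EmptyRecordError(f"{record.patient_id}: no samples left after dropping missing values")
    if removed == 0:
        return record, 0
    cleaned = replace(
        record,
        spo2=record.spo2[keep],
        labels=record.labels[keep],
        events=None,  # second offsets shift when samples are removed
        meta={**record.meta, "n_dropped": removed},
    )
    return cleaned, removed


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Rescale an array to [0, 1] via (v - min) / (max - min).

    A constant array maps to all zeros so that flat oximetry windows do not
    abort the pipeline.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot normalize an empty array")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def window_record(
    record: PatientRecord,
    length_s: int,
    stride_s: int | None = None,
    normalize: bool = True,
) -> list[Segment]:
    """Cut a record into fixed-length windows.

    Windows start at 0, stride, 2·stride, ...; a trailing remainder shorter
    than ``length_s`` is discarded. Each window is min–max normalized
    independently (disable with ``normalize=False``).
    """
    if length_s < 1:
        raise ValueError("length_s must be >= 1")
    stride_s = length_s if stride_s is None else stride_s
    if stride_s < 1:
        raise ValueError("stride_s must be >= 1")
    t = len(record)
    if length_s > t:
        warnings.warn(
            f"{record.patient_id}: record of {t} s is shorter than window {length_s} s; no segments",
            stacklevel=2,
        )
        return []
    if np.isnan(record.spo2).any():
        raise ValueError("record contains missing values; run drop_missing first")
    count = (t - length_s) // stride_s + 1
    segments = []
    for j in range(count):
        start = j * stride_s
        vals = record.spo2[start : start + length_s]
        segments.append(
            Segment(
                values=minmax_normalize(vals) if normalize else vals.copy(),
                labels=record.labels[start : start + length_s].copy(),
                patient_id=record.patient_id,
                start_s=start,
            )
        )
    return segments


# -- splitting ----------------------------------------------------------------


def split_holdout(
    items: list,
    test_fraction: float,
    mode: str = "segment-random",
    seed: int = 0,
):
    """Split segments or records into train and test sets.

    ``segment-random`` shuffles items individually; ``patient-grouped``
    keeps every item of a patient on one side (items must expose a
    ``patient_id`` attribute).
    """
    if not 0.0 < test_fraction < 1.0:
        raise SplitError("test_fraction must be in (0, 1)")
    if mode == "segment-random":
        if len(items) < 2:
            raise SplitError("need at least 2 items to split")
        train, test = train_test_split(
            items, test_size=test_fraction, random_state=seed, shuffle=True
        )
        return list(train), list(test)
    if mode == "patient-grouped":
        groups = [getattr(it, "patient_id") for it in items]
        if len(set(groups)) < 2:
            raise SplitError("patient-grouped split needs at least 2 patients")
        splitter = GroupShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
        (train_idx, test_idx), = splitter.split(items, groups=groups)
        return [items[i] for i in train_idx], [items[i] for i in test_idx]
    raise ValueError(f"unknown split mode {mode!r}")
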