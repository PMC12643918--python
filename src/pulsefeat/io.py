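"""Waveform and annotation I/O, and slicing records into analysis windows.

The unit of ingestion is a single-channel pressure (ABP, mmHg) or
photoplethysmography (PPG, arbitrary units) sample series with a known
sampling rate. Analysis operates on non-overlapping fixed-length windows
(4 s by default); a trailing partial window is discarded.

All indexing is 0-based sample indexing; a sample index converts to
seconds as ``index / fs``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalKind",
    "LANDMARK_TYPES",
    "WaveformRecord",
    "Window",
    "AnnotationSet",
    "read_waveform",
    "write_waveform",
    "iter_windows",
    "read_annotations",
    "write_annotations",
]

#: The five temporal landmarks of a cardiac cycle, in within-cycle order:
#: systolic phase onset, systolic phase peak, dicrotic notch, diastolic
#: phase peak, diastolic phase endpoint.
LANDMARK_TYPES = ("SPO", "SPP", "DN", "DPP", "DPE")


class SignalKind(str, enum.Enum):
    """Waveform modality."""

    ABP = "ABP"
    PPG = "PPG"


@dataclass(frozen=True)
class WaveformRecord:
    """A single-channel waveform with sampling metadata.

    Parameters
    ----------
    samples
        Amplitude series (mmHg for ABP, arbitrary units for PPG).
    fs
        Sampling rate in Hz; must be positive.
    kind
        Signal modality (ABP or PPG).
    label
        Free-text identifier used in output tables.
    """

    samples: np.ndarray
    fs: float
    kind: SignalKind = SignalKind.ABP
    label: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float).ravel()
        )

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass(frozen=True)
class Window:
    """A contiguous slice of a parent record.

    ``start_index`` is the 0-based sample offset of the first sample in
    the parent record, so window-relative landmark indices convert to
    record-absolute ones by adding it.
    """

    start_index: int
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples", np.asarray(self.samples, dtype=float).ravel()
        )

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class AnnotationSet:
    """Sorted landmark sample indices per landmark type.

    ``marks`` maps each landmark type (``SPO`` ... ``DPE``) to a strictly
    increasing integer array of record-absolute sample indices.
    """

    marks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for key in LANDMARK_TYPES:
            idx = np.asarray(self.marks.get(key, []), dtype=int).ravel()
            idx = np.unique(idx)  # sorted + deduplicated
            clean[key] = idx
        self.marks = clean

    def __getitem__(self, landmark: str) -> np.ndarray:
        return self.marks[landmark]

    def total(self) -> int:
        return int(sum(len(v) for v in self.marks.values()))


def read_waveform(
    path: str | Path,
    fs: float,
    kind: SignalKind | str = SignalKind.ABP,
    label: str | None = None,
) -> WaveformRecord:
    """Read a single-channel waveform from a CSV file.

    The file holds one numeric value per row, with an optional header line
    (auto-detected by a non-numeric first row) and an optional leading time
    column; when two columns are present the second is taken as the sample
    series. Decimal separator is '.', field separator is ','.

    Raises
    ------
    ValueError
        If ``fs`` is not positive or a data row is non-numeric (the error
        names the offending row).
    FileNotFoundError
        If ``path`` does not exist.
    """
    path = Path(path)
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    if not path.exists():
        raise FileNotFoundError(str(path))
    kind = SignalKind(kind)

    with open(path, "r", newline="") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]

    def _parse_row(line: str) -> list[float] | None:
        try:
            return [float(tok) for tok in line.split(",")]
        except ValueError:
            return None

    start = 0
    if lines and _parse_row(lines[0]) is None:
        start = 1  # header line

    values: list[float] = []
    for rownum, line in enumerate(lines[start:], start=start + 1):
        parsed = _parse_row(line)
        if parsed is None:
            raise ValueError(f"{path}: non-numeric value on row {rownum}: {line!r}")
        # with a time column, the sample value is the second field
        values.append(parsed[1] if len(parsed) >= 2 else parsed[0])

    return WaveformRecord(
        samples=np.asarray(values, dtype=float),
        fs=fs,
        kind=kind,
        label=label if label is not None else path.stem,
    )


def write_waveform(record: WaveformRecord, path: str | Path, time_column: bool = False) -> None:
    """Write a waveform to CSV (one sample per row, optional time column)."""
    path = Path(path)
    if time_column:
        t = np.arange(len(record.samples)) / record.fs
        df = pd.DataFrame({"time": t, record.kind.value.lower(): record.samples})
    else:
        df = pd.DataFrame({record.kind.value.lower(): record.samples})
    df.to_csv(path, index=False, float_format="%.10g")


def iter_windows(
    record: WaveformRecord, window_seconds: float = 4.0
) -> Iterator[Window]:
    """Yield the record's non-overlapping complete analysis windows.

    Yields ``floor(N / (window_seconds * fs))`` windows of exactly
    ``round(window_seconds * fs)`` samples; a trailing partial window is
    discarded. A window longer than the record yields nothing.
    """
    if window_seconds <= 0:
        raise ValueError(f"window_seconds must be positive, got {window_seconds}")
    wlen = int(round(window_seconds * record.fs))
    n = len(record.samples)
    for start in range(0, n - wlen + 1, wlen):
        yield Window(
            start_index=start,
            samples=record.samples[start : start + wlen],
            fs=record.fs,
        )


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a landmark annotation CSV with columns (landmark_type, sample_index)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    type_col = cols.get("landmark_type", df.columns[0])
    idx_col = cols.get("sample_index", df.columns[1])
    marks: dict[str, list[int]] = {k: [] for k in LANDMARK_TYPES}
    for _, row in df.iterrows():
        lm = str(row[type_col]).strip().upper()
        if lm not in marks:
            raise ValueError(f"{path}: unknown landmark type {lm!r}")
        marks[lm].append(int(row[idx_col]))
    return AnnotationSet(marks={k: np.array(v, dtype=int) for k, v in marks.items()})


def write_annotations(
    annotations: AnnotationSet,
    path: str | Path,
    fs: float | None = None,
    extra: Mapping[str, Sequence] | None = None,
) -> None:
    """Write an annotation set to CSV with columns (landmark_type, sample_index[, time_s])."""
    rows = []
    for lm in LANDMARK_TYPES:
        for idx in annotations[lm]:
            row: dict[str, object] = {"landmark_type": lm, "sample_index": int(idx)}
            if fs is not None:
                row["time_s"] = idx / fs
            rows.append(row)
    pd.DataFrame(rows, columns=["landmark_type", "sample_index"] + (["time_s"] if fs else [])).to_csv(
        path, index=False
    )
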