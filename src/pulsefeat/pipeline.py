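"""End-to-end feature extraction: screen -> filter -> normalize -> IEM ->
delineate -> featurize, over non-overlapping 4-s windows.

Two execution modes share the identical per-window computation:

* ``recorded`` — the whole record is read, then windowed;
* ``stream_replay`` — the record is replayed in complete 4-s chunks, as
  a live monitor feed would deliver them. No partial windows are
  emitted and no state crosses chunk boundaries, so both modes produce
  identical landmarks on the windows they share.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .features import (
    CycleContext,
    build_manifest,
    compute_vitals,
    extract_cycle_features,
    write_features,
)
from .iem import IEMParams, decompose, scale_sg_window
from .io import (
    AnnotationSet,
    SignalKind,
    WaveformRecord,
    Window,
    iter_windows,
    write_annotations,
)
from .landmarks import CycleLandmarks, LandmarkParams, delineate_cycles, landmarks_to_record
from .preprocess import ScreenReason, lowpass_filter, normalize_minmax, screen_window

logger = logging.getLogger("pulsefeat")

__all__ = ["RunConfig", "RunReport", "featurize_record", "process_window"]

EXIT_OK = 0
EXIT_ERROR = 1
EXIT_NO_WINDOWS = 2


@dataclass
class RunConfig:
    """Settings for one featurization run.

    Window, filter and screening parameters mirror the pre-processing
    stage; ``iem`` and ``landmarks`` hold the decomposition and
    delineation settings. ``mode`` selects recorded or streaming-replay
    execution.
    """

    window_seconds: float = 4.0
    butter_order: int = 4
    butter_cutoff_hz: float = 16.0
    screen_min_peaks: int = 3
    screen_max_peaks: int = 10
    screen_percentile: float = 75.0
    iem: IEMParams = field(default_factory=IEMParams)
    landmarks: LandmarkParams = field(default_factory=LandmarkParams)
    mode: str = "recorded"
    out_dir: Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("recorded", "stream_replay"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def for_fs(cls, fs: float, **kwargs) -> "RunConfig":
        """Config with the SG window rescaled to the sampling rate."""
        iem = kwargs.pop("iem", None) or IEMParams(sg_window=scale_sg_window(fs))
        return cls(iem=iem, **kwargs)


@dataclass
class RunReport:
    """Counts and outputs of one run; accepted + rejected == total."""

    windows_total: int = 0
    windows_accepted: int = 0
    windows_rejected: int = 0
    reject_reasons: dict[str, int] = field(default_factory=dict)
    cycles_detected: int = 0
    cycles_featurized: int = 0
    mode: str = "recorded"
    features_path: Path | None = None
    landmarks_path: Path | None = None
    vitals_path: Path | None = None
    elapsed_s: float = 0.0

    @property
    def exit_code(self) -> int:
        return EXIT_OK if self.windows_accepted else EXIT_NO_WINDOWS

    def to_json(self) -> str:
        d = {k: (str(v) if isinstance(v, Path) else v)
             for k, v in self.__dict__.items()}
        return json.dumps(d, indent=2)


def process_window(
    window: Window, config: RunConfig
) -> tuple[ScreenReason, list[CycleLandmarks], "np.ndarray | None", "np.ndarray | None"]:
    """Run the per-window stages; shared by both execution modes.

    Returns the screening verdict, detected cycles (window-relative),
    and the normalized and raw filtered samples (None when rejected).
    """
    verdict = screen_window(
        window,
        min_peaks=config.screen_min_peaks,
        max_peaks=config.screen_max_peaks,
        percentile=config.screen_percentile,
    )
    if not verdict.accepted:
        return verdict.reason, [], None, None
    filtered = lowpass_filter(window, cutoff=config.butter_cutoff_hz, order=config.butter_order)
    nw = normalize_minmax(filtered)
    dec = decompose(nw.samples, config.iem)
    cycles = delineate_cycles(dec.nsts, window.fs, config.landmarks, signal=nw.samples)
    logger.info(
        "window@%d: accepted, %d cycles, %d IEM iterations",
        window.start_index, len(cycles), dec.n_iter,
    )
    return verdict.reason, cycles, nw.samples, nw.raw


def _window_stream(record: WaveformRecord, config: RunConfig) -> Iterable[Window]:
    """Recorded mode windows the record; stream replay feeds 4-s chunks."""
    if config.mode == "recorded":
        yield from iter_windows(record, config.window_seconds)
        return
    # stream_replay: deliver the same complete chunks sequentially, each
    # chunk re-windowed independently (no lookahead, no partial windows)
    wlen = int(round(config.window_seconds * record.fs))
    for start in range(0, len(record.samples) - wlen + 1, wlen):
        chunk = WaveformRecord(
            samples=record.samples[start : start + wlen],
            fs=record.fs,
            kind=record.kind,
            label=record.label,
        )
        for w in iter_windows(chunk, config.window_seconds):
            yield Window(start_index=start + w.start_index, samples=w.samples, fs=w.fs)


def featurize_record(record: WaveformRecord, config: RunConfig) -> RunReport:
    """Run the full pipeline over a record and write the output tables.

    Writes ``landmarks.csv``, ``features.csv`` and (for ABP)
    ``vitals.csv`` into ``config.out_dir`` when set; otherwise the run
    is in-memory only and the report carries just the counts.
    """
    t0 = time.perf_counter()
    report = RunReport(mode=config.mode)
    manifest = build_manifest(record.kind)
    vectors = []
    metadata = []
    vitals_rows = []
    all_cycles: list[tuple[list[CycleLandmarks], Window]] = []
    cycle_id = 0

    for window in _window_stream(record, config):
        report.windows_total += 1
        reason, cycles, norm, raw = process_window(window, config)
        if norm is None:
            report.windows_rejected += 1
            report.reject_reasons[reason.value] = (
                report.reject_reasons.get(reason.value, 0) + 1
            )
            continue
        report.windows_accepted += 1
        all_cycles.append((cycles, window))
        for cyc in cycles:
            report.cycles_detected += 1
            span = slice(cyc.spo, cyc.dpe + 1)
            ctx = CycleContext(
                norm=norm[span], raw=raw[span], landmarks=cyc,
                fs=window.fs, kind=record.kind,
            )
            try:
                vectors.append(extract_cycle_features(ctx, manifest, cycle_id))
            except ValueError:
                logger.warning("cycle %d: feature extraction failed", cycle_id)
                continue
            meta = {"record": record.label, "cycle_id": cycle_id}
            for lm, idx in cyc.as_dict().items():
                meta[lm] = "" if idx is None else idx + window.start_index
            metadata.append(meta)
            if record.kind == SignalKind.ABP:
                sbp, dbp, mean_ap = compute_vitals(ctx)
                vitals_rows.append(
                    {"cycle_id": cycle_id, "SBP": sbp, "DBP": dbp, "MAP": mean_ap}
                )
            report.cycles_featurized += 1
            cycle_id += 1

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        merged = AnnotationSet()
        for cycles, window in all_cycles:
            part = landmarks_to_record(cycles, window)
            for lm in merged.marks:
                merged.marks[lm] = np.unique(
                    np.concatenate([merged.marks[lm], part[lm]])
                )
        report.landmarks_path = out / "landmarks.csv"
        write_annotations(merged, report.landmarks_path, fs=record.fs)
        report.features_path = out / "features.csv"
        write_features(vectors, manifest, report.features_path, metadata)
        if vitals_rows:
            import pandas as pd

            report.vitals_path = out / "vitals.csv"
            pd.DataFrame(vitals_rows).to_csv(report.vitals_path, index=False)

    report.elapsed_s = time.perf_counter() - t0
    if report.windows_accepted == 0:
        logger.warning("no window passed screening; outputs are empty")
    return report


def detect_landmarks(record: WaveformRecord, config: RunConfig) -> AnnotationSet:
    """Convenience: run the pipeline and return merged absolute annotations."""
    merged = AnnotationSet()
    for window in _window_stream(record, config):
        _, cycles, norm, _ = process_window(window, config)
        if norm is None:
            continue
        part = landmarks_to_record(cycles, window)
        for lm in merged.marks:
            merged.marks[lm] = np.unique(np.concatenate([merged.marks[lm], part[lm]]))
    return merged
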