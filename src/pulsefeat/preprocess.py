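"""Window screening, low-pass filtering, and min-max normalization.

Each analysis window is screened for artifacts before any filtering:
a window is rejected if it contains zero or negative values, or if the
number of prominent peaks (strict local maxima above the 75th percentile
of the window's amplitudes) is fewer than 3 or more than 10 — i.e. a
4-s window must contain a plausible number of cardiac cycles.

Accepted windows are low-pass filtered with a 4th-order Butterworth
filter (16 Hz cutoff), applied forward-backward so landmark times are
not shifted by filter phase delay, then normalized to [0, 1] by the
window's extrema. The pre-normalization extrema are retained so raw
amplitudes (e.g. pressures in mmHg) can be recovered.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import Window

__all__ = [
    "ScreenReason",
    "ScreenResult",
    "NormalizedWindow",
    "screen_window",
    "lowpass_filter",
    "normalize_minmax",
    "strict_local_maxima",
    "strict_local_minima",
]


class ScreenReason(str, enum.Enum):
    OK = "ok"
    NONPOSITIVE_VALUES = "nonpositive_values"
    TOO_FEW_PEAKS = "too_few_peaks"
    TOO_MANY_PEAKS = "too_many_peaks"


@dataclass(frozen=True)
class ScreenResult:
    """Artifact-screening verdict for one window."""

    accepted: bool
    reason: ScreenReason
    n_peaks: int = 0

    def __post_init__(self) -> None:
        assert self.accepted == (self.reason == ScreenReason.OK)


@dataclass(frozen=True)
class NormalizedWindow:
    """A filtered window rescaled to [0, 1].

    ``y_min``/``y_max`` are the pre-normalization extrema of the filtered
    window; ``raw`` keeps the filtered (un-normalized) samples so absolute
    amplitudes remain available for vitals computation.
    """

    samples: np.ndarray
    fs: float
    start_index: int
    y_min: float
    y_max: float
    raw: np.ndarray

    def __len__(self) -> int:
        return len(self.samples)


def strict_local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus collapse to their first index.

    Boundary samples are never extrema. A plateau counts as a maximum only
    if the signal rises into it and falls after it.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        return np.array([], dtype=int)
    d = np.diff(y)
    out = []
    i = 0
    while i < n - 1:
        if d[i] > 0:
            # end of ascent; skip any plateau, require a descent after it
            j = i + 1
            while j < n - 1 and d[j] == 0:
                j += 1
            if j < n - 1 and d[j] < 0:
                out.append(i + 1)  # first sample of the peak/plateau
            i = j
        else:
            i += 1
    return np.array(out, dtype=int)


def strict_local_minima(y: np.ndarray) -> np.ndarray:
    """Indices of strict local minima (plateau -> first index)."""
    return strict_local_maxima(-np.asarray(y, dtype=float))


def screen_window(
    window: Window,
    min_peaks: int = 3,
    max_peaks: int = 10,
    percentile: float = 75.0,
    min_prominence_frac: float = 0.1,
) -> ScreenResult:
    """Apply the artifact-rejection criteria to a window.

    Rejects when any sample is <= 0, or when the count of qualifying
    peaks is below ``min_peaks`` or above ``max_peaks``. A qualifying
    peak is a local maximum exceeding the window's 75th amplitude
    percentile with prominence of at least ``min_prominence_frac`` of
    the window's amplitude range — the prominence floor keeps measurement
    noise from registering as pulse peaks.
    """
    y = np.asarray(window.samples, dtype=float)
    if len(y) == 0:
        raise ValueError("cannot screen an empty window")
    if np.any(y <= 0):
        return ScreenResult(False, ScreenReason.NONPOSITIVE_VALUES)
    thresh = np.percentile(y, percentile)  # linear interpolation convention
    rng = float(np.max(y) - np.min(y))
    peaks, _ = sps.find_peaks(y, prominence=min_prominence_frac * rng)
    qual = int(np.sum(y[peaks] > thresh)) if len(peaks) else 0
    if qual < min_peaks:
        return ScreenResult(False, ScreenReason.TOO_FEW_PEAKS, qual)
    if qual > max_peaks:
        return ScreenResult(False, ScreenReason.TOO_MANY_PEAKS, qual)
    return ScreenResult(True, ScreenReason.OK, qual)


def lowpass_filter(window: Window, cutoff: float = 16.0, order: int = 4) -> Window:
    """Zero-phase Butterworth low-pass filter of one window.

    Forward-backward application (``sosfiltfilt``) doubles the effective
    order but has exactly zero phase shift, so landmark positions on the
    filtered trace align with the raw waveform.
    """
    nyq = window.fs / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(
            f"cutoff must lie in (0, fs/2) = (0, {nyq}); got {cutoff}"
        )
    sos = sps.butter(order, cutoff, btype="low", fs=window.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, window.samples)
    return Window(start_index=window.start_index, samples=filtered, fs=window.fs)


def normalize_minmax(window: Window) -> NormalizedWindow:
    """Min-max normalize a (filtered) window to [0, 1].

    y_norm(n) = (y(n) - y_min) / (y_max - y_min).
    """
    y = np.asarray(window.samples, dtype=float)
    if len(y) < 2:
        raise ValueError("normalization requires at least 2 samples")
    y_min, y_max = float(np.min(y)), float(np.max(y))
    if y_max == y_min:
        raise ValueError("degenerate window: max == min (should have been screened)")
    return NormalizedWindow(
        samples=(y - y_min) / (y_max - y_min),
        fs=window.fs,
        start_index=window.start_index,
        y_min=y_min,
        y_max=y_max,
        raw=y,
    )
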