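"""Cardiac-cycle landmark detection on the non-stationary (NSTS) component.

After IEM decomposition the NSTS oscillates around zero: systolic peaks
(SPP) and diastolic peaks (DPP) appear as positive local maxima, while
systolic onsets (SPO), dicrotic notches (DN) and diastolic endpoints
(DPE) appear as negative local minima. Delineation applies the sign and
separation conditions:

* peaks taken as SPP/DPP must have NSTS value > 0; valleys taken as
  SPO/DN/DPE must have NSTS value < 0;
* DN must lie at least ``min_separation_s`` (default 0.1 s, i.e. 25
  samples at 256 Hz) after SPP, and DPP at least ``min_separation_s``
  before DPE;
* a cycle's onset-to-endpoint length must be physiologic
  (0.27-2.0 s by default, ~30-220 bpm).

Cycles are anchored on the dominant positive peaks: an SPP is a positive
NSTS maximum whose prominence is large relative to the window's peak
population (the deep onset valleys on either side of a true systolic
peak make it far more prominent than any dicrotic/reflection peak), and
each onset is the last negative valley before its SPP. The endpoint of
cycle k is the onset of cycle k+1, so only cycles followed by another
detected systolic peak are complete; trailing partial cycles are
dropped, and cycles without a qualifying DN are dropped rather than
imputed. DPP may be absent (flagged ``None``) — e.g. on DN-less
morphologies where no positive peak follows the notch.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import peak_prominences, savgol_filter

from .io import AnnotationSet, Window
from .preprocess import strict_local_maxima, strict_local_minima

__all__ = [
    "Polarity",
    "SignedExtremum",
    "CycleLandmarks",
    "LandmarkParams",
    "find_signed_extrema",
    "delineate_cycles",
    "landmarks_to_record",
]


class Polarity(str, enum.Enum):
    PEAK = "peak"
    VALLEY = "valley"


@dataclass(frozen=True)
class SignedExtremum:
    index: int
    value: float
    polarity: Polarity


@dataclass(frozen=True)
class CycleLandmarks:
    """The five landmark indices of one cardiac cycle (window-relative).

    ``dpp`` may be ``None`` when no qualifying diastolic peak exists.
    ``window_start`` is the parent window's offset into the record.
    """

    spo: int
    spp: int
    dn: int
    dpe: int
    dpp: int | None = None
    window_start: int = 0

    def __post_init__(self) -> None:
        order = [self.spo, self.spp, self.dn]
        if self.dpp is not None:
            order.append(self.dpp)
        order.append(self.dpe)
        if any(b <= a for a, b in zip(order, order[1:])):
            raise ValueError(f"landmarks out of order: {order}")

    def as_dict(self) -> dict[str, int | None]:
        return {
            "SPO": self.spo,
            "SPP": self.spp,
            "DN": self.dn,
            "DPP": self.dpp,
            "DPE": self.dpe,
        }


@dataclass(frozen=True)
class LandmarkParams:
    """Tunables of the delineator.

    ``min_separation_s`` is the minimum SPP-to-DN and DPP-to-DPE spacing
    (0.1 s = 25 samples at 256 Hz). ``min_cycle_s``/``max_cycle_s`` bound
    the physiologic cycle length (~30-220 bpm). ``spp_prominence_frac``
    is the fraction of the window's upper-quartile peak prominence a
    positive peak must reach to anchor a cycle as SPP.

    Localization is two-stage: the cycle structure (which extrema exist
    and their roles) is read off a Savitzky-Golay-smoothed NSTS
    (``smooth_window``/``smooth_polyorder``, matching the decomposition's
    smoothing), and each landmark is then refined to the extremum of the
    lightly smoothed localization target (``refine_window`` /
    ``refine_polyorder``; the normalized waveform when supplied to
    :func:`delineate_cycles`, else the NSTS) within ``refine_radius_s``
    of the structural position. On noise-free input the refinement
    reproduces the exact waveform extremum; under measurement noise it
    keeps noise excursions from displacing or duplicating landmarks.
    """

    min_separation_s: float = 0.1
    min_cycle_s: float = 0.27
    max_cycle_s: float = 2.0
    spp_prominence_frac: float = 0.5
    smooth_window: int = 25
    smooth_polyorder: int = 3
    refine_window: int = 7
    refine_polyorder: int = 2
    refine_radius_s: float = 0.03

    def __post_init__(self) -> None:
        if self.min_separation_s <= 0:
            raise ValueError("min_separation_s must be positive")
        if not 0 < self.min_cycle_s < self.max_cycle_s:
            raise ValueError("require 0 < min_cycle_s < max_cycle_s")


def find_signed_extrema(nsts: np.ndarray) -> list[SignedExtremum]:
    """All strict local extrema of the NSTS in index order.

    Plateaus collapse to their first index; boundary samples are never
    extrema. Constant input yields an empty list.
    """
    y = np.asarray(nsts, dtype=float)
    out = [
        SignedExtremum(int(i), float(y[i]), Polarity.PEAK)
        for i in strict_local_maxima(y)
    ] + [
        SignedExtremum(int(i), float(y[i]), Polarity.VALLEY)
        for i in strict_local_minima(y)
    ]
    return sorted(out, key=lambda e: e.index)


def _select_spp(y: np.ndarray, pos_peaks: np.ndarray, params: LandmarkParams, fs: float) -> np.ndarray:
    """Positive peaks prominent enough to anchor a cycle, min-cycle apart."""
    if len(pos_peaks) == 0:
        return pos_peaks
    # pad with the global minimum so peaks near the window edges get full
    # bases: an un-padded edge peak has an artificially clipped prominence
    pad = int(round(params.min_cycle_s * fs))
    ypad = np.concatenate([np.full(pad, y.min()), y, np.full(pad, y.min())])
    prom = peak_prominences(ypad, pos_peaks + pad)[0]
    # reference the top of the prominence distribution (the systolic peaks):
    # a lower quantile would collapse when noise floods the peak population
    thresh = params.spp_prominence_frac * np.percentile(prom, 90)
    cand = pos_peaks[prom >= thresh]
    cand_prom = prom[prom >= thresh]
    # enforce minimum spacing, keeping the more prominent of close pairs
    min_gap = int(round(params.min_cycle_s * fs))
    keep: list[int] = []
    for i in np.argsort(-cand_prom):  # most prominent first
        idx = cand[i]
        if all(abs(idx - k) >= min_gap for k in keep):
            keep.append(int(idx))
    return np.array(sorted(keep), dtype=int)


def delineate_cycles(
    nsts: np.ndarray,
    fs: float,
    params: LandmarkParams | None = None,
    signal: np.ndarray | None = None,
) -> list[CycleLandmarks]:
    """Detect complete cardiac cycles in one window's NSTS.

    Returns only complete cycles (SPO, SPP, DN, DPE all found, cycle
    length within physiologic bounds); DPP may be flagged absent. An
    empty list is returned when no complete cycle exists.

    When the normalized window ``signal`` is supplied, each landmark is
    localized to the corresponding extremum of the (lightly smoothed)
    waveform itself within ``refine_radius_s`` of its NSTS position: the
    NSTS decides which extrema are landmarks and their signs, while the
    waveform — whose extrema are far less perturbed by residual trend
    and noise — fixes the reported sample index. Without ``signal`` the
    NSTS itself is the localization target.
    """
    if params is None:
        params = LandmarkParams()
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    y = np.asarray(nsts, dtype=float)

    # stage 1: cycle structure from the smoothed NSTS
    ys = y
    if len(y) > params.smooth_window:
        ys = savgol_filter(y, params.smooth_window, params.smooth_polyorder)
    # stage 2 target: lightly smoothed waveform (or NSTS) for localization
    yr = np.asarray(signal, dtype=float) if signal is not None else y
    if len(yr) != len(y):
        raise ValueError("signal and nsts must have equal length")
    if len(yr) > params.refine_window:
        yr = savgol_filter(yr, params.refine_window, params.refine_polyorder)
    radius = max(int(round(params.refine_radius_s * fs)), 1)

    def refine(idx: int, polarity: Polarity) -> int:
        lo = max(idx - radius, 0)
        hi = min(idx + radius + 1, len(y))
        seg = yr[lo:hi]
        off = int(np.argmax(seg)) if polarity == Polarity.PEAK else int(np.argmin(seg))
        return lo + off

    def vertex_refine(idx: int) -> int:
        # least-squares parabola vertex: averages noise over the whole
        # refinement window, better than argmax for broad low-curvature
        # peaks such as the diastolic peak
        lo = max(idx - radius, 0)
        hi = min(idx + radius + 1, len(y))
        seg = yr[lo:hi]
        x = np.arange(len(seg), dtype=float)
        a, b, _ = np.linalg.lstsq(
            np.vstack([x**2, x, np.ones_like(x)]).T, seg, rcond=None
        )[0]
        if a >= 0:
            return idx
        v = -b / (2 * a)
        if not 0 <= v <= len(seg) - 1:
            return idx
        return lo + int(round(v))

    extrema = find_signed_extrema(ys)
    if not extrema:
        return []

    struct_peaks = np.array(
        [e.index for e in extrema if e.polarity == Polarity.PEAK], dtype=int
    )
    struct_valleys = np.array(
        [e.index for e in extrema if e.polarity == Polarity.VALLEY], dtype=int
    )
    peaks = np.array(
        sorted({refine(i, Polarity.PEAK) for i in struct_peaks}), dtype=int
    )
    valleys = np.array(
        sorted({refine(i, Polarity.VALLEY) for i in struct_valleys}), dtype=int
    )
    pos_peaks = peaks[y[peaks] > 0] if len(peaks) else peaks
    neg_valleys = valleys[y[valleys] < 0] if len(valleys) else valleys
    if len(pos_peaks) < 2 or len(neg_valleys) < 2:
        return []

    # anchor selection runs on the structural peaks (true extrema of the
    # smoothed NSTS, where prominences are well defined); the selected
    # anchors are then refined and sign-checked on the raw NSTS
    struct_pos = struct_peaks[y[struct_peaks] > 0] if len(struct_peaks) else struct_peaks
    spp_struct = _select_spp(ys, struct_pos, params, fs)
    spps = np.array(
        sorted({refine(i, Polarity.PEAK) for i in spp_struct}), dtype=int
    )
    spps = spps[y[spps] > 0]
    if len(spps) < 2:
        return []

    min_sep = int(round(params.min_separation_s * fs))
    min_len = int(round(params.min_cycle_s * fs))
    max_len = int(round(params.max_cycle_s * fs))

    def last_valley_before(idx: int) -> int | None:
        prior = neg_valleys[neg_valleys < idx]
        return int(prior[-1]) if len(prior) else None

    cycles: list[CycleLandmarks] = []
    for spp, next_spp in zip(spps, spps[1:]):
        spo = last_valley_before(spp)
        dpe = last_valley_before(next_spp)
        if spo is None or dpe is None or dpe <= spp:
            continue
        if not (min_len <= dpe - spo <= max_len):
            continue
        # DN: first negative valley at least min_sep after SPP, before DPE
        dn_cands = neg_valleys[
            (neg_valleys >= spp + min_sep) & (neg_valleys < dpe)
        ]
        if len(dn_cands) == 0:
            continue  # dropped, not imputed
        dn = int(dn_cands[0])
        # DPP: most prominent positive peak after DN, >= min_sep before DPE
        # (ranked on the smoothed localization target, robust to noise)
        dpp_cands = pos_peaks[(pos_peaks > dn) & (pos_peaks <= dpe - min_sep)]
        dpp = int(dpp_cands[np.argmax(yr[dpp_cands])]) if len(dpp_cands) else None
        if dpp is not None:
            cand = vertex_refine(dpp)
            if dn < cand <= dpe - min_sep:
                dpp = cand
        try:
            cycles.append(
                CycleLandmarks(spo=spo, spp=int(spp), dn=dn, dpe=dpe, dpp=dpp)
            )
        except ValueError:
            continue  # ordering violated by degenerate geometry
    return cycles


def landmarks_to_record(
    cycles: Sequence[CycleLandmarks], window: Window
) -> AnnotationSet:
    """Convert window-relative cycle landmarks to record-absolute annotations.

    Landmarks shared across windows (a boundary DPE equal to the next
    window's first SPO) deduplicate in the merged annotation set.
    """
    marks: dict[str, list[int]] = {k: [] for k in ("SPO", "SPP", "DN", "DPP", "DPE")}
    n = len(window)
    for cyc in cycles:
        for lm, idx in cyc.as_dict().items():
            if idx is None:
                continue
            if not 0 <= idx < n:
                raise ValueError(
                    f"landmark {lm}={idx} outside window of length {n}"
                )
            marks[lm].append(idx + window.start_index)
    return AnnotationSet(marks={k: np.array(v, dtype=int) for k, v in marks.items()})
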