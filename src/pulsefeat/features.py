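"""Per-cycle feature manifest (852 features) and feature extraction.

Every complete cardiac cycle yields 852 features spanning time-domain,
statistical and frequency-domain descriptors, all derived from the five
detected landmarks (SPO, SPP, DN, DPP, DPE) and the cycle's samples.
The feature catalogue is organized in 15 families with fixed sizes:

====================  =====
family                count
====================  =====
amplitude                30
amplitude_ratio         210
duration                 10
duration_ratio           46
average                  40
median                   20
rms                      20
skewness                  1
kurtosis                  1
area                     40
area_ratio              180
width                    36
frequency                12
first_derivative         28
second_derivative       178
====================  =====

Total: 852. The 25 canonical amplitude/duration features keep their
published names (``ABP/PPG_AM_SPP_wrtSPO``, ``ABP/PPG_D_DN_wrtDPE``,
...); the remaining members of each family are generated by the
deterministic rules documented per family in
:func:`manifest_to_markdown`'s output. Features that cannot be computed
for a cycle (absent diastolic peak, degenerate segment, undetectable
second-derivative waves) are set to NaN and serialized as empty CSV
cells, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq
from scipy.signal import savgol_filter
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .io import SignalKind
from .landmarks import CycleLandmarks
from .preprocess import strict_local_maxima, strict_local_minima

__all__ = [
    "FAMILY_COUNTS",
    "FeatureEntry",
    "FeatureManifest",
    "CycleContext",
    "FeatureVector",
    "build_manifest",
    "extract_cycle_features",
    "compute_vitals",
    "write_features",
    "manifest_to_markdown",
]

#: Published per-family feature counts; the manifest builder asserts them.
FAMILY_COUNTS = {
    "amplitude": 30,
    "amplitude_ratio": 210,
    "duration": 10,
    "duration_ratio": 46,
    "average": 40,
    "median": 20,
    "rms": 20,
    "skewness": 1,
    "kurtosis": 1,
    "area": 40,
    "area_ratio": 180,
    "width": 36,
    "frequency": 12,
    "first_derivative": 28,
    "second_derivative": 178,
}

_PREFIX = "ABP/PPG"
_LM = ("SPO", "SPP", "DN", "DPP", "DPE")

# the 15 published amplitude descriptors (landmark, reference) in table order
_AMPLITUDE_DEFS = [
    ("SPO", "Zero"), ("SPP", "SPO"), ("SPP", "Zero"), ("SPP", "DN"),
    ("SPP", "DPP"), ("SPP", "DPE"), ("DN", "Zero"), ("DN", "SPO"),
    ("DN", "DPE"), ("DPP", "Zero"), ("DPP", "SPO"), ("DPP", "DN"),
    ("DPP", "DPE"), ("DPE", "SPO"), ("DPE", "Zero"),
]
# the 10 published duration descriptors (from, to) in table order
_DURATION_DEFS = [
    ("SPO", "SPP"), ("SPO", "DN"), ("SPO", "DPP"), ("SPO", "DPE"),
    ("SPP", "DN"), ("SPP", "DPP"), ("SPP", "DPE"), ("DN", "DPP"),
    ("DN", "DPE"), ("DPP", "DPE"),
]
# the 10 landmark-delimited segments, in (earlier, later) order
_SEGMENTS = [
    ("SPO", "SPP"), ("SPO", "DN"), ("SPO", "DPP"), ("SPO", "DPE"),
    ("SPP", "DN"), ("SPP", "DPP"), ("SPP", "DPE"), ("DN", "DPP"),
    ("DN", "DPE"), ("DPP", "DPE"),
]
_WIDTH_HEIGHTS = tuple(range(10, 100, 10))  # 10% .. 90% of pulse height
_SDW = ("a", "b", "c", "d", "e")  # second-derivative wave labels


@dataclass(frozen=True)
class FeatureEntry:
    """One manifest entry: a named, family-tagged feature recipe."""

    name: str
    family: str
    description: str
    recipe: tuple


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered catalogue of the 852 per-cycle features."""

    kind: SignalKind
    entries: tuple[FeatureEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def family_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e.family] = out.get(e.family, 0) + 1
        return out


@dataclass
class CycleContext:
    """One cycle's data: normalized and raw samples plus landmark indices.

    ``norm`` and ``raw`` both span ``[spo .. dpe]`` inclusive; landmark
    indices in ``landmarks`` are window-relative, with ``norm[0]``
    corresponding to the SPO sample.
    """

    norm: np.ndarray
    raw: np.ndarray
    landmarks: CycleLandmarks
    fs: float
    kind: SignalKind = SignalKind.ABP

    def __post_init__(self) -> None:
        self.norm = np.asarray(self.norm, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.norm) != len(self.raw):
            raise ValueError("norm and raw spans differ in length")
        expect = self.landmarks.dpe - self.landmarks.spo + 1
        if len(self.norm) != expect:
            raise ValueError(
                f"cycle span length {len(self.norm)} != landmark span {expect}"
            )

    def rel(self, lm: str) -> int | None:
        """Landmark index relative to the cycle span (None for absent DPP)."""
        idx = self.landmarks.as_dict()[lm]
        return None if idx is None else idx - self.landmarks.spo


@dataclass
class FeatureVector:
    """One cycle's feature values, keyed exactly by the manifest names."""

    cycle_id: int
    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def _pairs_ordered(items: Sequence[str]) -> list[tuple[str, str]]:
    return [(a, b) for a in items for b in items if a != b]


def _pairs_unordered(items: Sequence[str]) -> list[tuple[str, str]]:
    return [(items[i], items[j]) for i in range(len(items)) for j in range(i + 1, len(items))]


def build_manifest(kind: SignalKind | str = SignalKind.ABP) -> FeatureManifest:
    """Build the deterministic 852-entry feature manifest.

    Two invocations return identical manifests; the published 25
    amplitude/duration features appear first within their families under
    their exact names.
    """
    kind = SignalKind(kind)
    entries: list[FeatureEntry] = []
    add = entries.append

    # -- amplitude (30): 15 published on the normalized window scale + the
    #    same 15 measured on the raw (pre-normalization) samples
    amp_names: list[str] = []
    for lm, ref in _AMPLITUDE_DEFS:
        name = f"{_PREFIX}_AM_{lm}_wrt{ref}"
        amp_names.append(name)
        add(FeatureEntry(name, "amplitude",
                         f"{lm} amplitude with respect to {ref} (normalized)",
                         ("amplitude", lm, ref, "norm")))
    for lm, ref in _AMPLITUDE_DEFS:
        add(FeatureEntry(f"{_PREFIX}_AM_{lm}_wrt{ref}_raw", "amplitude",
                         f"{lm} amplitude with respect to {ref} (raw units)",
                         ("amplitude", lm, ref, "raw")))

    # -- amplitude ratios (210): all ordered pairs of the 15 normalized
    #    amplitude descriptors
    short = [n.removeprefix(f"{_PREFIX}_AM_") for n in amp_names]
    for (na, nb) in _pairs_ordered(short):
        add(FeatureEntry(f"{_PREFIX}_AMR_{na}_over_{nb}", "amplitude_ratio",
                         f"amplitude ratio AM_{na} / AM_{nb}",
                         ("amplitude_ratio", na, nb)))

    # -- durations (10): published time differences, seconds
    dur_short: list[str] = []
    for a, b in _DURATION_DEFS:
        name = f"{_PREFIX}_D_{a}_wrt{b}"
        dur_short.append(f"{a}_wrt{b}")
        add(FeatureEntry(name, "duration",
                         f"duration from {a} to {b} in seconds",
                         ("duration", a, b)))

    # -- duration ratios (46): 45 unordered pairs + systolic/diastolic
    #    phase-duration ratio (SPD = SPO->DN, DPD = DN->DPE)
    for (na, nb) in _pairs_unordered(dur_short):
        add(FeatureEntry(f"{_PREFIX}_DR_{na}_over_{nb}", "duration_ratio",
                         f"duration ratio D_{na} / D_{nb}",
                         ("duration_ratio", na, nb)))
    add(FeatureEntry(f"{_PREFIX}_DR_SPD_over_DPD", "duration_ratio",
                     "systolic phase duration / diastolic phase duration",
                     ("spd_dpd_ratio",)))

    # -- averages (40): segment means of normalized signal, raw signal,
    #    first and second derivative
    seg_names = [f"{a}_{b}" for a, b in _SEGMENTS]
    for src in ("norm", "raw", "d1", "d2"):
        for (a, b), sn in zip(_SEGMENTS, seg_names):
            add(FeatureEntry(f"{_PREFIX}_AVG_{sn}_{src}", "average",
                             f"mean of {src} over segment {a}-{b}",
                             ("segstat", "mean", a, b, src)))
    # -- medians (20) and RMS (20): normalized signal and first derivative
    for stat, family in (("median", "median"), ("rms", "rms")):
        for src in ("norm", "d1"):
            for (a, b), sn in zip(_SEGMENTS, seg_names):
                add(FeatureEntry(f"{_PREFIX}_{stat.upper()}_{sn}_{src}", family,
                                 f"{stat} of {src} over segment {a}-{b}",
                                 ("segstat", stat, a, b, src)))

    # -- skewness, kurtosis (1 + 1): full normalized cycle
    add(FeatureEntry(f"{_PREFIX}_SKEW", "skewness",
                     "skewness of the normalized cycle samples", ("skew",)))
    add(FeatureEntry(f"{_PREFIX}_KURT", "kurtosis",
                     "excess kurtosis of the normalized cycle samples", ("kurt",)))

    # -- areas (40): trapezoidal integrals over the 10 segments, on the
    #    same four sources as the averages
    for src in ("norm", "raw", "d1", "d2"):
        for (a, b), sn in zip(_SEGMENTS, seg_names):
            add(FeatureEntry(f"{_PREFIX}_AR_{sn}_{src}", "area",
                             f"trapezoidal area of {src} over segment {a}-{b}",
                             ("area", a, b, src)))

    # -- area ratios (180): ordered pairs of the 10 normalized-signal
    #    segment areas (90) and of the 10 raw-signal segment areas (90)
    for src in ("norm", "raw"):
        for (sa, sb) in _pairs_ordered(seg_names):
            add(FeatureEntry(f"{_PREFIX}_ARR_{sa}_over_{sb}_{src}", "area_ratio",
                             f"area ratio {sa} / {sb} on {src}",
                             ("area_ratio", sa, sb, src)))

    # -- widths (36): at 9 heights (10-90% of pulse height): systolic
    #    (rise) width, diastolic (decay) width, total width, decay/rise ratio
    for h in _WIDTH_HEIGHTS:
        add(FeatureEntry(f"{_PREFIX}_SW_{h}", "width",
                         f"systolic rise width at {h}% height, seconds",
                         ("width", "sw", h)))
    for h in _WIDTH_HEIGHTS:
        add(FeatureEntry(f"{_PREFIX}_DW_{h}", "width",
                         f"decay-phase width at {h}% height, seconds",
                         ("width", "dw", h)))
    for h in _WIDTH_HEIGHTS:
        add(FeatureEntry(f"{_PREFIX}_TW_{h}", "width",
                         f"total width at {h}% height, seconds",
                         ("width", "tw", h)))
    for h in _WIDTH_HEIGHTS:
        add(FeatureEntry(f"{_PREFIX}_DWSW_{h}", "width",
                         f"decay/rise width ratio at {h}% height",
                         ("width", "ratio", h)))

    # -- frequency domain (12)
    for i in (1, 2, 3):
        add(FeatureEntry(f"{_PREFIX}_FQ_PK{i}_HZ", "frequency",
                         f"frequency of spectral peak {i} (Hz)",
                         ("freq", f"pk{i}_hz")))
        add(FeatureEntry(f"{_PREFIX}_FQ_PK{i}_MAG", "frequency",
                         f"magnitude of spectral peak {i}",
                         ("freq", f"pk{i}_mag")))
    for key, desc in (
        ("centroid", "spectral centroid (Hz)"),
        ("bandwidth", "spectral bandwidth (Hz)"),
        ("rolloff", "85% spectral rolloff frequency (Hz)"),
        ("flatness", "spectral flatness"),
        ("fundamental", "fundamental frequency 1/cycle duration (Hz)"),
        ("h2h1", "second-to-first harmonic magnitude ratio"),
    ):
        add(FeatureEntry(f"{_PREFIX}_FQ_{key.upper()}", "frequency", desc,
                         ("freq", key)))

    # -- first derivative (28): values at the 5 landmarks, their 20 ordered
    #    differences, and global max, min, min/max ratio
    for lm in _LM:
        add(FeatureEntry(f"{_PREFIX}_D1_{lm}", "first_derivative",
                         f"first derivative at {lm} (1/s, normalized units)",
                         ("d1_at", lm)))
    for (a, b) in _pairs_ordered(list(_LM)):
        add(FeatureEntry(f"{_PREFIX}_D1_{a}_minus_{b}", "first_derivative",
                         f"first-derivative difference {a} - {b}",
                         ("d1_diff", a, b)))
    add(FeatureEntry(f"{_PREFIX}_D1_MAX", "first_derivative",
                     "maximum of the first derivative (max upslope)", ("d1_max",)))
    add(FeatureEntry(f"{_PREFIX}_D1_MIN", "first_derivative",
                     "minimum of the first derivative (max downslope)", ("d1_min",)))
    add(FeatureEntry(f"{_PREFIX}_D1_MIN_over_MAX", "first_derivative",
                     "ratio of max downslope to max upslope", ("d1_ratio",)))

    # -- second derivative (178): built from the a-e waves of the
    #    second derivative plus its values at the 5 landmarks
    pts = list(_SDW) + [f"at{lm}" for lm in _LM]  # 10 amplitude points
    for p in pts:
        add(FeatureEntry(f"{_PREFIX}_D2_AMP_{p}", "second_derivative",
                         f"second-derivative amplitude at {p}", ("d2_amp", p)))
    for wv in _SDW:
        add(FeatureEntry(f"{_PREFIX}_D2_T_{wv}", "second_derivative",
                         f"time of {wv}-wave from cycle onset (s)", ("d2_time", wv)))
    for wv in _SDW:
        add(FeatureEntry(f"{_PREFIX}_D2_TN_{wv}", "second_derivative",
                         f"time of {wv}-wave normalized by cycle duration",
                         ("d2_timenorm", wv)))
    for (a, b) in _pairs_unordered(list(_SDW)):
        add(FeatureEntry(f"{_PREFIX}_D2_DT_{a}_{b}", "second_derivative",
                         f"time difference between {a}- and {b}-waves (s)",
                         ("d2_dt", a, b)))
    for (a, b) in _pairs_ordered(pts):
        add(FeatureEntry(f"{_PREFIX}_D2_R_{a}_over_{b}", "second_derivative",
                         f"second-derivative amplitude ratio {a} / {b}",
                         ("d2_ratio", a, b)))
    for (a, b) in _pairs_unordered(pts):
        add(FeatureEntry(f"{_PREFIX}_D2_DIFF_{a}_{b}", "second_derivative",
                         f"second-derivative amplitude difference {a} - {b}",
                         ("d2_diff", a, b)))
    for key, desc in (
        ("max", "global maximum of the second derivative"),
        ("max_t", "time of the global second-derivative maximum (s)"),
        ("min", "global minimum of the second derivative"),
        ("min_t", "time of the global second-derivative minimum (s)"),
    ):
        add(FeatureEntry(f"{_PREFIX}_D2_{key.upper()}", "second_derivative",
                         desc, ("d2_global", key)))
    for key, desc in (
        ("bcde_a", "(b - c - d - e) / a aging-type index"),
        ("be_a", "(b - e) / a index"),
        ("bcd_a", "(b - c - d) / a index"),
        ("cdb_a", "(c + d - b) / a index"),
    ):
        add(FeatureEntry(f"{_PREFIX}_D2_IX_{key.upper()}", "second_derivative",
                         desc, ("d2_index", key)))
    for key, desc in (
        ("rms_sys", "second-derivative RMS over the systolic phase"),
        ("rms_dia", "second-derivative RMS over the diastolic phase"),
        ("rms_all", "second-derivative RMS over the full cycle"),
        ("rms_ratio", "systolic/diastolic second-derivative RMS ratio"),
        ("zero_cross", "zero crossings of the second derivative"),
    ):
        add(FeatureEntry(f"{_PREFIX}_D2_{key.upper()}", "second_derivative",
                         desc, ("d2_stat", key)))

    manifest = FeatureManifest(kind=kind, entries=tuple(entries))
    counts = manifest.family_counts()
    assert counts == FAMILY_COUNTS, f"family counts off: {counts}"
    assert len(manifest) == sum(FAMILY_COUNTS.values()) == 852
    assert len(set(manifest.names)) == 852, "duplicate feature names"
    return manifest


# ---------------------------------------------------------------------------
# extraction


def _safe_div(a: float, b: float) -> float:
    if not np.isfinite(a) or not np.isfinite(b) or abs(b) < 1e-12:
        return np.nan
    return a / b


def _detect_sd_waves(d2: np.ndarray) -> dict[str, int]:
    """Locate the a-e waves: alternating extrema of the second derivative.

    The a-wave is the dominant early maximum; b the following minimum,
    then c (max), d (min), e (max). Returns whatever prefix of the
    sequence exists.
    """
    maxima = strict_local_maxima(d2)
    minima = strict_local_minima(d2)
    if len(maxima) == 0:
        return {}
    # a-wave: the largest maximum in the first half of the cycle
    half = max(len(d2) // 2, 2)
    early = maxima[maxima < half]
    if len(early) == 0:
        early = maxima[:1]
    a = int(early[np.argmax(d2[early])])
    waves = {"a": a}
    pos = a
    for label, (pool, pick) in zip(
        ("b", "c", "d", "e"),
        [(minima, np.argmin), (maxima, np.argmax), (minima, np.argmin), (maxima, np.argmax)],
    ):
        nxt = pool[pool > pos]
        if len(nxt) == 0:
            break
        pos = int(nxt[0])  # first alternating extremum after the previous wave
        waves[label] = pos
    return waves


def _crossing_widths(y: np.ndarray, fs: float, peak: int) -> dict[int, tuple[float, float]]:
    """Rise/decay widths at each height: linear-interpolated crossings."""
    lo, hi = float(np.min(y)), float(np.max(y))
    out: dict[int, tuple[float, float]] = {}
    for h in _WIDTH_HEIGHTS:
        level = lo + (hi - lo) * h / 100.0
        rise = np.nan
        for i in range(peak, 0, -1):  # walk left from the peak
            if y[i - 1] <= level <= y[i]:
                frac = (level - y[i - 1]) / (y[i] - y[i - 1]) if y[i] != y[i - 1] else 0.0
                rise = (peak - (i - 1 + frac)) / fs
                break
        decay = np.nan
        for i in range(peak, len(y) - 1):  # walk right from the peak
            if y[i] >= level >= y[i + 1]:
                frac = (y[i] - level) / (y[i] - y[i + 1]) if y[i] != y[i + 1] else 0.0
                decay = ((i + frac) - peak) / fs
                break
        out[h] = (rise, decay)
    return out


def _spectral(y: np.ndarray, fs: float) -> dict[str, float]:
    """Frequency-domain descriptors of one (mean-removed) cycle."""
    y = y - np.mean(y)
    nfft = max(1024, len(y))
    mag = np.abs(rfft(y, n=nfft))
    freqs = rfftfreq(nfft, d=1.0 / fs)
    mag[0] = 0.0
    out: dict[str, float] = {}
    pk = strict_local_maxima(mag)
    # first three spectral peaks in frequency order
    for i in (1, 2, 3):
        if len(pk) >= i:
            out[f"pk{i}_hz"] = float(freqs[pk[i - 1]])
            out[f"pk{i}_mag"] = float(mag[pk[i - 1]])
        else:
            out[f"pk{i}_hz"] = np.nan
            out[f"pk{i}_mag"] = np.nan
    total = float(np.sum(mag))
    if total > 0:
        out["centroid"] = float(np.sum(freqs * mag) / total)
        out["bandwidth"] = float(
            np.sqrt(np.sum((freqs - out["centroid"]) ** 2 * mag) / total)
        )
        cum = np.cumsum(mag ** 2)
        out["rolloff"] = float(freqs[int(np.searchsorted(cum, 0.85 * cum[-1]))])
        power = mag ** 2
        nz = power[power > 0]
        out["flatness"] = float(
            np.exp(np.mean(np.log(nz))) / np.mean(nz)
        ) if len(nz) else np.nan
    else:
        out.update(centroid=np.nan, bandwidth=np.nan, rolloff=np.nan, flatness=np.nan)
    f0 = fs / len(y) if len(y) else np.nan
    out["fundamental"] = float(f0)
    if np.isfinite(f0) and f0 > 0 and freqs[-1] >= 2 * f0:
        m1 = float(np.interp(f0, freqs, mag))
        m2 = float(np.interp(2 * f0, freqs, mag))
        out["h2h1"] = _safe_div(m2, m1)
    else:
        out["h2h1"] = np.nan
    return out


def extract_cycle_features(
    ctx: CycleContext, manifest: FeatureManifest, cycle_id: int = 0
) -> FeatureVector:
    """Evaluate every manifest entry for one cycle.

    Entries whose inputs are unavailable (absent DPP, degenerate
    segments, missing second-derivative waves) evaluate to NaN.
    """
    if len(ctx.norm) < 4:
        raise ValueError("cycle too short for feature extraction (< 4 samples)")
    fs = ctx.fs
    y, raw = ctx.norm, ctx.raw
    n = len(y)
    dur = (n - 1) / fs

    # landmark positions relative to the span (DPP may be None)
    rel = {lm: ctx.rel(lm) for lm in _LM}

    # derivatives on the normalized cycle, lightly smoothed for stability
    d1 = np.gradient(y) * fs
    d2 = np.gradient(d1) * fs
    win = min(25, n if n % 2 == 1 else n - 1)
    if win >= 5:
        d1s = savgol_filter(d1, win, min(3, win - 2))
        d2s = savgol_filter(d2, win, min(3, win - 2))
    else:
        d1s, d2s = d1, d2
    src = {"norm": y, "raw": raw, "d1": d1s, "d2": d2s}

    def lm_value(arr: np.ndarray, lm: str) -> float:
        i = rel[lm]
        return np.nan if i is None else float(arr[i])

    # base amplitude descriptors (normalized + raw)
    amp: dict[str, dict[str, float]] = {"norm": {}, "raw": {}}
    for srckey in ("norm", "raw"):
        arr = src[srckey]
        for lm, ref in _AMPLITUDE_DEFS:
            v = lm_value(arr, lm)
            r = 0.0 if ref == "Zero" else lm_value(arr, ref)
            amp[srckey][f"{lm}_wrt{ref}"] = v - r

    # durations in seconds
    dur_vals: dict[str, float] = {}
    for a, b in _DURATION_DEFS:
        ia, ib = rel[a], rel[b]
        dur_vals[f"{a}_wrt{b}"] = (
            np.nan if ia is None or ib is None else (ib - ia) / fs
        )

    # segment statistics and areas
    def seg_slice(a: str, b: str) -> np.ndarray | None:
        ia, ib = rel[a], rel[b]
        if ia is None or ib is None or ib - ia < 1:
            return None
        return np.arange(ia, ib + 1)

    seg_stats: dict[tuple[str, str, str], dict[str, float]] = {}
    seg_area: dict[tuple[str, str], dict[str, float]] = {}
    for a, b in _SEGMENTS:
        sl = seg_slice(a, b)
        for srckey, arr in src.items():
            key = (a, b, srckey)
            if sl is None or len(sl) < 2:
                seg_stats[key] = {"mean": np.nan, "median": np.nan, "rms": np.nan}
                seg_area.setdefault((a, b), {})[srckey] = np.nan
                continue
            v = arr[sl]
            seg_stats[key] = {
                "mean": float(np.mean(v)),
                "median": float(np.median(v)),
                "rms": float(np.sqrt(np.mean(v ** 2))),
            }
            seg_area.setdefault((a, b), {})[srckey] = float(
                np.trapezoid(v, dx=1.0 / fs)
            )

    # widths around the systolic peak
    widths = _crossing_widths(y, fs, rel["SPP"]) if rel["SPP"] is not None else {}

    # frequency-domain block
    spec = _spectral(y, fs)

    # second-derivative waves
    waves = _detect_sd_waves(d2s)
    d2amp: dict[str, float] = {}
    d2time: dict[str, float] = {}
    for wv in _SDW:
        if wv in waves:
            d2amp[wv] = float(d2s[waves[wv]])
            d2time[wv] = waves[wv] / fs
        else:
            d2amp[wv] = np.nan
            d2time[wv] = np.nan
    for lm in _LM:
        d2amp[f"at{lm}"] = lm_value(d2s, lm)

    sys_sl = seg_slice("SPO", "DN")
    dia_sl = seg_slice("DN", "DPE")
    rms_sys = float(np.sqrt(np.mean(d2s[sys_sl] ** 2))) if sys_sl is not None else np.nan
    rms_dia = float(np.sqrt(np.mean(d2s[dia_sl] ** 2))) if dia_sl is not None else np.nan

    # dispatch every manifest entry
    out: dict[str, float] = {}
    for e in manifest.entries:
        r = e.recipe
        kind = r[0]
        if kind == "amplitude":
            _, lm, ref, srckey = r
            val = amp[srckey][f"{lm}_wrt{ref}"]
        elif kind == "amplitude_ratio":
            val = _safe_div(amp["norm"][r[1]], amp["norm"][r[2]])
        elif kind == "duration":
            val = dur_vals[f"{r[1]}_wrt{r[2]}"]
        elif kind == "duration_ratio":
            val = _safe_div(dur_vals[r[1]], dur_vals[r[2]])
        elif kind == "spd_dpd_ratio":
            val = _safe_div(dur_vals["SPO_wrtDN"], dur_vals["DN_wrtDPE"])
        elif kind == "segstat":
            _, stat, a, b, srckey = r
            val = seg_stats[(a, b, srckey)][stat]
        elif kind == "skew":
            val = float(_skew(y))
        elif kind == "kurt":
            val = float(_kurtosis(y))
        elif kind == "area":
            _, a, b, srckey = r
            val = seg_area[(a, b)][srckey]
        elif kind == "area_ratio":
            _, sa, sb, srckey = r
            ka = tuple(sa.split("_"))
            kb = tuple(sb.split("_"))
            val = _safe_div(seg_area[ka][srckey], seg_area[kb][srckey])
        elif kind == "width":
            _, which, h = r
            rise, decay = widths.get(h, (np.nan, np.nan))
            if which == "sw":
                val = rise
            elif which == "dw":
                val = decay
            elif which == "tw":
                val = rise + decay
            else:
                val = _safe_div(decay, rise)
        elif kind == "freq":
            val = spec[r[1]]
        elif kind == "d1_at":
            val = lm_value(d1s, r[1])
        elif kind == "d1_diff":
            val = lm_value(d1s, r[1]) - lm_value(d1s, r[2])
        elif kind == "d1_max":
            val = float(np.max(d1s))
        elif kind == "d1_min":
            val = float(np.min(d1s))
        elif kind == "d1_ratio":
            val = _safe_div(float(np.min(d1s)), float(np.max(d1s)))
        elif kind == "d2_amp":
            val = d2amp[r[1]]
        elif kind == "d2_time":
            val = d2time[r[1]]
        elif kind == "d2_timenorm":
            val = _safe_div(d2time[r[1]], dur)
        elif kind == "d2_dt":
            val = d2time[r[2]] - d2time[r[1]]
        elif kind == "d2_ratio":
            val = _safe_div(d2amp[r[1]], d2amp[r[2]])
        elif kind == "d2_diff":
            val = d2amp[r[1]] - d2amp[r[2]]
        elif kind == "d2_global":
            which = r[1]
            if which == "max":
                val = float(np.max(d2s))
            elif which == "max_t":
                val = float(np.argmax(d2s)) / fs
            elif which == "min":
                val = float(np.min(d2s))
            else:
                val = float(np.argmin(d2s)) / fs
        elif kind == "d2_index":
            a_, b_, c_, d_, e_ = (d2amp[w] for w in _SDW)
            which = r[1]
            if which == "bcde_a":
                val = _safe_div(b_ - c_ - d_ - e_, a_)
            elif which == "be_a":
                val = _safe_div(b_ - e_, a_)
            elif which == "bcd_a":
                val = _safe_div(b_ - c_ - d_, a_)
            else:
                val = _safe_div(c_ + d_ - b_, a_)
        elif kind == "d2_stat":
            which = r[1]
            if which == "rms_sys":
                val = rms_sys
            elif which == "rms_dia":
                val = rms_dia
            elif which == "rms_all":
                val = float(np.sqrt(np.mean(d2s ** 2)))
            elif which == "rms_ratio":
                val = _safe_div(rms_sys, rms_dia)
            else:
                val = float(np.sum(np.diff(np.sign(d2s[d2s != 0])) != 0))
        else:  # pragma: no cover - manifest and extractor built together
            raise KeyError(f"unknown recipe {r}")
        out[e.name] = float(val) if np.isfinite(val) else np.nan
    return FeatureVector(cycle_id=cycle_id, values=out)


def compute_vitals(ctx: CycleContext) -> tuple[float, float, float]:
    """Per-cycle SBP, DBP and MAP in mmHg from the raw ABP samples.

    SBP is the cycle maximum, DBP the minimum, and MAP the arithmetic
    mean of the raw pressure samples (the full waveform is available, so
    the true mean is used rather than the DBP + PP/3 estimate).
    """
    if ctx.kind != SignalKind.ABP:
        raise ValueError("vitals are defined for ABP cycles only")
    if len(ctx.raw) < 2:
        raise ValueError("cycle too short for vitals")
    return (
        float(np.max(ctx.raw)),
        float(np.min(ctx.raw)),
        float(np.mean(ctx.raw)),
    )


def write_features(
    vectors: Sequence[FeatureVector],
    manifest: FeatureManifest,
    path: str | Path,
    metadata: Sequence[Mapping[str, object]] | None = None,
) -> None:
    """Write one row per cycle: metadata columns then the 852 features.

    NaN sentinels serialize as empty cells.
    """
    meta_cols = ["record", "cycle_id", "SPO", "SPP", "DN", "DPP", "DPE"]
    rows = []
    for i, vec in enumerate(vectors):
        row: dict[str, object] = {c: "" for c in meta_cols}
        row["cycle_id"] = vec.cycle_id
        if metadata is not None and i < len(metadata):
            row.update(metadata[i])
        row.update(vec.values)
        rows.append(row)
    df = pd.DataFrame(rows, columns=meta_cols + manifest.names)
    df.to_csv(path, index=False, float_format="%.10g")


def manifest_to_markdown(manifest: FeatureManifest) -> str:
    """Render the manifest as a Markdown document (name, family, definition)."""
    lines = [
        "# Feature manifest",
        "",
        f"{len(manifest)} features per cardiac cycle, {len(FAMILY_COUNTS)} families.",
        "",
        "| # | name | family | definition |",
        "|---|------|--------|------------|",
    ]
    for i, e in enumerate(manifest.entries, start=1):
        lines.append(f"| {i} | `{e.name}` | {e.family} | {e.description} |")
    lines.append("")
    return "\n".join(lines)
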