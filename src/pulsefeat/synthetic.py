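"""Synthetic ABP/PPG pulse trains with known ground-truth landmarks.

Each cardiac cycle is an additive template in cycle phase ``u in [0,1)``:

* a systolic wave with a Gaussian apex, a quartic-sharpened rise (the
  abrupt upstroke of real pressure pulses, which keeps the cycle foot a
  sharp, well-defined minimum) and an exponential decay that persists
  through diastole until the next foot;
* a dicrotic Gaussian bump riding on the decay (the diastolic /
  reflection wave);
* a narrow negative Gaussian dip between systole and the bump (the
  incisura), whose amplitude scales with ``notch_depth``.

As ``notch_depth`` falls to 0 the dicrotic bump is simultaneously
broadened and advanced so the notch and the distinct diastolic peak
merge into the systolic decay — the DN-less morphology seen in many PPG
recordings. Per-cycle periods are drawn from a log-normal with
coefficient of variation ``hr_jitter_cv`` to avoid exact periodicity.
The assembled pulse train is scaled by ``systolic_amp``, shifted by
``baseline_offset`` (mmHg for ABP), and optionally summed with a slow
sinusoidal baseline drift and additive white Gaussian noise.

Ground-truth landmarks are located numerically on the noise-free,
drift-free assembled template: SPP is the cycle's maximal local maximum,
DN the first local minimum after SPP, DPP the largest local maximum
after DN, and SPO/DPE the inter-cycle minima. A cycle enters the ground
truth only when its endpoint *and* the following systolic peak lie
inside the record, mirroring visual markup where a cycle's end is only
identifiable once the next upstroke is visible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import AnnotationSet, SignalKind, WaveformRecord
from .preprocess import strict_local_maxima, strict_local_minima

__all__ = ["SynthParams", "GroundTruth", "synth_pulse_train"]

# systolic wave: peak phase, rise width (with quartic sharpening of the
# takeoff, emulating the abrupt upstroke of real pressure pulses), and the
# exponential decay constant of the systolic/diastolic runoff
_MU_S, _SIG_RISE, _QUARTIC = 0.15, 0.06, 0.4
_TAU_FALL = 0.38
_TAIL_SPAN = 2.3  # phase span after the peak at which the decay reaches zero
# dicrotic bump nominal center/width; incisura dip center/width
_MU_D, _SIG_D = 0.52, 0.045
_MU_N, _SIG_N = 0.40, 0.03
_DIP_GAIN = 0.28  # incisura dip amplitude per unit notch_depth
# a cycle enters the ground truth only when the next systolic peak lies at
# least this long before the record end (the endpoint is only identifiable
# once the following upstroke is fully visible)
_EDGE_MARGIN_S = 0.1


@dataclass(frozen=True)
class SynthParams:
    """Generator settings.

    Defaults emulate an adult radial ABP at 256 Hz: 75 bpm, pulse
    pressure 40 mmHg over an 80 mmHg diastolic baseline, a clearly
    visible dicrotic notch, mild heart-rate jitter, no drift or noise.
    """

    fs: float = 256.0
    duration_s: float = 10.0
    heart_rate_bpm: float = 75.0
    systolic_amp: float = 40.0
    dicrotic_amp: float = 0.16
    notch_depth: float = 0.6
    baseline_offset: float = 80.0
    drift_amp: float = 0.0
    drift_hz: float = 0.2
    noise_sd: float = 0.0
    hr_jitter_cv: float = 0.03
    start_phase: float = 0.7
    kind: SignalKind = SignalKind.ABP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not 20 < self.heart_rate_bpm < 240:
            raise ValueError(
                f"heart_rate_bpm must be in (20, 240), got {self.heart_rate_bpm}"
            )
        if self.notch_depth < 0 or self.notch_depth > 1:
            raise ValueError(f"notch_depth must be in [0, 1], got {self.notch_depth}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """True landmark indices plus per-cycle notch-visibility flags."""

    annotations: AnnotationSet
    dn_visible: tuple[bool, ...]
    n_cycles: int


def _cycle_template(u: np.ndarray, dicrotic_amp: float, notch_depth: float) -> np.ndarray:
    """Evaluate the unit-amplitude cycle template at phases ``u``.

    The systolic wave has a Gaussian apex with a quartic-sharpened rise
    (abrupt takeoff at the foot) and an exponential decay that persists
    through the cycle, so end-diastole keeps falling until the next foot.
    """
    zr = (_MU_S - np.minimum(u, _MU_S)) / _SIG_RISE
    rise = np.exp(-(0.5 * zr**2 + _QUARTIC * zr**4))
    # shifted exponential decay: reaches exactly zero at the tail span so
    # truncating a cycle's contribution introduces no step discontinuity
    x = np.maximum(u - _MU_S, 0.0)
    c = np.exp(-_TAIL_SPAN / _TAU_FALL)
    fall = np.clip((np.exp(-x / _TAU_FALL) - c) / (1.0 - c), 0.0, None)
    out = rise * fall
    # low notch depth -> broader, earlier dicrotic bump (merged morphology)
    mu_d = _MU_D - 0.06 * (1.0 - notch_depth)
    sig_d = _SIG_D + 0.08 * (1.0 - notch_depth)
    out += dicrotic_amp * np.exp(-0.5 * ((u - mu_d) / sig_d) ** 2)
    out -= _DIP_GAIN * notch_depth * np.exp(-0.5 * ((u - _MU_N) / _SIG_N) ** 2)
    return out


def synth_pulse_train(params: SynthParams) -> tuple[WaveformRecord, GroundTruth]:
    """Generate a pulse train and its ground-truth landmark annotations.

    Returns the noisy record and landmarks measured on the clean
    template; identical ``params`` (including ``seed``) reproduce both
    exactly.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs

    # draw per-cycle periods until the record is covered (plus margin)
    mean_period = 60.0 / params.heart_rate_bpm
    cv = max(params.hr_jitter_cv, 0.0)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    mu = np.log(mean_period) - 0.5 * sigma**2
    periods: list[float] = []
    starts: list[float] = [-params.start_phase * mean_period]
    while starts[-1] < params.duration_s + 2 * mean_period:
        T = float(rng.lognormal(mu, sigma)) if cv > 0 else mean_period
        periods.append(T)
        starts.append(starts[-1] + T)

    # assemble the clean pulse train (template tails reach +-0.5 cycle)
    clean = np.zeros(n)
    for t0, T in zip(starts[:-1], periods):
        u = (t - t0) / T
        mask = (u > -0.5) & (u < _MU_S + _TAIL_SPAN)
        if np.any(mask):
            clean[mask] += _cycle_template(
                u[mask], params.dicrotic_amp, params.notch_depth
            )

    gt = _ground_truth(clean, starts, periods, params)

    samples = params.baseline_offset + params.systolic_amp * clean
    if params.drift_amp:
        samples = samples + params.drift_amp * np.sin(
            2 * np.pi * params.drift_hz * t
        )
    if params.noise_sd:
        samples = samples + rng.normal(0.0, params.noise_sd, size=n)

    record = WaveformRecord(
        samples=samples, fs=params.fs, kind=params.kind, label=f"synth-{params.seed}"
    )
    return record, gt


def _ground_truth(
    clean: np.ndarray,
    starts: list[float],
    periods: list[float],
    params: SynthParams,
) -> GroundTruth:
    """Locate true landmarks on the clean assembled template."""
    n = len(clean)
    maxima = strict_local_maxima(clean)
    minima = strict_local_minima(clean)

    # onset of each cycle: the local minimum nearest its nominal start time
    onsets: list[int] = []
    for t0 in starts:
        k = int(round(t0 * params.fs))
        if k < 1 or k > n - 2 or len(minima) == 0:
            onsets.append(-1)
            continue
        cand = minima[np.abs(minima - k) < 0.45 * params.fs * min(periods)]
        onsets.append(int(cand[np.argmin(np.abs(cand - k))]) if len(cand) else -1)

    marks: dict[str, list[int]] = {k: [] for k in ("SPO", "SPP", "DN", "DPP", "DPE")}
    dn_flags: list[bool] = []
    n_cycles = 0
    for i in range(len(onsets) - 1):
        spo, dpe = onsets[i], onsets[i + 1]
        if spo < 0 or dpe < 0 or dpe <= spo:
            continue
        in_cycle_max = maxima[(maxima > spo) & (maxima < dpe)]
        if len(in_cycle_max) == 0:
            continue
        spp = int(in_cycle_max[np.argmax(clean[in_cycle_max])])
        # require the next upstroke's peak comfortably inside the record:
        # the cycle's endpoint is only identifiable once the next systolic
        # peak is fully visible
        nxt = maxima[maxima > dpe]
        if len(nxt) == 0 or nxt[0] >= n - round(_EDGE_MARGIN_S * params.fs):
            continue
        dn_cands = minima[(minima > spp) & (minima < dpe)]
        dn = int(dn_cands[0]) if len(dn_cands) else None
        dpp = None
        if dn is not None:
            dpp_cands = maxima[(maxima > dn) & (maxima < dpe)]
            if len(dpp_cands):
                dpp = int(dpp_cands[np.argmax(clean[dpp_cands])])
        marks["SPO"].append(spo)
        marks["SPP"].append(spp)
        if dn is not None:
            marks["DN"].append(dn)
        if dpp is not None:
            marks["DPP"].append(dpp)
        marks["DPE"].append(dpe)
        dn_flags.append(dn is not None)
        n_cycles += 1

    ann = AnnotationSet(marks={k: np.array(v, dtype=int) for k, v in marks.items()})
    return GroundTruth(annotations=ann, dn_visible=tuple(dn_flags), n_cycles=n_cycles)


def clean_template_record(params: SynthParams) -> tuple[WaveformRecord, GroundTruth]:
    """The same record with drift and noise disabled (for oracle tests)."""
    quiet = replace(params, drift_amp=0.0, noise_sd=0.0)
    return synth_pulse_train(quiet)
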