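# Methods

This note documents the models, parameters and design choices behind
`pulsefeat`, and what the synthetic evaluation does and does not show.

## Pre-processing

Waveforms are processed in non-overlapping windows of
`window_seconds = 4.0` s. Screening precedes filtering: a window is
rejected when it contains any sample ≤ 0, or when the count of
qualifying peaks is < 3 or > 10. A qualifying peak is a local maximum
above the window's 75th amplitude percentile (linear-interpolation
percentile convention) whose prominence is at least 10% of the window's
amplitude range. The prominence floor is this package's addition: with
a bare strict-local-maximum definition, any measurable noise turns
every wiggle into a "peak" and the screen rejects all windows. Both the
percentile rule and the screening verdict are invariant to positive
rescaling of the signal.

Accepted windows are low-pass filtered with a 4th-order Butterworth
filter, 16 Hz cutoff, applied forward–backward (`sosfiltfilt`). The
zero-phase application doubles the effective order but introduces no
group delay, so landmark times on the filtered trace align with the raw
waveform. Filtering is per accepted window; min–max normalization to
[0, 1] follows, with the pre-normalization extrema retained so raw
amplitudes (pressures in mmHg) stay available.

## Iterative Envelope Mean decomposition

Each iteration smooths the current residual with a Savitzky–Golay
filter (`sg_window = 25` samples at 256 Hz — about twice the shortest
inter-landmark interval of interest — scaled as `round(25·fs/256)`
kept odd for other rates; polynomial order 3, the standard order that
preserves peak shapes), locates the smoothed residual's local extrema,
and
interpolates the *raw* residual values at those locations with a
shape-preserving piecewise cubic (PCHIP), mirroring the first/last
knot to the window edges. Subtracting the envelope mean
`m_j = (upper + lower)/2` gives the next residual; iteration stops when
`max|m_j| ≤ β · range(input)` with `β = 0.1`, or at `max_iter = 50`.
The stopping norm (max-norm) is a conservative choice among the
norms compatible with a single accuracy level. The final residual is the
NSTS and the accumulated means are the STS, so `NSTS + STS == input`
exactly (float 64 round-off only, < 1e-12). Cost is O(J·N); J is
typically 2–4 on pulse waveforms.

**Envelope knots are prominence-filtered**: only extrema whose
prominence reaches `knot_prominence_frac = 0.25` of the smoothed
residual's range become knots. Without the filter, knots at the
dicrotic bump and notch give the envelope mean a within-cycle wave
that (a) leaks cardiac-period power into the STS — the recovered trend
then misses a known drift by an RMSE of ~0.066 normalized units even
though the drift band itself is recovered to ~0.003 — and (b) displaces
NSTS extrema by several samples. With the filter the envelopes pass
through the dominant per-cycle extrema (systolic peaks, cycle feet),
the STS is smooth at the cycle scale (drift RMSE ~0.007), and every
landmark-recovery figure improves. Setting the fraction to 0 restores
all-extrema envelopes.

## Landmark detection

Detection uses the sign and separation conditions on the NSTS: SPP and
DPP must be positive-valued maxima; SPO, DN and DPE negative-valued
minima; DN at least `min_separation_s = 0.1` s after SPP and DPP at
least 0.1 s before DPE (25 samples at 256 Hz); cycle length within
`min_cycle_s = 0.27` s to `max_cycle_s = 2.0` s (~30–220 bpm).

Cycle anchoring is prominence-based: SPP candidates are positive NSTS
maxima whose prominence reaches `spp_prominence_frac = 0.5` of the 90th
percentile of positive-peak prominences (the deep onset valleys on
either side of a true systolic peak make it far more prominent than
dicrotic or reflection peaks; the 90th-percentile reference keeps the
threshold meaningful when noise floods the peak population, and
prominences are computed on an array padded with the window minimum so
edge peaks get full bases). Each onset is the last negative valley
before its SPP; the endpoint of cycle k is the onset of cycle k+1, so
trailing partial cycles are dropped. DN is the first qualifying valley
after SPP (the notch precedes the diastolic wave); DPP the most
prominent qualifying peak after DN, optional — cycles without a
qualifying DN are dropped and logged, never imputed.

Localization is two-stage. The cycle *structure* is read off the
Savitzky–Golay-smoothed NSTS (same 25/3 smoothing as the
decomposition). Each landmark's *index* is then the extremum of the
lightly smoothed (7-sample, order-2) normalized waveform within
`refine_radius_s = 0.03` s of the structural position; for the broad,
low-curvature diastolic peak, the vertex of a least-squares parabola
over the refinement window is used instead of the argmax, which
averages noise over the window. Sign conditions are always evaluated
on the NSTS. On noise-free input this reproduces the waveform's exact
extremum; the NSTS alone is used when no waveform is supplied. The
waveform-refinement stage exists because the NSTS retains a residual
trend (iteration stops at β = 0.1) that, under measurement noise,
displaces NSTS extrema by 3–4 samples even though the filtered
waveform's own extrema stay within ±2 samples of truth ~98% of the
time.

## Feature extraction

The 852-feature catalogue is generated deterministically; family sizes
are fixed (30 amplitudes, 210 amplitude ratios, 10 durations, 46
duration ratios, 40 averages, 20 medians, 20 RMS, skewness, kurtosis,
40 areas, 180 area ratios, 36 widths, 12 frequency-domain, 28
first-derivative, 178 second-derivative). The 25 canonical
amplitude/duration features keep their established names; the
remaining members follow generation rules chosen by this package and
documented per entry in the `FEATURES.md` dump: amplitude ratios are all ordered pairs of the 15
normalized amplitudes; duration ratios the 45 unordered duration pairs
plus the systolic/diastolic phase-duration ratio; segment statistics
and areas run over the 10 landmark-delimited segments on the normalized
signal, raw signal and first/second derivative; widths are systolic,
diastolic, total and ratio at 9 heights (10–90% in 10% steps);
frequency-domain features come from the zero-padded spectrum of the
mean-removed cycle; second-derivative features build on the a–e waves
(alternating extrema of the smoothed second derivative) plus its values
at the five landmarks. "wrtZero" amplitudes are measured on the
normalized window scale, where zero is the window minimum. Derivatives
are central differences, Savitzky–Golay smoothed before extremum
picking. Incomputable entries (absent DPP, degenerate segment, missing
a–e waves) are NaN, serialized as empty CSV cells — never silent zeros.

MAP is the arithmetic mean of the cycle's raw pressure samples rather
than the DBP + PP/3 estimate: the full waveform is available, so the
true mean is computable.

## Evaluation

Matching is greedy nearest-neighbor and one-to-one within
±8 ms (`round(tol_ms·fs/1000)` samples); SE, PPV, F1 as usual, and the
error rate keeps its published asymmetric denominator
ER = (FP+FN)/(TP+FP), with a symmetric option for diagnostics. DPE is
excluded from scored landmark types by default since it coincides with
the next cycle's onset. Pooled (micro-averaged) counts are reported
alongside per-type rows. Bland–Altman limits are bias ± 1.96·SD
(n−1 SD).

## Synthetic waveform model

Each cycle is an additive template in cycle phase u ∈ [0, 1): a
systolic wave with a Gaussian apex (peak at u = 0.15, rise width
0.06), a quartic-sharpened rise — real pressure upstrokes take off
abruptly, and that sharpness is what makes the cycle foot a
well-defined minimum — and an exponential decay (τ = 0.38 cycle,
shifted to reach exactly zero at its truncation span so assembling
cycles introduces no steps); a dicrotic Gaussian bump
(amplitude 0.16 of pulse height at u = 0.52); and a narrow incisura
dip between them whose depth scales with `notch_depth`. As
`notch_depth → 0` the bump broadens and advances until notch and
diastolic peak merge into the decay (DN-less morphology, flagged per
cycle). Per-cycle periods are log-normal with CV
`hr_jitter_cv = 0.03`; the train is scaled to a 40 mmHg pulse over an
80 mmHg baseline (adult radial ABP scale), with optional sinusoidal
baseline drift and additive white Gaussian noise. Defaults were chosen
for physiological plausibility: normalized notch level ≈ 0.47 and
diastolic peak ≈ 0.53 of pulse height, systolic upstroke ≈ 100 ms,
notch at ≈ 40% of the cycle.

Ground truth is located numerically on the noise-free, drift-free
assembled template: SPP is the cycle's largest maximum, DN the first
minimum after it, DPP the largest maximum after DN, SPO/DPE the
inter-cycle minima. A cycle enters the ground truth only when its
endpoint and the following systolic peak lie at least 0.1 s inside the
record — an endpoint is only identifiable once the next upstroke is
fully visible, as in visual markup.

**What the synthetic evaluation shows and does not show.** The
generator exercises quasi-periodicity, heart-rate variation, baseline
drift, additive noise, DN-less morphologies and the artifact screen,
with exactly known landmark times — so detector accuracy can be stated
to the sample. It does not emulate arrhythmia, motion artifacts,
damped catheter lines, pulsus alternans, reflected-wave variability
across vascular ages, or PPG-specific morphology changes; passing
these tests demonstrates correctness of the algorithmic chain, not
clinical performance on real recordings. Windows rejected by the
screen are excluded from scoring, mirroring markup protocols that
annotate accepted windows only.

## Numerical and policy details

- 0-based sample indices throughout; seconds = index / fs.
- Evaluation-corpus problem sizes: 200 independent 4-s windows per
  condition (about 850 cycles), heart rates uniform in 50–110 bpm,
  noise at 2% of pulse amplitude for the noisy condition; chosen to
  give two-decimal stability of the percentage metrics.
- Degenerate inputs: constant windows fail normalization (and are
  screened out first); monotone signals use a documented fallback
  envelope through the endpoints and global extremum; flat NSTS yields
  no cycles; empty annotation sets score as warnings + NaN, never 0.
- Streaming mode is a replay of complete 4-s chunks through the same
  per-window code path — no partial windows, no cross-chunk state — so
  recorded and streamed runs are bit-identical on shared windows. Live
  monitor ingestion is out of scope; the chunk interface is the
  attachment point.
- Known limitations: landmarks are reported at integer sample
  resolution (no sub-sample interpolation); the screening thresholds
  are fixed rather than adaptive; high-frequency artifact rejection
  beyond the 16 Hz low-pass is not attempted; the IEM parameters
  (SG window, β) are fixed rather than data-driven.
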