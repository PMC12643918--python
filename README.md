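# pulsefeat

Automatic landmark detection and per-cycle feature extraction for
arterial blood pressure (ABP) and photoplethysmography (PPG) waveforms.

Continuous ABP and PPG recordings carry rich physiological information,
but using them quantitatively requires locating, in every cardiac
cycle, five temporal landmarks: the systolic phase onset (SPO), the
systolic phase peak (SPP), the dicrotic notch (DN), the diastolic phase
peak (DPP), and the diastolic phase endpoint (DPE, which coincides with
the next cycle's onset). `pulsefeat` is aimed at researchers who need
those landmarks — and the hundreds of morphological features derived
from them — from recorded or streamed single-channel waveforms, without
hand-marking.

## Method

The pipeline processes non-overlapping 4-s windows:

1. **Artifact screening** — a window is rejected if it contains zero or
   negative values, or if the number of prominent peaks above the 75th
   amplitude percentile is below 3 or above 10.
2. **Filtering and normalization** — a 4th-order Butterworth low-pass
   filter (16 Hz cutoff, zero-phase) followed by min–max normalization
   `y_norm(n) = (y(n) − y_min) / (y_max − y_min)`.
3. **Iterative Envelope Mean (IEM) decomposition** — repeatedly
   subtract the sample-by-sample mean of the signal's upper and lower
   envelopes (interpolated through the extrema of a Savitzky–Golay
   smoothed copy, 25-sample window). The iteration stops when the
   envelope mean falls below an accuracy level β = 0.1 of the signal
   range, splitting the window into a non-stationary component (NSTS,
   the oscillatory landmark-bearing part) and a stationary component
   (STS, the baseline trend); NSTS + STS reproduces the input exactly.
4. **Landmark detection on the NSTS** — systolic and diastolic peaks
   must be positive-valued NSTS maxima, onsets/notches/endpoints
   negative-valued minima; the notch must lie at least 0.1 s (25
   samples at 256 Hz) after the systolic peak, and the diastolic peak
   at least 0.1 s before the endpoint. Cycles are anchored on the
   prominent systolic peaks and must have physiologic length.
5. **Feature extraction** — 852 features per complete cycle in 15
   families (amplitudes, durations, their ratios, segment statistics,
   areas, widths at fractional heights, frequency-domain descriptors,
   and first/second-derivative features), written one row per cycle to
   CSV. For ABP, per-cycle SBP/DBP/MAP are reported as the cycle's
   maximum, minimum and mean pressure.

Detector output is scored against reference annotations with a ±8 ms
(2 samples at 256 Hz) one-to-one matching rule, yielding sensitivity
SE = TP/(TP+FN), positive predictive value PPV = TP/(TP+FP), their
harmonic mean F1, the error rate ER = (FP+FN)/(TP+FP), and Bland–Altman
agreement (bias ± 1.96 SD limits).

A synthetic pulse-train generator with analytic ground truth makes the
entire pipeline testable without clinical data; see
`docs/methods.md` for the waveform model and its limitations.

## Worked example

Simulate one minute of ABP-like data at 256 Hz, featurize it, and score
the detected landmarks against the generator's ground truth:

```sh
pulsefeat simulate --duration 60 --heart-rate 72 --seed 5 --out-dir sim
pulsefeat featurize --input sim/waveform.csv --fs 256 --kind abp --out-dir run
pulsefeat evaluate --detected run/landmarks.csv --reference sim/ground_truth.csv --fs 256
```

which prints (abridged):

```
wrote sim/waveform.csv (60.0 s, seed=5) and 71 ground-truth cycles
{
  "windows_total": 15,
  "windows_accepted": 15,
  "cycles_featurized": 56,
  ...
}
             tp     fp      fn     se    ppv     f1     er  bias_s
SPO     56.0000 0.0000 15.0000 0.7887 1.0000 0.8819 0.2679  0.0010
SPP     56.0000 0.0000 15.0000 0.7887 1.0000 0.8819 0.2679 -0.0005
DN      56.0000 0.0000 15.0000 0.7887 1.0000 0.8819 0.2679  0.0001
DPP     56.0000 0.0000 15.0000 0.7887 1.0000 0.8819 0.2679  0.0036
```

All 56 detected cycles are placed exactly (PPV = 1.0, bias ≤ 4 ms); the
15 false negatives are the cycles that straddle a 4-s window boundary,
which windowed processing cannot delineate (one per window). Scoring
whole 4-s windows against window-level ground truth — as the evaluation
corpus in the test suite does — yields SE = 100% and F1 ≈ 98% per
landmark. `run/features.csv` holds one row per cycle with 852 feature
columns, and `run/vitals.csv` the per-cycle SBP/DBP/MAP:

```
cycle_id,SBP,DBP,MAP
0,122.69436173830584,83.37958887532315,97.80029597932764
```

`pulsefeat manifest` writes `FEATURES.md`, the full catalogue of the
852 features with their family and definition.

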