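# Methods

## Data model

A subject's recording is a sequence of non-negative activity counts at fixed
one-minute spacing with a start timestamp (`ActigraphySeries`). A cohort
couples such recordings with a diagnostic group label and, for patients
only, MADRS depression scores taken before and after the recording window.
Before feature extraction every series is truncated to the cohort-wide
minimum length, keeping the earliest minutes. Truncating from the start
(rather than the end) preserves recording-onset alignment and is
deterministic; by construction no derived biomarker is ever missing.
Timestamps are taken at face value (no timezone/DST handling) because no
feature depends on absolute clock time.

## Feature families

For a truncated length *N* the vector has 209 + ⌊padlen(*N*)/2⌋ entries,
where padlen(*N*) is the smallest integer ≥ *N* whose prime factors are all
≤ 5. At *N* = 19,299, padlen = 19,440 = 2⁴·3⁵·5 and the vector has 9,929
entries.

- **Distribution (106).** Min, max, mean, median, mode, skewness
  m₃/m₂^{3/2}, excess kurtosis m₄/m₂² − 3, and the 1st–99th percentiles
  with the linear-interpolation quantile definition. The mode is the most
  frequent value after rounding to the nearest integer, ties resolved to
  the smallest value (activity counts are integers in practice; all other
  features treat values as reals). Skewness and kurtosis are defined as 0
  for zero-variance input so degenerate series still yield a complete
  vector.
- **Variability (3).** RMSSD_k = √(mean_t (x_{t+k} − x_t)²) at lags k = 1, 2
  minutes — an index of sharp short-interval shifts — plus the sample
  standard deviation (denominator n − 1).
- **Autoregressive (100).** The sample autocorrelation (mean-centered,
  normalized by the lag-0 sum of squares, FFT-computed) at lags 1–100 min
  describes the consistency of movement over a smooth continuum of lags. It
  is smoothed across the lag axis with a cubic smoothing spline whose
  penalty is selected by generalized cross-validation, then read back at
  the integer lags and clipped to [−1.05, 1.05] (the raw ACF lies in
  [−1, 1]; the spline may overshoot only marginally). A zero-variance
  series yields 100 zeros. The smoothing spline is a deliberately simple
  stand-in for richer time-varying lag models: the lag-feature continuum is
  what the classifier consumes, and for stationary processes the smoothed
  ACF recovers the theoretical autocorrelation (tested against AR(1) with
  coefficient 0.8 at lags ≤ 10 within ±0.05).
- **Spectral (⌊padlen/2⌋).** The raw periodogram I(f_k) = |DFT(x − x̄)_k|²/N
  of the mean-removed series zero-padded to padlen(*N*), at Fourier
  frequencies k/padlen for k = 1…⌊padlen/2⌋ (Nyquist included when padlen
  is even; f = 0 excluded as the mean is removed). No tapering or segment
  averaging: the raw periodogram is the simplest estimator consistent with
  a fixed per-frequency feature grid. 5-smooth padding is the standard
  FFT-efficiency convention, and it is the decomposition under which the
  four families sum to exactly 9,929 features at *N* = 19,299. The
  conjugate-symmetry-weighted bin sum satisfies the Parseval identity
  Σ w_k I_k = (padlen/N)·Σ(x − x̄)², tested to 1e-6 relative.

Scale behavior (audited by test): scaling the series by c > 0 scales
location/spread features by c and the periodogram by c², and leaves
skewness, kurtosis and the autocorrelation features unchanged.

## Prediction

Gradient-boosted trees (xgboost) under leave-one-subject-out
cross-validation (LOOCV): for each subject a fresh model is fit on the
other n − 1 rows (per-fold seed = master seed + fold index) and applied to
the held-out row. Defaults — 200 rounds, depth 3, learning rate 0.1, L2
penalty 1.0, row subsample 0.8 — are conservative choices for the small-n /
high-p regime (tens of subjects, ~10⁴ features) and are exposed in
`ModelConfig`. No within-fold hyperparameter tuning is performed; one
configuration is reused across folds. Classification ties at probability
0.5 resolve to the positive class (control), deterministically.

Outcome metrics: accuracy, sensitivity, specificity and Cohen's kappa from
the 2×2 confusion matrix with **control as the positive class**; the
no-information rate (majority-class proportion) with an exact one-sided
binomial tail P(X ≥ #correct | n, NIR); Pearson r between predicted and
actual MADRS change (patients only) with the two-sided t-transform p-value
(n − 2 df), plus both vectors sample-standardized to z-scores for plotting.
Change scores are pre − post, so positive change = symptom improvement.

Permutation tests re-run the **entire** LOOCV-plus-metric pipeline on each
of B outcome shuffles; p = (1 + #{null ≥ observed})/(B + 1). Because the
null draws pass through the same cross-validation machinery, any bias of
the estimator is reproduced under the null and the p-values stay
calibrated. This matters: LOOCV of a flexible classifier has a well-known
*pessimistic* bias on null data (holding out one subject tilts the training
majority against it), so null-cohort accuracy sits systematically below the
no-information rate. The calibration test in this package checks both that
permutation p-values are uniform across seeds (Kolmogorov–Smirnov) and that
null accuracy stays within per-cohort binomial noise of the NIR.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline targets: by
default 23 patients and 32 controls, 19,299 minutes each. Minute t (with
minute-of-day m) is

x_t = round(max(0, g_t·(μ_g + s·1[t ≥ N/2] + A_g·cos(2π(m − φ)/1440) + e_t)))

- μ_g: waking mean, 220 counts/min for controls, ×0.6 for patients;
- A_g: circadian amplitude, 180 counts for controls, ×0.6 for patients;
  acrophase φ = 900 min (15:00);
- e_t: stationary AR(1) noise, coefficient 0.6, innovation sd 80 counts;
- g_t: sleep gate — inside the wrap-around window 23:00→07:00 the signal is
  scaled to a mean near 5 counts/min;
- s: per-subject level shift ~ N(0, 30²) counts applied to the second half
  of the recording (all subjects, so null cohorts remain exchangeable).

Patient MADRS: pre ~ Uniform(18, 30); post = pre − 4·δ + N(0, 2²), where δ
is the patient's *standardized* second-half-minus-first-half mean activity
computed from the final rounded series. Coupling change to a within-subject
activity shift (rather than to diagnosis) gives the regression task signal
independent of the classification task, and computing δ from the emitted
series makes the change exactly recoverable from the actigraphy (with zero
MADRS noise the correlation is exactly 1). Parameter values without an
external anchor (noise sd, AR coefficient, shift sd, coupling strength)
were set once to give realistic count magnitudes, visible circadian
structure, and moderate — not trivial — task difficulty.

One master seed drives everything; per-subject streams derive from a stable
hash of (master seed, subject index, stream), so cohorts are bit-identical
across runs and stable under reordering.

What the generator does **not** emulate: device physics (32 Hz sampling and
acceleration thresholds — counts are emitted directly), between-subject
heterogeneity in baseline level or sleep timing, weekday/weekend structure,
medication or inpatient movement restriction, missing wear time. Passing
tests therefore show that the pipeline recovers the structure it assumes,
not that real cohorts will separate this cleanly.

## Problem sizes in the tests

Signal recovery runs at the spec-level conditions (40 subjects, full
19,299 minutes, patient ratio 0.5). Calibration and invariance properties
run on reduced designs chosen as the smallest that still exercise the
property: null calibration at 12 subjects × 960 minutes with B = 19
permutations and 30 boosting rounds over 50 seeds; effect-size monotonicity
at 40 subjects × 2,880 minutes. The full 55-subject reference design runs
in `scripts/acceptance.py`.

## Known limitations

- The periodogram is raw (no tapering/averaging), so individual bins are
  noisy; the boosted trees, not the spectral estimator, do the smoothing.
- The GCV smoothing spline can flatten genuine sharp ACF structure at very
  short series lengths; features are intended for series of several days.
- With tens of subjects and ~10⁴ features, LOOCV point metrics have large
  sampling variance; the permutation test, not the point estimate, carries
  the inferential weight.
- Regression is restricted to subjects carrying outcome scores (patients).
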