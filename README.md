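# actibiomark

Digital biomarkers of mood disorder from minute-level wrist actigraphy.

Clinical assessment of major depressive and bipolar disorder is
resource-intensive. Passive movement data from a wrist-worn actigraph —
summarized as one non-negative activity count per minute — carries enough
structure (overall activity level, circadian rhythm, sleep gating,
short-range persistence) to support two prediction tasks:

1. **Diagnosis**: classify each subject as *patient* (mood disorder) or
   *control* from actigraphy features alone.
2. **Symptom change**: predict each patient's pre/post change in the
   Montgomery–Åsberg Depression Rating Scale (MADRS) over the ~2-week
   recording.

`actibiomark` implements the full analysis as a reusable, tested pipeline
for biostatisticians and digital-phenotyping researchers, plus a synthetic
cohort generator so every stage can be exercised and calibrated without any
external recording.

## Method

Every recording is truncated to the cohort-wide minimum length *N* (for the
reference design, *N* = 19,299 minutes), then summarized into a fixed-order
feature vector with four families:

| family | count at *N* = 19,299 | content |
|---|---|---|
| `dist.*` | 106 | min, max, mean, median, mode, skewness, excess kurtosis, 1st–99th percentiles |
| `var.*` | 3 | RMSSD at lags 1 and 2 min, sample SD: RMSSD_k = √(mean_t (x_{t+k} − x_t)²) |
| `ar.*` | 100 | sample autocorrelation at lags 1–100 min, smoothed over the lag axis by a GCV-tuned cubic smoothing spline |
| `spec.*` | 9,720 | raw periodogram I(f_k) = \|DFT(x − x̄)_k\|²/N on the grid zero-padded to the next 5-smooth length (19,440), k = 1…9,720 |

for a total of 9,929 features. All features are functions of relative time
(lag, frequency), never absolute study time, so they generalize across
recordings.

Prediction uses gradient-boosted trees (xgboost; shallow trees, shrinkage,
L2 penalty, row subsampling) under leave-one-subject-out cross-validation:
subject *i* is predicted by a model fit on the other *n* − 1 subjects.
Classification is scored by accuracy, sensitivity, specificity, Cohen's
kappa, and an exact binomial test against the no-information rate;
regression (patients only) by Pearson *r* between predicted and actual MADRS
change with the *t*-transform p-value. Permutation tests that re-run the
entire cross-validated pipeline on shuffled outcomes give empirical
significance, p = (1 + #{null ≥ observed}) / (B + 1).

## Worked example

```python
import numpy as np
from actibiomark import (SynthConfig, ModelConfig, generate_cohort,
                         build_matrix, loocv_predict, classification_metrics,
                         regression_metrics)

cfg = SynthConfig(n_patients=20, n_controls=20, n_minutes=19_299, seed=1,
                  patient_mean_ratio=0.5)
matrix = build_matrix(generate_cohort(cfg))
print(matrix.X.shape)

preds = loocv_predict(matrix, ModelConfig(task="classify", seed=1))
cm, m = classification_metrics(preds, matrix.labels)
print(f"accuracy={m.accuracy:.3f} kappa={m.kappa:.2f}")

change = loocv_predict(matrix, ModelConfig(task="regress", seed=1))
reg = regression_metrics(change, matrix.outcomes[np.isfinite(matrix.outcomes)])
print(f"r={reg.r:.3f} p={reg.pvalue:.4f}")
```

prints

```
(40, 9929)
accuracy=0.975 kappa=0.95
r=0.573 p=0.0083
```

40 subjects × 9,929 features; with a strong group effect (patients at 60%
of control activity — here attenuated further to 50%) the classifier
recovers the groups almost perfectly (kappa 0.95), and the predicted MADRS
change correlates r ≈ 0.57 with the simulated truth across the 20 patients.

The same pipeline runs from the shell:

```bash
acti-biomark simulate --out cohort/ --seed 1
acti-biomark extract --cohort cohort/ --out features.tsv
acti-biomark classify --features features.tsv --out metrics.json
acti-biomark regress  --features features.tsv --out change.json
acti-biomark permtest --features features.tsv --b 99 --out perm.json
```

or end-to-end from one YAML via `acti-biomark run --config run.yaml`.
To analyze a real cohort instead, point `extract` (or the `input_dir` key of
the run config) at a directory holding `condition/` and `control/`
subject CSVs (`timestamp,date,activity` at one-minute spacing) plus a
`scores.csv` with `number`, `afftype`, `madrs1`, `madrs2` columns.

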