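"""Leave-one-subject-out boosted-tree prediction and outcome statistics.

Both tasks — classifying diagnostic group and regressing the pre/post MADRS
change of the patients — use gradient-boosted trees (xgboost) evaluated by
leave-one-out cross-validation: each subject is predicted by a model trained
on all remaining subjects, so no subject ever contributes to its own
prediction.  Significance is assessed two ways: an exact binomial test of
accuracy against the no-information rate, and label-permutation tests that
re-run the entire cross-validated pipeline under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from xgboost import XGBClassifier, XGBRegressor

from .core import GROUP_CONTROL, GROUP_PATIENT
from .features import FeatureMatrix

STATISTICS = ("kappa", "accuracy", "pearson_r")


@dataclass
class ModelConfig:
    """Boosting hyperparameters, kept deliberately conservative for the
    small-n / high-p regime: shallow trees, shrinkage, L2 penalty, row
    subsampling."""

    task: str = "classify"            # classify | regress
    rounds: int = 200
    max_depth: int = 3
    learning_rate: float = 0.1
    l2_penalty: float = 1.0
    subsample: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("classify", "regress"):
            raise ValueError("task must be 'classify' or 'regress'")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 < self.subsample <= 1):
            raise ValueError("subsample must be in (0, 1]")

    def _xgb_params(self, fold_seed: int) -> dict:
        return dict(n_estimators=self.rounds, max_depth=self.max_depth,
                    learning_rate=self.learning_rate, reg_lambda=self.l2_penalty,
                    subsample=self.subsample, tree_method="hist",
                    n_jobs=1, random_state=fold_seed)


@dataclass
class ConfusionMatrix:
    """2x2 counts with a designated positive class (default: control)."""

    tp: int
    fn: int
    fp: int
    tn: int
    positive_class: str = GROUP_CONTROL

    def __post_init__(self) -> None:
        for c in (self.tp, self.fn, self.fp, self.tn):
            if c < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class ClassificationMetrics:
    accuracy: float
    kappa: float
    sensitivity: float
    specificity: float
    nir: float
    nir_pvalue: float


@dataclass
class RegressionMetrics:
    r: float
    pvalue: float
    n: int
    predicted_z: np.ndarray
    observed_z: np.ndarray


@dataclass
class PermutationResult:
    observed: float
    null_draws: np.ndarray
    b: int
    p_empirical: float
    seed: int


# ---------------------------------------------------------------------------
# LOOCV prediction


def _check_finite(X: np.ndarray) -> None:
    if np.any(~np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")


def loocv_predict(matrix: FeatureMatrix, config: ModelConfig,
                  labels: Optional[np.ndarray] = None,
                  outcomes: Optional[np.ndarray] = None) -> np.ndarray:
    """Predict every subject from a model fit on the other n-1 subjects.

    For ``classify`` returns predicted group labels for all subjects; for
    ``regress`` returns predicted change scores for the subjects that carry
    an outcome (the patients), in matrix order.  ``labels``/``outcomes``
    override the matrix columns (used by the permutation test).  Each fold
    refits a fresh model seeded ``config.seed + fold index``; a probability
    of exactly 0.5 is resolved to the positive (control) class.
    """
    X_all = matrix.X.to_numpy(dtype=float)
    _check_finite(X_all)

    if config.task == "classify":
        y = np.asarray(matrix.labels if labels is None else labels)
        n = len(y)
        if n < 3:
            raise ValueError("LOOCV needs at least 3 subjects")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        classes = np.array(sorted(np.unique(y)))  # ('control', 'patient')
        y_code = np.searchsorted(classes, y)
        pos_code = int(np.searchsorted(classes, GROUP_CONTROL))
        preds = np.empty(n, dtype=object)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            if len(np.unique(y_code[mask])) < 2:
                raise ValueError(f"training fold {i} contains a single class")
            model = XGBClassifier(**config._xgb_params(config.seed + i))
            model.fit(X_all[mask], y_code[mask])
            p_pos = float(model.predict_proba(X_all[i:i + 1])[0, pos_code])
            preds[i] = classes[pos_code] if p_pos >= 0.5 else \
                classes[1 - pos_code]
        return preds

    out = np.asarray(matrix.outcomes if outcomes is None else outcomes,
                     dtype=float)
    has = np.isfinite(out)
    if not has.any():
        raise ValueError("regression task requires outcomes")
    idx = np.flatnonzero(has)
    if idx.size < 3:
        raise ValueError("LOOCV needs at least 3 subjects with outcomes")
    X = X_all[idx]
    y = out[idx]
    preds = np.empty(idx.size)
    for j in range(idx.size):
        mask = np.ones(idx.size, dtype=bool)
        mask[j] = False
        model = XGBRegressor(**config._xgb_params(config.seed + j))
        model.fit(X[mask], y[mask])
        preds[j] = float(model.predict(X[j:j + 1])[0])
    return preds


# ---------------------------------------------------------------------------
# outcome metrics


def confusion_from_predictions(predictions: Sequence[str], labels: Sequence[str],
                               positive_class: str = GROUP_CONTROL) -> ConfusionMatrix:
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    known = set(np.unique(labels)) | set(np.unique(predictions))
    allowed = {GROUP_CONTROL, GROUP_PATIENT}
    if not known <= allowed:
        raise ValueError(f"unknown label(s): {sorted(known - allowed)}")
    if positive_class not in allowed:
        raise ValueError(f"unknown positive class {positive_class!r}")
    pos_true = labels == positive_class
    pos_pred = predictions == positive_class
    return ConfusionMatrix(
        tp=int(np.sum(pos_pred & pos_true)),
        fn=int(np.sum(~pos_pred & pos_true)),
        fp=int(np.sum(pos_pred & ~pos_true)),
        tn=int(np.sum(~pos_pred & ~pos_true)),
        positive_class=positive_class,
    )


def metrics_from_confusion(cm: ConfusionMatrix) -> ClassificationMetrics:
    """Accuracy, Cohen's kappa, sensitivity, specificity, no-information rate
    and the exact one-sided binomial p of accuracy vs the NIR."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    correct = cm.tp + cm.tn
    accuracy = correct / n
    # chance agreement from row/column marginals
    p_pos = (cm.tp + cm.fn) / n          # true positive-class rate
    q_pos = (cm.tp + cm.fp) / n          # predicted positive-class rate
    p_e = p_pos * q_pos + (1 - p_pos) * (1 - q_pos)
    kappa = 0.0 if p_e == 1 else (accuracy - p_e) / (1 - p_e)
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else float("nan")
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else float("nan")
    nir = max(p_pos, 1 - p_pos)
    nir_p = float(stats.binomtest(correct, n, nir, alternative="greater").pvalue)
    return ClassificationMetrics(accuracy=accuracy, kappa=kappa,
                                 sensitivity=sens, specificity=spec,
                                 nir=nir, nir_pvalue=nir_p)


def classification_metrics(predictions: Sequence[str], labels: Sequence[str],
                           positive_class: str = GROUP_CONTROL,
                           ) -> Tuple[ConfusionMatrix, ClassificationMetrics]:
    cm = confusion_from_predictions(predictions, labels, positive_class)
    return cm, metrics_from_confusion(cm)


def regression_metrics(predicted_change: Sequence[float],
                       observed_change: Sequence[float]) -> RegressionMetrics:
    """Pearson r between predicted and observed change with the two-sided
    t-transform p (n-2 df), plus both vectors as sample z-scores for plots."""
    pred = np.asarray(predicted_change, dtype=float)
    obs = np.asarray(observed_change, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("predicted and observed must be 1-D of equal length")
    if pred.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.any(~np.isfinite(pred)) or np.any(~np.isfinite(obs)):
        raise ValueError("non-finite values in change scores")
    if np.std(pred, ddof=1) == 0 or np.std(obs, ddof=1) == 0:
        raise ValueError("correlation undefined: zero variance")
    res = stats.pearsonr(pred, obs)
    z = lambda v: (v - v.mean()) / v.std(ddof=1)
    return RegressionMetrics(r=float(res.statistic), pvalue=float(res.pvalue),
                             n=pred.size, predicted_z=z(pred), observed_z=z(obs))


def standardize_change(scores_pre: Sequence[float],
                       scores_post: Sequence[float]) -> np.ndarray:
    """Sample-standardized pre minus post difference scores (z-scores)."""
    pre = np.asarray(scores_pre, dtype=float)
    post = np.asarray(scores_post, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("need >= 2 aligned pre/post pairs")
    diff = pre - post
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in difference scores")
    return (diff - diff.mean()) / sd


# ---------------------------------------------------------------------------
# permutation significance


def _statistic_value(matrix: FeatureMatrix, config: ModelConfig, statistic: str,
                     labels: Optional[np.ndarray] = None,
                     outcomes: Optional[np.ndarray] = None) -> float:
    preds = loocv_predict(matrix, config, labels=labels, outcomes=outcomes)
    if statistic in ("kappa", "accuracy"):
        y = matrix.labels if labels is None else labels
        _, m = classification_metrics(preds, y)
        return m.kappa if statistic == "kappa" else m.accuracy
    out = np.asarray(matrix.outcomes if outcomes is None else outcomes, dtype=float)
    return regression_metrics(preds, out[np.isfinite(out)]).r


def permutation_test(matrix: FeatureMatrix, config: ModelConfig, statistic: str,
                     b: int, seed: int) -> PermutationResult:
    """Empirical significance of a LOOCV statistic under outcome permutation.

    The group labels (classification) or change scores (regression) are
    shuffled ``b`` times and the *full* LOOCV-plus-metric pipeline is re-run
    on each shuffle, so the null distribution carries the same optimistic
    bias, if any, as the observed statistic.
    p = (1 + #{null >= observed}) / (b + 1).
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if statistic == "pearson_r" and config.task != "regress":
        raise ValueError("pearson_r requires a regression task")
    if statistic in ("kappa", "accuracy") and config.task != "classify":
        raise ValueError(f"{statistic} requires a classification task")

    observed = _statistic_value(matrix, config, statistic)
    rng = np.random.default_rng(seed)
    draws = np.empty(b)
    for k in range(b):
        if config.task == "classify":
            perm = rng.permutation(matrix.labels)
            draws[k] = _statistic_value(matrix, config, statistic, labels=perm)
        else:
            out = np.asarray(matrix.outcomes, dtype=float)
            has = np.isfinite(out)
            shuffled = out.copy()
            shuffled[has] = rng.permutation(out[has])
            draws[k] = _statistic_value(matrix, config, statistic, outcomes=shuffled)
    p = (1 + int(np.sum(draws >= observed))) / (b + 1)
    return PermutationResult(observed=float(observed), null_draws=draws,
                             b=b, p_empirical=float(p), seed=seed)
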