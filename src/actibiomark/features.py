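"""Digital-biomarker feature extraction.

Four families are computed from a single minute-level activity series and
concatenated in a fixed order with stable names:

1. distribution (106): min, max, mean, median, mode, skewness, kurtosis and
   the 1st-99th percentiles of the activity intensity distribution;
2. variability (3): RMSSD at lags 1 and 2 minutes plus the sample standard
   deviation — indices of sharp short-interval shifts in movement;
3. autoregressive (100): the sample autocorrelation at lags 1-100 minutes,
   smoothed across the lag axis with a GCV-tuned cubic smoothing spline, so
   the features describe the consistency of movement over a smooth
   continuum of lags;
4. spectral (floor(padlen(N)/2)): the raw periodogram at the Fourier
   frequencies of the series zero-padded to the next 5-smooth length.

All features are functions of relative time only (lag, frequency), never of
absolute clock time, so they transfer across recordings with different start
times and lengths.  For a 19,299-minute series the vector has
106 + 3 + 100 + 9,720 = 9,929 entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline
from statsmodels.tsa.stattools import acf as _acf

from .core import GROUP_PATIENT, ActigraphySeries, Cohort

MAX_AR_LAG = 100
MIN_SERIES_LENGTH = 201  # at least two observations per autocorrelation lag


def padlen(n: int) -> int:
    """Smallest 5-smooth integer (prime factors <= 5) that is >= n.

    A power of two always lies in [n, 2n), so candidates 3^b * 5^c >= 2n
    can never win and the enumeration is tiny.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    best = None
    p5 = 1
    while p5 < 2 * n:
        p35 = p5
        while p35 < 2 * n:
            m = p35
            while m < n:
                m *= 2
            if best is None or m < best:
                best = m
            p35 *= 3
        p5 *= 5
    return int(best)


# ---------------------------------------------------------------------------
# feature families


def distribution_features(values: np.ndarray) -> Dict[str, float]:
    """106 summaries of the activity intensity distribution.

    Quantiles use linear interpolation between order statistics; the mode is
    the most frequent value after rounding to the nearest integer (ties ->
    smallest); skewness and excess kurtosis are defined as 0 for
    zero-variance input so the vector is always complete.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("distribution features require length >= 2")

    rounded = np.rint(x)
    uniq, counts = np.unique(rounded, return_counts=True)
    mode = float(uniq[np.argmax(counts)])  # np.unique sorts: first max = smallest

    if np.var(x) == 0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))

    out = {
        "dist.min": float(np.min(x)),
        "dist.max": float(np.max(x)),
        "dist.mean": float(np.mean(x)),
        "dist.median": float(np.median(x)),
        "dist.mode": mode,
        "dist.skewness": skew,
        "dist.kurtosis": kurt,
    }
    qs = np.quantile(x, np.arange(1, 100) / 100.0, method="linear")
    for k, q in zip(range(1, 100), qs):
        out[f"dist.q{k}"] = float(q)
    return out


def variability_features(values: np.ndarray) -> Dict[str, float]:
    """RMSSD at lags 1 and 2 minutes plus the sample standard deviation.

    RMSSD_k = sqrt(mean_t (x_{t+k} - x_t)^2).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("variability features require length >= 3")
    rmssd1 = float(np.sqrt(np.mean(np.diff(x, 1) ** 2)))
    rmssd2 = float(np.sqrt(np.mean((x[2:] - x[:-2]) ** 2)))
    return {
        "var.rmssd_lag1": rmssd1,
        "var.rmssd_lag2": rmssd2,
        "var.sd": float(np.std(x, ddof=1)),
    }


def autoregressive_features(values: np.ndarray,
                            max_lag: int = MAX_AR_LAG) -> Dict[str, float]:
    """Smoothed sample autocorrelation at integer lags 1..max_lag.

    The raw ACF (mean-centered, normalized by the lag-0 sum of squares) is
    smoothed across the lag axis with a cubic smoothing spline whose penalty
    is chosen by generalized cross-validation, then read back at the integer
    lags.  A zero-variance series yields all zeros.  Smoothed values are
    clipped to [-1.05, 1.05]; the raw ACF lies in [-1, 1] so the spline may
    overshoot only marginally.
    """
    x = np.asarray(values, dtype=float)
    if x.size < max_lag + 1:
        raise ValueError(f"autoregressive features require length >= {max_lag + 1}")
    if np.var(x) == 0:
        return {f"ar.lag{k}": 0.0 for k in range(1, max_lag + 1)}

    lags = np.arange(0, max_lag + 1, dtype=float)
    raw = _acf(x, nlags=max_lag, fft=True, adjusted=False)
    spline = make_smoothing_spline(lags, raw)  # lam=None -> GCV
    smoothed = np.clip(spline(lags[1:]), -1.05, 1.05)
    return {f"ar.lag{k}": float(v) for k, v in zip(range(1, max_lag + 1), smoothed)}


def spectral_features(values: np.ndarray) -> Dict[str, float]:
    """Raw periodogram of the mean-removed series on a 5-smooth padded grid.

    The series is zero-padded to ``padlen(N)`` and I(f_k) = |DFT(x)_k|^2 / N
    is reported at the positive Fourier frequencies k = 1..floor(padlen/2)
    (Nyquist included when the padded length is even; f = 0 excluded since
    the mean is removed).  Names encode the frequency index.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("spectral features require length >= 2")
    n = x.size
    p = padlen(n)
    spec = np.abs(np.fft.rfft(x - x.mean(), n=p)) ** 2 / n
    half = p // 2
    return {f"spec.f{k:06d}": float(spec[k]) for k in range(1, half + 1)}


# ---------------------------------------------------------------------------
# assembled vector and matrix


@dataclass
class FeatureVector:
    """Ordered, stably named biomarker values for one subject."""

    names: List[str]
    values: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names and values must align")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")

    def __len__(self) -> int:
        return int(self.values.size)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def expected_feature_count(n: int) -> int:
    """Vector length for a series of n minutes: 209 + floor(padlen(n)/2)."""
    return 106 + 3 + MAX_AR_LAG + padlen(n) // 2


def extract_features(series: ActigraphySeries) -> FeatureVector:
    """Concatenate the four families in fixed order for one subject.

    The result depends only on the activity values (relative time), never on
    ``start_time``; a 19,299-minute series yields exactly 9,929 features.
    """
    x = series.values
    if x.size < MIN_SERIES_LENGTH:
        raise ValueError(f"series must have >= {MIN_SERIES_LENGTH} minutes, got {x.size}")
    feats: Dict[str, float] = {}
    feats.update(distribution_features(x))
    feats.update(variability_features(x))
    feats.update(autoregressive_features(x))
    feats.update(spectral_features(x))
    return FeatureVector(names=list(feats.keys()),
                         values=np.array(list(feats.values())),
                         source_length=int(x.size))


@dataclass
class FeatureMatrix:
    """One feature row per subject, with group labels and optional outcomes."""

    subjects: List[str]
    X: pd.DataFrame              # rows = subjects, columns = feature names
    labels: np.ndarray           # group per subject
    outcomes: Optional[np.ndarray] = None  # MADRS change; NaN for controls
    source_length: Optional[int] = None

    def __post_init__(self) -> None:
        if list(self.X.index) != list(self.subjects):
            raise ValueError("matrix rows must follow subject order")
        if len(self.labels) != len(self.subjects):
            raise ValueError("one label per subject required")
        if self.outcomes is not None and len(self.outcomes) != len(self.subjects):
            raise ValueError("one outcome per subject required")

    def __len__(self) -> int:
        return len(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        """Flat table: subject_id, group, madrs_change, then the features."""
        frame = self.X.copy()
        frame.insert(0, "subject_id", self.subjects)
        frame.insert(1, "group", self.labels)
        change = self.outcomes if self.outcomes is not None else np.nan
        frame.insert(2, "madrs_change", change)
        return frame.reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   source_length: Optional[int] = None) -> "FeatureMatrix":
        meta = ["subject_id", "group", "madrs_change"]
        missing = [c for c in meta if c not in frame.columns]
        if missing:
            raise ValueError(f"feature table missing column(s) {missing}")
        subjects = frame["subject_id"].astype(str).tolist()
        X = frame.drop(columns=meta)
        X.index = subjects
        return cls(subjects=subjects, X=X,
                   labels=frame["group"].to_numpy(),
                   outcomes=frame["madrs_change"].to_numpy(dtype=float),
                   source_length=source_length)


def feature_registry_markdown(source_length: int) -> str:
    """Markdown registry of the stable feature names for a given series length."""
    p = padlen(source_length)
    lines = [
        "# Feature-name registry",
        "",
        f"Series length {source_length} minutes; padded spectral grid {p}; "
        f"{expected_feature_count(source_length)} features total.",
        "",
        "| prefix | count | meaning |",
        "|---|---|---|",
        "| `dist.min` … `dist.kurtosis` | 7 | min, max, mean, median, mode "
        "(integer-rounded, ties -> smallest), skewness, excess kurtosis |",
        "| `dist.q1` … `dist.q99` | 99 | percentiles, linear interpolation |",
        "| `var.rmssd_lag1`, `var.rmssd_lag2`, `var.sd` | 3 | RMSSD at lags "
        "1-2 min; sample SD |",
        f"| `ar.lag1` … `ar.lag{MAX_AR_LAG}` | {MAX_AR_LAG} | GCV-spline-"
        "smoothed sample autocorrelation at integer lags (minutes) |",
        f"| `spec.f000001` … `spec.f{p // 2:06d}` | {p // 2} | periodogram "
        f"|DFT(x - mean)_k|^2/N at frequency k/{p} cycles/min |",
        "",
    ]
    return "\n".join(lines)


def build_matrix(cohort: Cohort) -> FeatureMatrix:
    """Extract features for every subject of a length-normalized cohort."""
    if cohort.common_length is None:
        raise ValueError("cohort must be truncated to a common length first")
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    subjects, rows, labels, outcomes = [], [], [], []
    names: Optional[List[str]] = None
    for rec in cohort:
        vec = extract_features(rec.series)
        if names is None:
            names = vec.names
        subjects.append(rec.subject_id)
        rows.append(vec.values)
        labels.append(rec.group)
        outcomes.append(rec.madrs_change if rec.group == GROUP_PATIENT else np.nan)
    X = pd.DataFrame(np.vstack(rows), index=subjects, columns=names)
    return FeatureMatrix(subjects=subjects, X=X,
                         labels=np.array(labels),
                         outcomes=np.array(outcomes, dtype=float),
                         source_length=cohort.common_length)
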