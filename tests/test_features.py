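"""Feature-family oracles: hand computations, Monte-Carlo nulls, the known
AR(1) autocorrelation, the Parseval identity, and the feature-count formula."""

import numpy as np
import pytest
from scipy.signal import lfilter

from actibiomark import (SynthConfig, build_matrix, expected_feature_count,
                         extract_features, generate_cohort, padlen)
from actibiomark.features import (autoregressive_features,
                                  distribution_features, spectral_features,
                                  variability_features)
from conftest import make_series


def smooth_5_brute(n):
    """Oracle: smallest integer >= n with no prime factor above 5."""
    m = n
    while True:
        k = m
        for p in (2, 3, 5):
            while k % p == 0:
                k //= p
        if k == 1:
            return m
        m += 1


@pytest.mark.parametrize("n", [1, 2, 7, 11, 97, 1440, 1441, 2500, 19_299])
def test_padlen_matches_bruteforce(n):
    assert padlen(n) == smooth_5_brute(n)


def test_feature_count_formula():
    assert padlen(19_299) == 19_440
    assert expected_feature_count(19_299) == 9_929
    assert expected_feature_count(1_440) == 929  # 1440 = 2^5 * 3^2 * 5


# ---------------------------------------------------------------------------
# distribution family


def test_distribution_constant_series():
    f = distribution_features(np.full(50, 7.0))
    for key in ("dist.min", "dist.max", "dist.mean", "dist.median",
                "dist.mode", "dist.q1", "dist.q50", "dist.q99"):
        assert f[key] == 7.0
    assert f["dist.skewness"] == 0.0 and f["dist.kurtosis"] == 0.0


def test_distribution_on_uniform_grid():
    f = distribution_features(np.arange(101, dtype=float))
    assert f["dist.mean"] == f["dist.median"] == 50.0
    assert f["dist.q17"] == 17.0 and f["dist.q99"] == 99.0
    assert f["dist.mode"] == 0.0  # all counts tie; smallest wins


def test_distribution_hand_example():
    f = distribution_features(np.array([1.0, 1.0, 2.0, 9.0]))
    assert f["dist.mode"] == 1.0
    assert f["dist.max"] == 9.0
    assert f["dist.mean"] == pytest.approx(3.25)


def test_distribution_needs_two_points():
    with pytest.raises(ValueError):
        distribution_features(np.array([3.0]))


# ---------------------------------------------------------------------------
# variability family


def test_variability_constant_is_zero():
    f = variability_features(np.full(10, 4.0))
    assert (f["var.rmssd_lag1"], f["var.rmssd_lag2"], f["var.sd"]) == (0, 0, 0)


def test_variability_hand_example():
    f = variability_features(np.array([0.0, 3.0, 1.0, 5.0]))
    assert f["var.rmssd_lag1"] == pytest.approx(np.sqrt(29 / 3))
    assert f["var.rmssd_lag2"] == pytest.approx(np.sqrt(5 / 2))
    assert f["var.sd"] == pytest.approx(np.std([0, 3, 1, 5], ddof=1))


def test_variability_alternating_series():
    a, b = 2.0, 9.0
    x = np.tile([a, b], 10)
    f = variability_features(x)
    assert f["var.rmssd_lag1"] == pytest.approx(abs(a - b))
    assert f["var.rmssd_lag2"] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# autoregressive family


def test_acf_features_null_envelope():
    """Independent noise: all 100 smoothed lags inside the ~2/sqrt(n) band."""
    rng = np.random.default_rng(12)
    f = autoregressive_features(rng.normal(size=19_299))
    assert max(abs(v) for v in f.values()) < 0.05


def test_acf_features_recover_ar1_decay():
    """AR(1) with coefficient 0.8 has ACF 0.8^k; smoothing must preserve it."""
    rng = np.random.default_rng(34)
    eps = rng.normal(size=19_299)
    x = lfilter([1.0], [1.0, -0.8], eps)
    f = autoregressive_features(x)
    for k in range(1, 11):
        assert abs(f[f"ar.lag{k}"] - 0.8 ** k) < 0.05


def test_acf_features_zero_variance_and_bounds():
    f = autoregressive_features(np.full(300, 5.0))
    assert all(v == 0.0 for v in f.values())
    rng = np.random.default_rng(56)
    f = autoregressive_features(np.abs(rng.normal(size=500)))
    assert all(-1.05 <= v <= 1.05 for v in f.values())


def test_acf_features_require_enough_data():
    with pytest.raises(ValueError):
        autoregressive_features(np.arange(50, dtype=float))


# ---------------------------------------------------------------------------
# spectral family


def test_spectral_concentration_at_fourier_frequency():
    t = np.arange(1440, dtype=float)
    f = spectral_features(np.cos(2 * np.pi * 3 * t / 1440))
    vals = np.array(list(f.values()))
    peak = int(np.argmax(vals)) + 1  # names are 1-based frequency indices
    assert peak == 3
    assert vals[peak - 1] >= 100 * np.partition(vals, -2)[-2]


@pytest.mark.parametrize("n", [300, 1440, 19_299])
def test_parseval_identity(n):
    """Weighted periodogram mass equals padlen/n times the centered energy."""
    rng = np.random.default_rng(n)
    x = np.abs(rng.normal(200, 60, size=n))
    vals = np.array(list(spectral_features(x).values()))
    p = padlen(n)
    weights = np.full(vals.size, 2.0)
    if p % 2 == 0:
        weights[-1] = 1.0  # Nyquist bin is its own conjugate
    lhs = float(weights @ vals)
    rhs = (p / n) * float(((x - x.mean()) ** 2).sum())
    assert lhs == pytest.approx(rhs, rel=1e-6)


def test_spectral_count_is_half_padlen():
    assert len(spectral_features(np.arange(1441, dtype=float))) == padlen(1441) // 2


# ---------------------------------------------------------------------------
# assembled vector


def test_full_length_vector_has_9929_features():
    cfg = SynthConfig(n_minutes=19_299, seed=8)
    from actibiomark import generate_subject
    vec = extract_features(generate_subject(cfg, "control", 0).series)
    assert len(vec) == 9_929
    assert len(set(vec.names)) == 9_929
    assert np.all(np.isfinite(vec.values))


def test_vector_ignores_start_time():
    values = np.abs(np.random.default_rng(3).normal(150, 40, size=1440))
    a = extract_features(make_series(values, start="2003-05-07 12:00:00"))
    b = extract_features(make_series(values, start="2004-11-30 03:17:00"))
    assert a.names == b.names
    np.testing.assert_array_equal(a.values, b.values)


def test_vector_length_formula_at_1440():
    values = np.abs(np.random.default_rng(4).normal(150, 40, size=1440))
    assert len(extract_features(make_series(values))) == 929


def test_scale_equivariance():
    """Scaling the series by c scales location/spread features by c, the
    periodogram by c^2, and leaves shape/autocorrelation untouched."""
    rng = np.random.default_rng(5)
    values = rng.integers(0, 400, size=1440).astype(float)
    c = 3.0
    a = extract_features(make_series(values)).as_series()
    b = extract_features(make_series(c * values)).as_series()
    for name in ("dist.min", "dist.max", "dist.mean", "dist.median",
                 "dist.mode", "dist.q25", "dist.q75", "var.sd",
                 "var.rmssd_lag1", "var.rmssd_lag2"):
        assert b[name] == pytest.approx(c * a[name], rel=1e-9)
    for name in ("dist.skewness", "dist.kurtosis"):
        assert b[name] == pytest.approx(a[name], rel=1e-9)
    ar_cols = [n for n in a.index if n.startswith("ar.")]
    np.testing.assert_allclose(b[ar_cols], a[ar_cols], atol=1e-9)
    spec_cols = [n for n in a.index if n.startswith("spec.")]
    np.testing.assert_allclose(b[spec_cols], c**2 * a[spec_cols], rtol=1e-9)


def test_zero_variance_series_yields_complete_vector():
    vec = extract_features(make_series(np.full(1440, 9.0)))
    assert np.all(np.isfinite(vec.values))
    assert len(vec) == 929


# ---------------------------------------------------------------------------
# matrix assembly


def test_build_matrix_requires_truncated_cohort():
    cohort = generate_cohort(SynthConfig(n_patients=1, n_controls=2,
                                         n_minutes=300, seed=9))
    cohort.common_length = None
    with pytest.raises(ValueError, match="common length"):
        build_matrix(cohort)


def test_build_matrix_rows_match_extractor():
    cfg = SynthConfig(n_patients=2, n_controls=2, n_minutes=300, seed=10)
    cohort = generate_cohort(cfg)
    matrix = build_matrix(cohort)
    assert matrix.X.shape == (4, expected_feature_count(300))
    for rec in cohort:
        np.testing.assert_array_equal(
            matrix.X.loc[rec.subject_id].to_numpy(),
            extract_features(rec.series).values)
    # outcomes: patients carry pre - post, controls NaN
    for rec, out in zip(cohort, matrix.outcomes):
        if rec.group == "patient":
            assert out == pytest.approx(rec.madrs_pre - rec.madrs_post)
        else:
            assert np.isnan(out)


def test_matrix_frame_roundtrip(small_matrix):
    from actibiomark import FeatureMatrix
    back = FeatureMatrix.from_frame(small_matrix.to_frame())
    assert back.subjects == small_matrix.subjects
    np.testing.assert_array_equal(back.labels, small_matrix.labels)
    np.testing.assert_allclose(back.X.to_numpy(), small_matrix.X.to_numpy())
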