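"""PACF, lagged correlations and continuous preprocessing."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import dyadtheta as dt
from dyadtheta.behavior import binary_attention_series
from dyadtheta.events import LookEvent
from dyadtheta.lagged import (
    _rebin_binary,
    group_average,
    lag_correlations,
    pacf_binary,
    preprocess_continuous,
    shuffled_duration_baseline,
    xcorr_binary,
    xcorr_continuous,
)
from dyadtheta.series import BehaviourSeries


def _brute_force_pacf(x: np.ndarray, k: int) -> float:
    """Independent oracle: normal-equations OLS of x(t) on x(t-1..k)."""
    n = x.size
    cols = [np.ones(n - k)] + [x[k - j: n - j] for j in range(1, k + 1)]
    design = np.column_stack(cols)
    resp = x[k:]
    cases = np.isfinite(design).all(axis=1) & np.isfinite(resp)
    X, y = design[cases], resp[cases]
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[-1]


@pytest.fixture(scope="module")
def binary_series():
    cfg = dt.SyntheticConfig(seed=31, session_length=300.0)
    sessions, _ = dt.simulate_study(cfg, 1)
    return binary_attention_series(sessions[0].infant_events, 300.0)


class TestPACF:
    def test_matches_normal_equations_oracle(self, binary_series):
        lags, pacf = pacf_binary(binary_series, 0.5, 10.0)
        x = _rebin_binary(binary_series, 0.5)
        for k in (1, 2, 5, 10, 20):
            assert pacf[k - 1] == pytest.approx(_brute_force_pacf(x, k), abs=1e-10)

    def test_lag1_equals_regression_autocorrelation(self, binary_series):
        lags, pacf = pacf_binary(binary_series, 0.5, 10.0)
        x = _rebin_binary(binary_series, 0.5)
        a, b = x[:-1], x[1:]
        m = np.isfinite(a) & np.isfinite(b)
        a, b = a[m], b[m]
        slope = np.cov(a, b, ddof=1)[0, 1] / np.var(a, ddof=1)
        # OLS slope of x(t) on x(t-1) with intercept
        assert pacf[0] == pytest.approx(slope, abs=1e-6)

    def test_recovers_population_pacf_of_ar2(self):
        # AR(2): population PACF is (phi1/(1-phi2), phi2, 0, 0, ...)
        rng = np.random.default_rng(5)
        phi1, phi2 = 0.5, 0.25
        n = 200_000
        x = np.zeros(n)
        eps = rng.standard_normal(n)
        for t in range(2, n):
            x[t] = phi1 * x[t - 1] + phi2 * x[t - 2] + eps[t]
        series = BehaviourSeries(x, rate=50.0)
        lags, pacf = pacf_binary(series, bin_width=0.02, max_lag=0.08)
        assert pacf[0] == pytest.approx(phi1 / (1 - phi2), abs=0.02)
        assert pacf[1] == pytest.approx(phi2, abs=0.02)
        assert abs(pacf[2]) < 0.02 and abs(pacf[3]) < 0.02

    def test_insufficient_cases_give_missing(self):
        series = BehaviourSeries(np.array([0.0, 1.0] * 20), rate=50.0)
        lags, pacf = pacf_binary(series, 0.02, 0.1, min_cases=100)
        assert np.all(np.isnan(pacf))

    def test_rebin_majority_and_tie_rule(self):
        v = np.array([0, 0, 1, 1, 1, 1, 0, 1, 0, 0], dtype=float)
        series = BehaviourSeries(v, rate=50.0)
        out = _rebin_binary(series, 0.1)  # bins of 5 samples
        assert out[0] == 1.0  # majority 3/5 ones
        assert out[1] == 0.0  # majority zeros

    def test_rebin_tie_takes_bin_start_value(self):
        v = np.array([1, 1, 0, 0], dtype=float)
        out = _rebin_binary(BehaviourSeries(v, rate=50.0), 0.08)
        assert out[0] == 1.0


class TestShuffledBaseline:
    def test_duration_multiset_preserved(self, rng):
        events = [
            LookEvent("infant", t, t + d, "object1")
            for t, d in zip(np.cumsum([0, 1.0, 2.0, 0.5][:-1]), [1.0, 2.0, 0.5])
        ]
        # rebuild shuffled events through the public API and compare multisets
        curves = shuffled_duration_baseline(
            events, rng, n_perm=3, bin_width=0.5, max_lag=1.0
        )
        assert curves.shape == (3, 2)

    def test_equal_durations_reproduce_observed_pacf(self, rng):
        events = [
            LookEvent("infant", float(i), float(i + 1), "object1") for i in range(60)
        ]
        series = binary_attention_series(events, 60.0)
        _, observed = pacf_binary(series, 0.5, 5.0)
        curves = shuffled_duration_baseline(
            events, rng, n_perm=5, bin_width=0.5, max_lag=5.0
        )
        for c in curves:
            np.testing.assert_allclose(c, observed, atol=1e-12)

    def test_fewer_than_two_looks_rejected(self, rng):
        events = [LookEvent("infant", 0.0, 5.0, "object1")]
        with pytest.raises(ValueError, match="two codable looks"):
            shuffled_duration_baseline(events, rng)


class TestLagCorrelations:
    def test_equals_explicitly_shifted_correlation(self, rng):
        x = rng.standard_normal(3000)
        y = 0.5 * x + rng.standard_normal(3000)
        x[rng.integers(0, 3000, 100)] = np.nan
        lag_samples = np.array([-250, -25, 0, 25, 250])
        r = lag_correlations(x, y, lag_samples)
        for k, got in zip(lag_samples, r):
            a = x[: 3000 - k] if k >= 0 else x[-k:]
            b = y[k:] if k >= 0 else y[: 3000 + k]
            m = np.isfinite(a) & np.isfinite(b)
            assert got == pytest.approx(np.corrcoef(a[m], b[m])[0, 1], abs=1e-12)

    def test_spearman_matches_scipy_on_overlap(self, rng):
        x = rng.standard_normal(500)
        y = rng.standard_normal(500)
        r = lag_correlations(x, y, np.array([10]), method="spearman", min_overlap=10)
        expected = spearmanr(x[:490], y[10:]).statistic
        assert r[0] == pytest.approx(expected, abs=1e-12)

    def test_short_overlap_is_missing(self, rng):
        x = rng.standard_normal(150)
        r = lag_correlations(x, x, np.array([60]), min_overlap=100)
        assert np.isnan(r[0])


class TestXcorr:
    def test_identity_at_lag_zero(self, binary_series):
        lags, r = xcorr_binary(binary_series, binary_series)
        assert lags[0] == 0.0
        assert r[0] == pytest.approx(1.0)

    def test_shifted_caregiver_peaks_at_shift(self, binary_series):
        shifted = BehaviourSeries(np.roll(binary_series.values, 100), rate=50.0)
        lags, r = xcorr_binary(binary_series, shifted)
        assert lags[np.nanargmax(r)] == pytest.approx(2.0)

    def test_continuous_shift_oracle(self, rng):
        x = BehaviourSeries(np.cumsum(rng.standard_normal(5000)) * 0.01 + 5, rate=50.0)
        vals = np.full(5000, np.nan)
        vals[75:] = x.values[:-75] + 0.01 * rng.standard_normal(4925)
        y = BehaviourSeries(vals, rate=50.0)
        lags, r = xcorr_continuous(x, y, max_lag=5.0)
        assert abs(lags[np.nanargmax(r)] - 1.5) <= 0.5

    def test_rate_mismatch_rejected(self, binary_series):
        other = BehaviourSeries(np.zeros(100), rate=25.0)
        with pytest.raises(ValueError, match="rates"):
            xcorr_binary(binary_series, other)


class TestPreprocessContinuous:
    def test_pure_linear_trend_gives_zero_residuals(self):
        t = np.arange(1000) / 50
        series = BehaviourSeries(np.exp(0.1 + 0.05 * t), rate=50.0)
        out = preprocess_continuous(series)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_outlier_rule_boundaries(self, rng):
        base = rng.normal(0.0, 1.0, 5000)
        q1, q3 = np.percentile(base, [25, 75])
        iqr = q3 - q1
        v = np.exp(np.concatenate([base, [q3 + 2.5 * iqr, q3 + 1.5 * iqr]]))
        out = preprocess_continuous(BehaviourSeries(v, rate=50.0))
        assert np.isnan(out.values[-2])  # beyond Q3 + 2 IQR: masked
        assert np.isfinite(out.values[-1])  # within: kept

    def test_nonpositive_values_become_missing(self):
        v = np.concatenate([np.full(100, 2.0), [-1.0, 0.0]])
        out = preprocess_continuous(BehaviourSeries(v, rate=50.0))
        assert np.isnan(out.values[-2:]).all()

    def test_quadratic_signal_selects_quadratic_fit(self, rng):
        hits = 0
        for _ in range(100):
            t = np.arange(500) / 50
            v = np.exp(1.0 + 0.3 * t - 0.03 * t**2 + 0.05 * rng.standard_normal(500))
            out = preprocess_continuous(BehaviourSeries(v, rate=50.0))
            # a linear fit leaves curvature; the quadratic residuals do not
            resid = out.values
            coef = np.polyfit(t - t.mean(), resid, 2)
            hits += abs(coef[0]) < 1e-6
        assert hits >= 95

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="usable samples"):
            preprocess_continuous(BehaviourSeries(np.full(5, 1.0), rate=50.0))


def test_group_average_matches_bruteforce(rng):
    lags = np.arange(3)
    curves = {
        "a": [rng.standard_normal(3), rng.standard_normal(3)],
        "b": [rng.standard_normal(3)],
    }
    out = group_average(curves, lags)
    manual_a = np.mean(np.vstack(curves["a"]), axis=0)
    manual = np.mean(np.vstack([manual_a, curves["b"][0]]), axis=0)
    np.testing.assert_allclose(out.group_mean, manual, atol=1e-15)
    np.testing.assert_allclose(out.per_participant["a"], manual_a, atol=1e-15)
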