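"""Performance metric, OLS tradeoff fits, ANCOVA and t-tests vs oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from thermolag.stats import (
    compare_slopes_ancova,
    fit_tradeoff,
    performance,
    summarize_replicates,
    two_sample_t,
)


class TestPerformance:
    @pytest.mark.parametrize(
        "t_ref, t_cond, expected",
        [(10.0, 10.0, 1.0), (10.0, 20.0, 0.5), (12.0, 8.0, 1.5)],
    )
    def test_ratio(self, t_ref, t_cond, expected):
        assert performance(t_ref, t_cond).performance == pytest.approx(expected)

    def test_missing_condition_time_propagates(self):
        record = performance(10.0, None, strain="A1")
        assert record.performance is None
        assert record.reason == "threshold_not_reached"

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError):
            performance(0.0, 10.0)
        with pytest.raises(ValueError):
            performance(10.0, -1.0)

    def test_monotone_in_condition_time(self):
        times = np.linspace(5.0, 50.0, 20)
        ps = [performance(10.0, t).performance for t in times]
        assert np.all(np.diff(ps) < 0)


def ols_normal_equations(x, y):
    """Independent closed-form OLS oracle (normal equations)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - intercept - slope * x
    sst = ((y - y.mean()) ** 2).sum()
    r2 = 0.0 if sst == 0 else 1.0 - (resid**2).sum() / sst
    return slope, intercept, r2


class TestFitTradeoff:
    def test_collinear_points(self):
        x = np.array([0.2, 0.4, 0.6, 0.8])
        fit = fit_tradeoff(x, -2.5 * x + 3.0)
        assert fit.slope == pytest.approx(-2.5, abs=1e-12)
        assert fit.intercept == pytest.approx(3.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_three_points(self):
        fit = fit_tradeoff([1.0, 2.0, 3.0], [2.0, 3.0, 5.0])
        assert fit.slope == pytest.approx(1.5, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert fit.r2 == pytest.approx(27.0 / 28.0, abs=1e-12)

    def test_constant_response(self):
        fit = fit_tradeoff([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == 0.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_tradeoff([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_tradeoff([1.0, 2.0], [1.0, 2.0])

    def test_missing_pairs_dropped_pairwise(self):
        x = [1.0, 2.0, np.nan, 3.0, 4.0]
        y = [2.0, 3.0, 9.0, np.nan, 6.0]
        fit = fit_tradeoff(x, y)
        assert fit.n == 3
        oracle = ols_normal_equations([1.0, 2.0, 4.0], [2.0, 3.0, 6.0])
        assert fit.slope == pytest.approx(oracle[0], abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            n = rng.integers(3, 30)
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 2.0 * x
            fit = fit_tradeoff(x, y)
            slope, intercept, r2 = ols_normal_equations(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)
            assert fit.r2 == pytest.approx(r2, abs=1e-10)


def ancova_oracle(xa, ya, xb, yb):
    """Interaction t-test by explicit normal equations + t distribution."""
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros(len(xa)), np.ones(len(xb))])
    X = np.column_stack([np.ones_like(x), x, g, x * g])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df = len(y) - 4
    sigma2 = (resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    t = beta[3] / np.sqrt(cov[3, 3])
    p = 2.0 * sps.t.sf(abs(t), df)
    return beta[3], t, df, p


class TestAncova:
    def test_identical_groups_no_interaction(self):
        x = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        y = np.array([1.0, 0.6, 0.1, -0.2, -0.9])
        cmp_res = compare_slopes_ancova((x, y), (x, y))
        assert cmp_res.interaction_estimate == pytest.approx(0.0, abs=1e-12)
        assert cmp_res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_distinct_slopes(self):
        x = np.array([0.2, 0.4, 0.6, 0.8])
        cmp_res = compare_slopes_ancova((x, -2.5 * x + 2.0), (x, -1.0 * x + 1.5))
        assert cmp_res.slope_a == pytest.approx(-2.5, abs=1e-10)
        assert cmp_res.slope_b == pytest.approx(-1.0, abs=1e-10)
        assert cmp_res.interaction_estimate == pytest.approx(1.5, abs=1e-10)
        assert cmp_res.p_value == 0.0
        assert "infinite_t" in cmp_res.flags

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            na, nb = int(rng.integers(5, 20)), int(rng.integers(5, 20))
            xa, xb = rng.normal(size=na), rng.normal(size=nb)
            ya = 1.0 - 2.5 * xa + rng.normal(scale=0.3, size=na)
            yb = 0.5 - 1.0 * xb + rng.normal(scale=0.3, size=nb)
            cmp_res = compare_slopes_ancova((xa, ya), (xb, yb))
            est, t, df, p = ancova_oracle(xa, ya, xb, yb)
            assert cmp_res.interaction_estimate == pytest.approx(est, abs=1e-10)
            assert cmp_res.statistic == pytest.approx(t, abs=1e-10)
            assert cmp_res.df == df
            assert cmp_res.p_value == pytest.approx(p, abs=1e-10)
            # pooled-model slopes coincide with separate per-group fits
            assert cmp_res.slope_b - cmp_res.slope_a == pytest.approx(
                est, abs=1e-10
            )

    def test_interaction_t_equals_difference_of_slopes_z(self):
        """With shared residual variance the interaction t is the slope-difference z."""
        rng = np.random.default_rng(21)
        x = np.linspace(0.1, 1.0, 12)
        noise = rng.normal(scale=0.1, size=12)
        ya = 2.0 - 2.5 * x + noise
        yb = 1.5 - 1.0 * x + noise  # identical noise: balanced design
        cmp_res = compare_slopes_ancova((x, ya), (x, yb))
        fa = sps.linregress(x, ya)
        fb = sps.linregress(x, yb)
        sxx = ((x - x.mean()) ** 2).sum()
        sse = sum(
            ((y - (f.intercept + f.slope * x)) ** 2).sum()
            for y, f in ((ya, fa), (yb, fb))
        )
        sigma2 = sse / (2 * len(x) - 4)
        z = (fb.slope - fa.slope) / np.sqrt(sigma2 * (1 / sxx + 1 / sxx))
        assert cmp_res.statistic == pytest.approx(z, abs=1e-10)

    def test_degenerate_group_rejected(self):
        x = np.array([0.5, 0.5, 0.5])
        with pytest.raises(ValueError):
            compare_slopes_ancova((x, x), ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))


class TestTwoSampleT:
    def test_identical_samples(self):
        result = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.t_statistic == 0.0
        assert result.p_value == 1.0

    def test_hand_computed_pooled_case(self):
        result = two_sample_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert result.t_statistic == pytest.approx(-np.sqrt(1.5), abs=1e-10)
        assert result.df == 4
        scipy_t, scipy_p = sps.ttest_ind([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert result.t_statistic == pytest.approx(scipy_t, abs=1e-12)
        assert result.p_value == pytest.approx(scipy_p, abs=1e-12)
        assert result.p_value == pytest.approx(0.288, abs=1e-3)

    def test_swap_symmetry(self):
        a, b = [0.5, 0.7, 0.9, 1.1], [0.6, 0.8, 1.4]
        fwd = two_sample_t(a, b)
        rev = two_sample_t(b, a)
        assert fwd.t_statistic == pytest.approx(-rev.t_statistic, abs=1e-12)
        assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)

    def test_zero_variance_unequal_means(self):
        result = two_sample_t([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(result.t_statistic)
        assert result.p_value == 0.0
        assert "infinite_t" in result.flags

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(0.5, 2.0, 12)
        result = two_sample_t(a, b, equal_var=False)
        scipy_t, scipy_p = sps.ttest_ind(a, b, equal_var=False)
        assert result.t_statistic == pytest.approx(scipy_t, abs=1e-10)
        assert result.p_value == pytest.approx(scipy_p, abs=1e-10)

    def test_null_rejection_rate_near_alpha(self):
        """On identically-distributed triplicates, rejections occur at ~5%."""
        rng = np.random.default_rng(17)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            a = rng.normal(size=3)
            b = rng.normal(size=3)
            if two_sample_t(a, b).p_value < 0.05:
                rejections += 1
        assert 0.03 < rejections / n_sim < 0.07


class TestSummarizeReplicates:
    def test_no_spread(self):
        summary = summarize_replicates([5.0, 5.0, 5.0])
        assert summary.mean == 5.0
        assert summary.sem == 0.0

    def test_hand_computed_sem(self):
        summary = summarize_replicates([0.4, 0.5, 0.6])
        assert summary.mean == pytest.approx(0.5)
        assert summary.sem == pytest.approx(0.1 / np.sqrt(3), abs=1e-9)

    def test_single_value_has_no_sem(self):
        summary = summarize_replicates([2.5])
        assert summary.mean == 2.5
        assert summary.sem is None
        assert summary.n == 1
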