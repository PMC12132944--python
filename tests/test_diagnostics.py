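"""Concordance statistics: identity-line R2, OLS, Q scores, Cook's distance."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from lwrbiomass.diagnostics import (
    cooks_distance,
    filter_influential,
    filter_q,
    iqr_outlier_screen,
    mae,
    ols_fit,
    q_scores,
    rmse,
    yx_r2,
)


def loo_cooks_oracle(x, y):
    """Deletion-definition Cook's distances by brute-force leave-one-out refits."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    X = sm.add_constant(x)
    full = sm.OLS(y, X).fit()
    yhat = np.asarray(full.fittedvalues)
    mse = float(full.resid @ full.resid) / (n - 2)
    d = np.empty(n)
    for i in range(n):
        keep = np.ones(n, bool)
        keep[i] = False
        sub = sm.OLS(y[keep], sm.add_constant(x[keep])).fit()
        yhat_i = sub.params[0] + sub.params[1] * x
        d[i] = float(np.sum((yhat - yhat_i) ** 2)) / (2 * mse)
    return d


class TestYxR2:
    def test_perfect_agreement(self):
        assert yx_r2([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_mean_constant_prediction_scores_zero(self):
        assert yx_r2([1, 2, 3], [2, 2, 2]) == pytest.approx(0.0)

    def test_reversed_prediction_is_strongly_negative(self):
        # SSE = 4+0+4 = 8 against SST = 2
        assert yx_r2([1, 2, 3], [3, 2, 1]) == pytest.approx(-3.0)

    def test_constant_measured_undefined(self):
        with pytest.raises(ValueError):
            yx_r2([2, 2, 2], [1, 2, 3])

    @given(st.integers(0, 10_000))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_never_exceeds_ols_r2(self, seed):
        """OLS minimizes SSE over all lines, so identity-line R2 <= OLS R2."""
        r = np.random.default_rng(seed)
        x = r.lognormal(1.0, 1.0, size=20)
        y = x * r.lognormal(0.0, 0.5, size=20)
        assert yx_r2(y, x) <= ols_fit(x, y).r2 + 1e-12


class TestOlsFit:
    def test_exact_collinearity(self):
        fit = ols_fit([1, 2, 3], [2, 4, 6])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_two_points_interpolate(self):
        fit = ols_fit([1.0, 3.0], [5.0, 9.0])
        assert fit.slope == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_normal_equations(self, rng):
        x = rng.normal(size=30)
        y = 1.5 * x + rng.normal(size=30)
        fit = ols_fit(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-10, abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], rel=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            ols_fit([1, 1, 1], [1, 2, 3])


class TestQScores:
    def test_worked_example(self):
        """Residual magnitudes [1,2,3,100]: MedAD 2.5, Q = r/2.5."""
        res = q_scores([1, 2, 3, 100], [0, 0, 0, 0])
        assert res.med_ad == pytest.approx(2.5)
        assert res.q == pytest.approx([0.4, 0.8, 1.2, 40.0])
        assert list(res.keep_mask) == [True, True, True, False]

    def test_equal_residuals_all_unity(self):
        res = q_scores([3, 4, 5], [1, 2, 3])
        assert res.q == pytest.approx([1.0, 1.0, 1.0])

    def test_scale_invariance(self):
        m = np.array([1.0, 2.0, 3.0, 100.0])
        res1 = q_scores(m, np.zeros(4))
        res10 = q_scores(10 * m, np.zeros(4))
        assert res10.q == pytest.approx(res1.q)

    def test_medad_zero_with_nonzero_residual(self):
        """Majority-exact fit: the discrepant points get Q = inf, filtered."""
        res = q_scores([1, 2, 3, 9], [1, 2, 3, 4])
        assert np.isinf(res.q[3]) and res.q[:3] == pytest.approx([0, 0, 0])
        assert list(res.keep_mask) == [True, True, True, False]

    def test_medad_zero_all_residuals_zero(self):
        res = q_scores([1, 2, 3], [1, 2, 3])
        assert res.q == pytest.approx([0.0, 0.0, 0.0])
        assert res.keep_mask.all()

    def test_filter_is_strict_at_threshold(self):
        # residuals [1,1,6,6] -> MedAD 3.5 ... build exact-boundary case instead
        measured = np.array([0.0, 2.0, 6.0, 12.0])
        estimated = np.zeros(4)
        res = filter_q(measured, estimated, threshold=3.0)
        # MedAD = 4, Q = [0, .5, 1.5, 3.0]; Q == threshold is kept
        assert res.q[3] == pytest.approx(3.0)
        assert res.keep_mask.all()


class TestCooksDistance:
    def test_collinear_all_zero(self):
        res = cooks_distance([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.d == pytest.approx(np.zeros(4), abs=1e-20)
        assert not res.influential_mask.any()

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("n", [5, 20, 120])
    def test_leverage_form_equals_loo_oracle(self, seed, n):
        r = np.random.default_rng(seed + 1000 * n)
        x = r.normal(size=n)
        y = 0.7 * x + r.normal(size=n)
        res = cooks_distance(x, y)
        np.testing.assert_allclose(res.d, loo_cooks_oracle(x, y), rtol=1e-10)

    def test_matches_statsmodels_influence(self, rng):
        x = rng.lognormal(size=50)
        y = x + rng.normal(size=50)
        res = cooks_distance(x, y)
        sm_d = sm.OLS(y, sm.add_constant(x)).fit().get_influence().cooks_distance[0]
        np.testing.assert_allclose(res.d, sm_d, rtol=1e-10)

    def test_duplicated_point_dilutes_influence(self, rng):
        """Duplicating an outlier lowers each copy's distance vs the unique case."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 20.0])
        y = np.array([1.1, 2.0, 2.9, 4.2, 40.0])
        d_unique = cooks_distance(x, y).d[-1]
        x2 = np.append(x, 20.0)
        y2 = np.append(y, 40.0)
        d_dup = cooks_distance(x2, y2).d[-2:]
        assert (d_dup < d_unique).all()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cooks_distance([1, 2, 3], [1, 2, 3.5])


class TestFilterInfluential:
    def test_identity_when_all_below_cutoff(self, rng):
        x = np.linspace(1, 10, 40)
        y = x + rng.normal(0, 0.1, size=40)
        res = filter_influential(x, y, cutoff=1e6)
        assert not res.influential_mask.any()

    def test_planted_high_leverage_outlier_is_flagged(self, rng):
        x = np.linspace(1, 10, 30)
        y = 2 * x + rng.normal(0, 0.05, size=30)
        x = np.append(x, 100.0)
        y = np.append(y, 5.0)  # far off the line at extreme leverage
        res = filter_influential(x, y)
        assert res.influential_mask[-1]
        assert res.influential_mask.sum() == 1

    def test_removal_never_increases_refit_sse(self, rng):
        """Refitting on the kept points cannot fit them worse than the full fit."""
        for _ in range(20):
            x = rng.lognormal(1, 0.8, size=40)
            y = x * rng.lognormal(0, 0.6, size=40)
            res = filter_influential(x, y)
            keep = ~res.influential_mask
            if keep.sum() < 4 or np.ptp(x[keep]) == 0:
                continue
            full = ols_fit(x, y)
            sse_full_on_kept = float(np.sum(
                (y[keep] - (full.intercept + full.slope * x[keep])) ** 2))
            refit = ols_fit(x[keep], y[keep])
            sse_refit = float(np.sum(refit.residuals**2))
            assert sse_refit <= sse_full_on_kept + 1e-9

    def test_top_k_rule(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 20.0])
        y = np.array([1.0, 2.1, 2.9, 4.0, 40.0])
        res = filter_influential(x, y, cutoff=("top_k", 1))
        assert res.influential_mask.sum() == 1
        assert res.influential_mask[np.argmax(res.d)]


class TestErrorMetrics:
    def test_identical_vectors_zero(self):
        assert rmse([1, 2], [1, 2]) == 0.0
        assert mae([1, 2], [1, 2]) == 0.0

    def test_closed_form(self):
        assert rmse([3, 4], [0, 0]) == pytest.approx(np.sqrt(12.5))
        assert mae([3, 4], [0, 0]) == pytest.approx(3.5)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_rmse_at_least_mae(self, seed):
        r = np.random.default_rng(seed)
        y = r.normal(size=15)
        yhat = r.normal(size=15)
        assert rmse(y, yhat) >= mae(y, yhat) - 1e-12


class TestIqrScreen:
    def test_log_symmetric_sample_clean(self):
        # log-uniform spread with no extremes: nothing beyond the fences
        w = np.exp(np.linspace(-1.0, 1.0, 50))
        assert not iqr_outlier_screen(w).any()

    def test_extreme_value_flagged(self):
        w = np.exp(np.linspace(-1.0, 1.0, 99))
        w = np.append(w, np.median(w) * 1e6)
        flags = iqr_outlier_screen(w)
        assert flags[-1] and flags.sum() == 1

    def test_rejects_nonpositive_weight(self):
        with pytest.raises(ValueError):
            iqr_outlier_screen([1.0, 0.0, 2.0])


@given(st.integers(0, 10_000))
@settings(deadline=None, derandomize=True, max_examples=30)
def test_statistics_are_permutation_invariant(seed):
    r = np.random.default_rng(seed)
    x = r.lognormal(1, 0.8, size=25)
    y = x * r.lognormal(0, 0.4, size=25)
    perm = r.permutation(25)
    assert yx_r2(y, x) == pytest.approx(yx_r2(y[perm], x[perm]), rel=1e-12)
    assert ols_fit(x, y).slope == pytest.approx(ols_fit(x[perm], y[perm]).slope, rel=1e-10)
    assert rmse(y, x) == pytest.approx(rmse(y[perm], x[perm]), rel=1e-12)
    np.testing.assert_allclose(
        np.sort(cooks_distance(x, y).d), np.sort(cooks_distance(x[perm], y[perm]).d),
        rtol=1e-9)
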