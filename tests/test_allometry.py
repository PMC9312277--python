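import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from allomet.allometry import (
    AllometricModel,
    delta_se_a,
    filter_by_mass,
    fit_ols,
    fit_wls,
    refit_intercept_fixed_slope,
    slope_ttest,
)

from conftest import make_table


def normal_equations_oracle(x, y, w=None):
    """Explicit weighted 2x2 solve, independent of the fitting path."""
    if w is None:
        w = np.ones_like(x)
    X = np.column_stack([np.ones_like(x), x])
    A = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(A, X.T @ (w * y))
    resid = y - X @ beta
    rss = float(np.sum(w * resid**2))
    sigma2 = rss / (len(x) - 2)
    cov = sigma2 * np.linalg.inv(A)
    return beta, np.sqrt(np.diag(cov)), rss


class TestFitOLS:
    def test_collinear_points_exact(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_ols(x, 0.5 + 0.7 * x)
        assert fit.log10_a == pytest.approx(0.5, abs=1e-12)
        assert fit.a == pytest.approx(10**0.5, rel=1e-12)
        assert fit.b == pytest.approx(0.7, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(2, 1, 20)
        y = 0.4 + 0.68 * x + rng.normal(0, 0.15, 20)
        fit = fit_ols(x, y)
        beta, se, rss = normal_equations_oracle(x, y)
        assert fit.log10_a == pytest.approx(beta[0], abs=1e-10)
        assert fit.b == pytest.approx(beta[1], abs=1e-10)
        assert fit.se_log10_a == pytest.approx(se[0], abs=1e-10)
        assert fit.se_b == pytest.approx(se[1], abs=1e-10)
        assert fit.residual_sd == pytest.approx(math.sqrt(rss / 18), abs=1e-10)

    def test_constant_x_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|equal"):
            fit_ols(np.ones(5), np.arange(5.0))

    @settings(max_examples=25, deadline=None)
    @given(c=st.floats(-5, 5))
    def test_shift_equivariance(self, c):
        rng = np.random.default_rng(7)
        x = rng.normal(size=15)
        y = 0.3 + 0.9 * x + rng.normal(size=15) * 0.1
        base = fit_ols(x, y)
        shifted_y = fit_ols(x, y + c)
        assert shifted_y.log10_a == pytest.approx(base.log10_a + c, abs=1e-9)
        assert shifted_y.b == pytest.approx(base.b, abs=1e-12)
        assert shifted_y.r2 == pytest.approx(base.r2, abs=1e-9)
        shifted_x = fit_ols(x + c, y)
        assert shifted_x.b == pytest.approx(base.b, abs=1e-9)


class TestFitWLS:
    def test_equal_weights_reduce_to_ols(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        f1 = fit_ols(x, y)
        f2 = fit_wls(x, y, np.full(12, 3.7))
        assert f2.log10_a == pytest.approx(f1.log10_a, abs=1e-12)
        assert f2.b == pytest.approx(f1.b, abs=1e-12)

    def test_zero_weight_rejected(self, rng):
        x = rng.normal(size=5)
        with pytest.raises(ValueError):
            fit_wls(x, x, np.array([1, 1, 0, 1, 1.0]))

    def test_replication_equivalence(self, rng):
        """Giving a point weight k equals duplicating it k times."""
        x = rng.normal(size=8)
        y = 0.2 + 0.7 * x + rng.normal(size=8) * 0.05
        k = 4
        w = np.ones(8)
        w[3] = k
        weighted = fit_wls(x, y, w)
        x_dup = np.concatenate([x, np.repeat(x[3], k - 1)])
        y_dup = np.concatenate([y, np.repeat(y[3], k - 1)])
        duplicated = fit_ols(x_dup, y_dup)
        assert weighted.log10_a == pytest.approx(duplicated.log10_a, abs=1e-10)
        assert weighted.b == pytest.approx(duplicated.b, abs=1e-10)


class TestFixedSlopeRefit:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 3, 7)
        log10_a, a, r2 = refit_intercept_fixed_slope(x, 0.5 + 0.7 * x, 0.7)
        assert log10_a == pytest.approx(0.5, abs=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_two_point_hand_case(self):
        log10_a, _, _ = refit_intercept_fixed_slope(
            np.array([0.0, 1.0]), np.array([0.0, 1.0]), 0.5
        )
        assert log10_a == pytest.approx(0.25, abs=1e-12)

    def test_consistent_with_free_fit(self, rng):
        x = rng.normal(size=30)
        y = 0.1 + 0.75 * x + rng.normal(size=30) * 0.1
        free = fit_ols(x, y)
        log10_a, a, r2 = refit_intercept_fixed_slope(x, y, free.b)
        assert log10_a == pytest.approx(free.log10_a, abs=1e-12)
        assert a == pytest.approx(free.a, rel=1e-12)

    def test_minimises_rss_over_intercepts(self, rng):
        x = rng.normal(size=25)
        y = 0.3 + 0.6 * x + rng.normal(size=25) * 0.2
        b0 = 0.8
        log10_a, _, _ = refit_intercept_fixed_slope(x, y, b0)
        best_rss = np.sum((y - log10_a - b0 * x) ** 2)
        for cand in np.linspace(log10_a - 0.5, log10_a + 0.5, 201):
            assert best_rss <= np.sum((y - cand - b0 * x) ** 2) + 1e-12

    def test_r2_not_above_free_fit(self, rng):
        x = rng.normal(size=20)
        y = 0.3 + 0.7 * x + rng.normal(size=20) * 0.1
        free = fit_ols(x, y)
        _, _, r2_fixed = refit_intercept_fixed_slope(x, y, 0.6)
        assert r2_fixed <= free.r2 + 1e-12

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            refit_intercept_fixed_slope(np.array([]), np.array([]), 0.7)


class TestSlopeTTest:
    def _fit(self, b, se_b, n):
        from allomet.allometry import AllometricFit

        return AllometricFit(
            log10_a=0.0, b=b, se_log10_a=0.1, se_b=se_b, r2=0.9, n=n,
            residual_sd=0.1, x_mean=0.0, ssx=1.0,
        )

    def test_equal_to_null_gives_t0_p1(self):
        t, p = slope_ttest(self._fit(0.75, 0.01, 100), 0.75)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_against_t_cdf(self):
        fit = self._fit(0.70, 0.01, 100)
        t, p = slope_ttest(fit, 0.75)
        assert t == pytest.approx(-5.0, abs=1e-12)
        assert p == pytest.approx(2 * stats.t.cdf(-5.0, df=98), rel=1e-12)
        assert p < 1e-5

    def test_sign_symmetry(self):
        _, p_low = slope_ttest(self._fit(0.70, 0.02, 50), 0.75)
        _, p_high = slope_ttest(self._fit(0.80, 0.02, 50), 0.75)
        assert p_low == pytest.approx(p_high, rel=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            slope_ttest(self._fit(0.7, 0.1, 2), 0.75)


class TestDeltaSE:
    def _fit(self, log10_a, se):
        from allomet.allometry import AllometricFit

        return AllometricFit(
            log10_a=log10_a, b=0.7, se_log10_a=se, se_b=0.01, r2=0.9, n=10,
            residual_sd=0.1, x_mean=0.0, ssx=1.0,
        )

    def test_zero_se(self):
        assert delta_se_a(self._fit(0.5, 0.0)) == 0.0

    def test_unit_case_ln10(self):
        assert delta_se_a(self._fit(0.0, 1.0)) == pytest.approx(math.log(10.0))

    def test_matches_monte_carlo_sd(self, rng):
        sigma = 0.01
        draws = 10 ** (0.6 + rng.normal(0, sigma, 100_000))
        mc_sd = np.std(draws)
        assert delta_se_a(self._fit(0.6, sigma)) == pytest.approx(mc_sd, rel=0.05)


class TestMassFilter:
    def test_threshold_above_all_is_identity(self):
        t = make_table([100.0, 200.0], [10.0, 20.0], ["A", "A"])
        assert len(filter_by_mass(t, 1e9)) == 2

    def test_inclusive_boundary(self):
        t = make_table([5000.0, 10000.0, 15000.0], [1, 2, 3.0], ["A"] * 3)
        kept = filter_by_mass(t, 10000.0)
        assert len(kept) == 2
        assert kept.data["mass_g"].max() == 10000.0

    def test_curved_generator_shifts_subset_slope(self):
        """Concave-up log-log curvature: restricting to small masses lowers
        the fitted slope relative to the full-range fit."""
        rng = np.random.default_rng(5)
        x = rng.uniform(0.5, 6.0, 800)  # log10 mass, up to ~1000 kg
        y = 0.5 + 0.6 * x + 0.02 * x**2 + rng.normal(0, 0.1, 800)
        t = make_table(10.0**x, 10.0**y, ["A"] * 800)
        full = AllometricModel.from_table(t).fit()
        small = filter_by_mass(t, 10_000.0)
        sub = AllometricModel.from_table(small).fit()
        assert sub.b < full.b
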