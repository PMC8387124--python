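import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from childmort import (
    LogLogTrajectory,
    atm_from_counts,
    find_minimum,
    loglog_points,
    residual_independence,
    standard_grid,
    table1_report,
)
from childmort.errors import InsufficientDataError, ValidationError
from conftest import ols_oracle


def _atm_with_rates(grid, rates, L=1e6):
    rates = np.asarray(rates, float)
    Ls = np.full(len(grid), float(L))
    deaths = np.rint(rates * Ls).astype(int)
    return atm_from_counts(grid, deaths, Ls)


class TestLogLogPoints:
    def test_standard_grid_gives_six_points_to_ten_years(self, grid15):
        x = np.array(grid15.midpoints())
        atm = _atm_with_rates(grid15, 6e-4 / x)
        lnx, lnmu = loglog_points(atm, (0, 10))
        assert len(lnx) == 6

    def test_exact_inverse_rates_are_collinear_with_slope_minus_one(self, grid10):
        x = np.array(grid10.midpoints())
        L = np.full(6, 1.0)
        atm = atm_from_counts(grid10, np.ones(6), L / (100.0 / x))
        lnx, lnmu = loglog_points(atm, (0, 10))
        slopes = np.diff(lnmu) / np.diff(lnx)
        np.testing.assert_allclose(slopes, -1.0, rtol=1e-12)

    def test_zero_death_category_in_range_is_an_error(self, grid10):
        atm = atm_from_counts(grid10, [5, 5, 0, 5, 5, 5], np.full(6, 1e4))
        with pytest.raises(ValidationError, match="7-27 days"):
            loglog_points(atm, (0, 10))

    def test_too_few_points_is_an_error(self, grid15):
        atm = atm_from_counts(grid15, np.ones(7, int), np.full(7, 1e4))
        with pytest.raises(InsufficientDataError):
            loglog_points(atm, (5, 15))


class TestCurvature:
    def test_exact_line_has_no_curvature(self):
        lnx = np.log([0.1, 0.5, 1, 3, 7, 10])
        model = LogLogTrajectory(lnx, 2.0 - lnx)
        curv = model.test_curvature()
        assert abs(curv.quad_coef) < 1e-12
        assert not curv.rejected

    def test_quadratic_signal_detected_and_matches_hand_ols(self):
        rng = np.random.default_rng(7)
        lnx = np.log(np.array([0.00137, 0.011, 0.048, 0.54, 3.0, 7.5]))
        lnmu = 1.0 - lnx - 0.5 * lnx**2 + rng.normal(0, 0.01, 6)
        model = LogLogTrajectory(lnx, lnmu)
        curv = model.test_curvature()
        assert curv.rejected
        X = np.column_stack([np.ones(6), lnx, lnx**2])
        beta, _, rss, se = ols_oracle(X, lnmu)
        assert curv.quad_coef == pytest.approx(beta[2], rel=1e-10)
        t = beta[2] / se[2]
        p = 2 * stats.t.sf(abs(t), 3)
        assert curv.p_quad == pytest.approx(p, rel=1e-10)

    def test_three_points_insufficient(self):
        model = LogLogTrajectory(np.log([1, 2, 4]), np.log([8, 4, 2]))
        with pytest.raises(InsufficientDataError):
            model.test_curvature()


class TestLinearFit:
    def test_exact_inverse_line_recovered(self):
        lnx = np.log([0.01, 0.1, 1, 10])
        res = LogLogTrajectory(lnx, math.log(100.0) - lnx).fit(scale=1.0)
        assert res.gamma == pytest.approx(-1.0, abs=1e-12)
        assert res.r2_adj == pytest.approx(1.0)
        assert res.mu1_level == pytest.approx(100.0, rel=1e-10)

    def test_hand_picked_collinear_points(self):
        # (x, mu) = (1, 8), (2, 4), (4, 2): exactly mu = 8/x
        res = LogLogTrajectory.from_rates([1, 2, 4], [8, 4, 2]).fit(scale=1.0)
        assert res.gamma == pytest.approx(-1.0, abs=1e-12)
        assert res.ln_mu1 == pytest.approx(math.log(8.0), rel=1e-12)

    def test_residuals_sum_to_zero_and_ci_brackets_slope(self):
        rng = np.random.default_rng(3)
        lnx = np.log([0.00137, 0.011, 0.048, 0.54, 3.0, 7.5])
        res = LogLogTrajectory(lnx, -lnx + rng.normal(0, 0.05, 6)).fit()
        assert res.residuals.sum() == pytest.approx(0.0, abs=1e-10)
        assert res.ci_lower < res.gamma < res.ci_upper

    def test_identical_abscissae_rejected(self):
        with pytest.raises(ValidationError):
            LogLogTrajectory(np.zeros(4), np.arange(4.0))

    @given(
        st.integers(0, 2**31 - 1),
        st.integers(4, 12),
        st.floats(-2.0, 1.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_ols_matches_normal_equations_oracle(self, seed, n, slope):
        """gamma, ln_mu1, RSS and se agree with an independent solve."""
        rng = np.random.default_rng(seed)
        lnx = np.sort(rng.uniform(-6, 3, n))
        if np.ptp(lnx) < 1e-3:
            return
        lnmu = slope * lnx + rng.normal(0, 0.3, n)
        res = LogLogTrajectory(lnx, lnmu).fit()
        X = np.column_stack([np.ones(n), lnx])
        beta, _, rss, se = ols_oracle(X, lnmu)
        assert res.ln_mu1 == pytest.approx(beta[0], rel=1e-10, abs=1e-12)
        assert res.gamma == pytest.approx(beta[1], rel=1e-10, abs=1e-12)
        assert res.rss == pytest.approx(rss, rel=1e-10, abs=1e-14)
        assert res.se_gamma == pytest.approx(se[1], rel=1e-10)


class TestInverseTest:
    def test_exact_inverse_data_guarded(self):
        lnx = np.log([0.01, 0.1, 1, 10])
        res = LogLogTrajectory(lnx, 2.0 - lnx).fit()
        inv = res.test_inverse()
        assert inv.F_stat == 0.0
        assert inv.p_value == 1.0
        assert inv.rb2 == pytest.approx(1.0)

    def test_nesting_rss_inverse_at_least_linear(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            lnx = np.sort(rng.uniform(-6, 3, 6))
            lnmu = rng.uniform(-1.4, -0.6) * lnx + rng.normal(0, 0.1, 6)
            res = LogLogTrajectory(lnx, lnmu).fit()
            inv = res.test_inverse()
            assert inv.rss_inverse >= res.rss - 1e-12
            assert inv.rb2 <= res.r2 + 1e-12

    def test_f_equals_squared_t_for_slope_against_minus_one(self):
        rng = np.random.default_rng(13)
        lnx = np.log([0.00137, 0.011, 0.048, 0.54, 3.0, 7.5])
        lnmu = -0.8 * lnx + rng.normal(0, 0.02, 6)
        res = LogLogTrajectory(lnx, lnmu).fit()
        inv = res.test_inverse()
        t = res.test_slope(-1.0)
        assert inv.F_stat == pytest.approx(t.t_stat**2, rel=1e-10)
        assert inv.p_value == pytest.approx(t.p_value, rel=1e-10)

    def test_against_brute_force_rss_oracle(self):
        rng = np.random.default_rng(17)
        lnx = np.log([0.00137, 0.011, 0.048, 0.54, 3.0, 7.5])
        lnmu = -0.80 * lnx + rng.normal(0, 0.02, 6)
        res = LogLogTrajectory(lnx, lnmu).fit()
        inv = res.test_inverse()
        # oracle: both models by direct normal equations
        X = np.column_stack([np.ones(6), lnx])
        _, _, rss_lin, _ = ols_oracle(X, lnmu)
        a = float(np.mean(lnmu + lnx))
        rss_inv = float(np.sum((lnmu - (a - lnx)) ** 2))
        F = (rss_inv - rss_lin) / (rss_lin / 4)
        assert inv.rss_linear == pytest.approx(rss_lin, rel=1e-10)
        assert inv.rss_inverse == pytest.approx(rss_inv, rel=1e-10)
        assert inv.F_stat == pytest.approx(F, rel=1e-10)
        assert inv.p_value == pytest.approx(float(stats.f.sf(F, 1, 4)), rel=1e-10)

    def test_median_p_decreases_as_truth_departs_from_inverse(self):
        lnx = np.log([0.00137, 0.011, 0.048, 0.54, 3.0, 7.5])
        medians = []
        for gamma in (-1.0, -0.9, -0.8):
            ps = []
            for seed in range(60):
                rng = np.random.default_rng(seed)
                lnmu = gamma * lnx + rng.normal(0, 0.03, 6)
                ps.append(
                    LogLogTrajectory(lnx, lnmu).fit().test_inverse().p_value
                )
            medians.append(np.median(ps))
        assert medians[0] > medians[1] > medians[2]


class TestZeroSlope:
    def test_flat_rates_not_rejected(self):
        rng = np.random.default_rng(23)
        lnx = np.log([0.5, 3.0, 7.5, 12.5])
        res = LogLogTrajectory(lnx, -7.0 + rng.normal(0, 0.02, 4)).fit()
        assert not res.test_zero_slope().rejected

    def test_inverse_data_rejected(self):
        lnx = np.log([0.01, 0.1, 1, 10])
        res = LogLogTrajectory(lnx, 2.0 - lnx).fit()
        assert res.test_zero_slope().rejected


class TestResidualIndependence:
    def test_perfect_fit_guarded_to_p_one(self):
        lnx = np.log([0.01, 0.1, 1, 10])
        res = LogLogTrajectory(lnx, 2.0 - lnx).fit()
        t = res.test_residual_independence("inverse")
        assert t.p_value == 1.0

    def test_trend_in_inverse_residuals_detected(self):
        # true slope -0.7: inverse-model residuals trend with ln x
        lnx = np.log(np.array([0.00137, 0.011, 0.048, 0.54, 3.0, 7.5]))
        rng = np.random.default_rng(29)
        lnmu = -0.7 * lnx + rng.normal(0, 0.01, 6)
        res = LogLogTrajectory(lnx, lnmu).fit()
        t = res.test_residual_independence("inverse")
        assert t.method == "permutation"
        assert t.p_value < 0.05

    def test_permutation_matches_direct_enumeration_oracle(self):
        rng = np.random.default_rng(31)
        lnx = np.sort(rng.uniform(-6, 2, 6))
        resid = rng.normal(0, 1, 6)
        t = residual_independence(lnx, resid)
        # oracle: Monte-Carlo permutation of Spearman |rho|, 10000 draws
        obs = abs(stats.spearmanr(lnx, resid).statistic)
        count = 0
        n_mc = 10_000
        for _ in range(n_mc):
            perm = rng.permutation(resid)
            if abs(stats.spearmanr(lnx, perm).statistic) >= obs - 1e-12:
                count += 1
        assert t.p_value == pytest.approx(count / n_mc, abs=0.02)

    def test_type_one_error_near_nominal(self):
        lnx = np.log([0.00137, 0.011, 0.048, 0.54, 3.0, 7.5])
        rejections = 0
        n = 400
        for seed in range(n):
            rng = np.random.default_rng(seed)
            resid = rng.normal(0, 1, 6)
            if residual_independence(lnx, resid).p_value < 0.05:
                rejections += 1
        # exact permutation test is conservative at n=6; never above nominal
        assert rejections / n <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n)


class TestMinimum:
    def test_strictly_decreasing_rates_reach_last_category(self, grid15):
        x = np.array(grid15.midpoints())
        atm = _atm_with_rates(grid15, 6e-4 / x)
        assert find_minimum(atm).label == "10-14 years"

    def test_inverse_then_rise_minimises_in_five_to_ten(self, grid15):
        x = np.array(grid15.midpoints())
        rates = np.where(x <= 7.5, 6e-4 / x, 6e-4 / 7.5 * 2)
        atm = _atm_with_rates(grid15, rates)
        assert find_minimum(atm).label == "5-9 years"

    def test_ties_break_younger(self, grid10):
        atm = atm_from_counts(grid10, [5, 4, 3, 2, 1, 1], np.full(6, 1e3))
        assert find_minimum(atm).label == "1-4 years"

    def test_all_zero_rates_degenerate(self, grid10):
        atm = atm_from_counts(grid10, np.zeros(6, int), np.full(6, 1e3))
        with pytest.raises(ValidationError):
            find_minimum(atm)


class TestReport:
    def test_single_population_row_passes_through_fit_outputs(self, grid10):
        x = np.array(grid10.midpoints())
        rng = np.random.default_rng(37)
        rates = 6e-4 / x * np.exp(rng.normal(0, 0.02, 6))
        atm = _atm_with_rates(grid10, rates, L=1e8)
        df = table1_report([atm], (0, 10), scale=1000.0)
        res = LogLogTrajectory.from_atm(atm, (0, 10)).fit()
        row = df.iloc[0]
        assert row["slope"] == pytest.approx(res.gamma)
        assert row["lower"] == pytest.approx(res.ci_lower)
        assert row["rb2"] == pytest.approx(res.test_inverse().rb2)

    def test_rendered_precision(self, grid10):
        x = np.array(grid10.midpoints())
        atm = _atm_with_rates(grid10, 6e-4 / x, L=1e8)
        df = table1_report([atm], (0, 10), rendered=True)
        assert df.iloc[0]["slope"] == round(df.iloc[0]["slope"], 3)
        assert df.iloc[0]["r2_adj"] == round(df.iloc[0]["r2_adj"], 4)
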