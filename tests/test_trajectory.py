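import numpy as np
import pandas as pd
import pytest

from epiclock.trajectory import (contrast_at_day, convergence_day,
                                 extrapolate_group_age, fit_trajectory,
                                 percent_slowdown, percent_slowdown_ci)

from _oracles import ols_normal_equations


def _data(slope_c=0.8, slope_d=0.56, b_c=4.0, b_d=8.0, noise=None, seed=0):
    days = np.repeat([6.0, 12, 18, 24, 30], 4)
    rng = np.random.default_rng(seed)
    y_c = b_c + slope_c * days
    y_d = b_d + slope_d * days
    if noise:
        y_c = y_c + rng.normal(0, noise, len(days))
        y_d = y_d + rng.normal(0, noise, len(days))
    pred = pd.Series(np.concatenate([y_c, y_d]))
    day = pd.Series(np.concatenate([days, days]))
    treat = pd.Series(["control"] * 20 + ["diapause"] * 20)
    return pred, day, treat


class TestFit:
    def test_exact_lines_recovered(self):
        pred, day, treat = _data()
        fit = fit_trajectory(pred, day, treat)
        assert fit.slopes["control"] == pytest.approx(0.8, abs=1e-10)
        assert fit.slopes["diapause"] == pytest.approx(0.56, abs=1e-10)
        assert fit.intercepts["control"] == pytest.approx(4.0, abs=1e-9)
        assert fit.intercepts["diapause"] == pytest.approx(8.0, abs=1e-9)

    def test_identical_group_lines_null_interaction(self):
        days = np.repeat([6.0, 12, 18, 24, 30], 4)
        rng = np.random.default_rng(1)
        y = 2 + 0.9 * days + rng.normal(0, 1.0, len(days))
        pred = pd.Series(np.concatenate([y, y]))
        day = pd.Series(np.concatenate([days, days]))
        treat = pd.Series(["control"] * 20 + ["diapause"] * 20)
        fit = fit_trajectory(pred, day, treat)
        assert fit.interaction == pytest.approx(0.0, abs=1e-10)
        assert fit.interaction_p > 0.99

    def test_matches_normal_equations_oracle(self):
        pred, day, treat = _data(noise=1.2, seed=7)
        fit = fit_trajectory(pred, day, treat)
        dc = day.to_numpy() - 6.0
        z = (treat == "diapause").to_numpy().astype(float)
        X = np.column_stack([np.ones(40), dc, z, dc * z])
        ref = ols_normal_equations(X, pred.to_numpy())
        assert fit.interaction == pytest.approx(ref["beta"][3], abs=1e-8)
        assert fit.interaction_se == pytest.approx(ref["se"][3], abs=1e-8)
        assert fit.interaction_t == pytest.approx(ref["t"][3], abs=1e-8)
        assert fit.interaction_p == pytest.approx(ref["p"][3], abs=1e-10)
        np.testing.assert_allclose(fit.cov, ref["cov"], atol=1e-8)
        assert fit.df_resid == 36  # 40 libraries, 4 parameters

    def test_residuals_orthogonal_to_design(self):
        pred, day, treat = _data(noise=2.0, seed=3)
        fit = fit_trajectory(pred, day, treat)
        dc = day.to_numpy() - fit.center_day
        z = (treat == "diapause").to_numpy().astype(float)
        X = np.column_stack([np.ones(40), dc, z, dc * z])
        yhat = X @ fit.params
        resid = pred.to_numpy() - yhat
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_single_day_group_rejected(self):
        pred = pd.Series([1.0, 2, 3, 4])
        day = pd.Series([6.0, 12, 6, 6])
        treat = pd.Series(["control", "control", "diapause", "diapause"])
        with pytest.raises(ValueError, match="diapause"):
            fit_trajectory(pred, day, treat)


class TestContrast:
    def test_balanced_marginal_mean_equals_sample_mean(self):
        pred, day, treat = _data(noise=1.0, seed=5)
        fit = fit_trajectory(pred, day, treat)
        c = contrast_at_day(fit, 18.0)  # mean sampling day of both groups
        ctl = pred[treat == "control"]
        assert c.means["control"] == pytest.approx(ctl.mean(), abs=1e-10)

    def test_identical_groups_zero_difference(self):
        days = np.repeat([6.0, 12, 18, 24, 30], 4)
        rng = np.random.default_rng(2)
        y = 2 + 0.9 * days + rng.normal(0, 1.0, len(days))
        fit = fit_trajectory(pd.Series(np.concatenate([y, y])),
                             pd.Series(np.concatenate([days, days])),
                             pd.Series(["control"] * 20 + ["diapause"] * 20))
        c = contrast_at_day(fit, 12.0)
        assert c.difference == pytest.approx(0.0, abs=1e-10)
        assert c.p > 0.99

    def test_contrast_matches_covariance_oracle(self):
        pred, day, treat = _data(noise=1.5, seed=11)
        fit = fit_trajectory(pred, day, treat)
        dc = day.to_numpy() - 6.0
        z = (treat == "diapause").to_numpy().astype(float)
        X = np.column_stack([np.ones(40), dc, z, dc * z])
        ref = ols_normal_equations(X, pred.to_numpy())
        for d in (6.0, 30.0):
            c = contrast_at_day(fit, d)
            L = np.array([0.0, 0.0, 1.0, d - 6.0])
            assert c.difference == pytest.approx(float(L @ ref["beta"]), abs=1e-8)
            assert c.se == pytest.approx(float(np.sqrt(L @ ref["cov"] @ L)), abs=1e-8)

    def test_extrapolation_warns(self):
        pred, day, treat = _data()
        fit = fit_trajectory(pred, day, treat)
        with pytest.warns(UserWarning, match="outside"):
            contrast_at_day(fit, 40.0)

    def test_zero_crossing_of_contrast_equals_convergence_day(self):
        pred, day, treat = _data(noise=0.8, seed=13)
        fit = fit_trajectory(pred, day, treat)
        conv = convergence_day(fit)
        c = contrast_at_day(fit, conv)
        assert c.difference == pytest.approx(0.0, abs=1e-8)


class TestSlowdown:
    def test_published_style_slopes(self):
        # slopes on the order of the diapause study give ~29%
        assert percent_slowdown(0.78812, 0.55828) == pytest.approx(29.1631, abs=1e-3)

    def test_equal_slopes_zero(self):
        assert percent_slowdown(0.7, 0.7) == 0.0

    def test_zero_treatment_slope_is_full_stop(self):
        assert percent_slowdown(0.7, 0.0) == 100.0

    def test_zero_control_slope_rejected(self):
        with pytest.raises(ValueError):
            percent_slowdown(0.0, 0.5)

    def test_ci_contains_point_estimate(self):
        pred, day, treat = _data(noise=1.0, seed=17)
        fit = fit_trajectory(pred, day, treat)
        point, lo, hi = percent_slowdown_ci(fit)
        assert lo < point < hi
        assert point == pytest.approx(
            percent_slowdown(fit.slopes["control"], fit.slopes["diapause"]), abs=1e-9)


class TestConvergenceAndExtrapolation:
    def test_anchored_lines_intersect_near_day_18(self):
        # lines anchored at day 6 at 8.53 and 11.32 with the two aging rates
        i_c = 8.53 - 0.78812 * 6
        i_d = 11.32 - 0.55828 * 6
        day = (i_d - i_c) / (0.78812 - 0.55828)
        assert day == pytest.approx(18.14, abs=0.01)

    def test_parallel_lines_return_none(self):
        pred, day, treat = _data(slope_c=0.7, slope_d=0.7, b_c=1.0, b_d=2.0)
        fit = fit_trajectory(pred, day, treat)
        assert convergence_day(fit) is None

    def test_identical_lines_return_none(self):
        pred, day, treat = _data(slope_c=0.7, slope_d=0.7, b_c=2.0, b_d=2.0)
        fit = fit_trajectory(pred, day, treat)
        assert convergence_day(fit) is None

    def test_fitted_convergence(self):
        pred, day, treat = _data(slope_c=0.8, slope_d=0.56, b_c=4.0, b_d=8.0)
        fit = fit_trajectory(pred, day, treat)
        # 4 + 0.8 d = 8 + 0.56 d  =>  d = 4 / 0.24
        assert convergence_day(fit) == pytest.approx(4 / 0.24, abs=1e-8)

    def test_extrapolation_is_linear(self):
        assert extrapolate_group_age(6.0, 8.53, 0.78812, 30.0) == pytest.approx(27.44, abs=0.005)
        assert extrapolate_group_age(6.0, 11.32, 0.55828, 30.0) == pytest.approx(24.72, abs=0.005)
        assert extrapolate_group_age(6.0, 9.9, 0.0, 25.0) == 9.9

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_group_age(6.0, np.nan, 0.5, 30.0)
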