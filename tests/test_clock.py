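import numpy as np
import pandas as pd
import pytest

from epiclock.clock import (ClockModel, correlation_filter, fit_elastic_net_clock,
                            predict_epigenetic_age, validate_clock)

from _oracles import elastic_net_cd, pearson_r_p


def _props(X, libs=None, sites=None):
    libs = libs or [f"l{i}" for i in range(X.shape[0])]
    sites = sites or [f"chr1:{i+1}" for i in range(X.shape[1])]
    return pd.DataFrame(X, index=libs, columns=sites)


class TestCorrelationFilter:
    def test_perfectly_linear_site_retained(self):
        ages = pd.Series([6.0, 12, 18, 24, 30], index=[f"l{i}" for i in range(5)])
        site = (ages / 100).to_numpy()
        frame = correlation_filter(pd.DataFrame({"l%d" % i: [site[i]] for i in range(5)},
                                                index=["chr1:1"]), ages)
        assert frame.loc["chr1:1", "retained"]
        assert frame.loc["chr1:1", "r"] == pytest.approx(1.0)

    def test_constant_site_excluded(self):
        ages = pd.Series([6.0, 12, 18, 24, 30], index=[f"l{i}" for i in range(5)])
        frame = correlation_filter(pd.DataFrame({f"l{i}": [0.5] for i in range(5)},
                                                index=["chr1:1"]), ages)
        assert not frame.loc["chr1:1", "retained"]
        assert np.isnan(frame.loc["chr1:1", "r"])

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(2)
        libs = [f"l{i}" for i in range(20)]
        ages = pd.Series(np.repeat([6.0, 12, 18, 24, 30], 4), index=libs)
        X = rng.random((30, 20))
        frame = correlation_filter(pd.DataFrame(X, columns=libs,
                                                index=[f"chr1:{i}" for i in range(30)]),
                                   ages, r_min=0.3, p_max=0.05)
        for i in range(30):
            r, p = pearson_r_p(X[i], ages.to_numpy())
            assert frame.iloc[i]["r"] == pytest.approx(r, abs=1e-10)
            assert frame.iloc[i]["p"] == pytest.approx(p, abs=1e-10)
            assert frame.iloc[i]["retained"] == (abs(r) >= 0.3 and p <= 0.05)

    def test_parameter_validation(self):
        ages = pd.Series([6.0, 12, 18], index=["a", "b", "c"])
        props = _props(np.random.default_rng(0).random((3, 2)), libs=["a", "b", "c"]).T
        with pytest.raises(ValueError, match="r_min"):
            correlation_filter(props, ages, r_min=0.0)


class TestElasticNetFit:
    def _ages(self, n=20):
        libs = [f"l{i}" for i in range(n)]
        return pd.Series(np.repeat([6.0, 12, 18, 24, 30], n // 5), index=libs)

    def test_single_perfect_feature_interpolates(self):
        ages = self._ages()
        X = (ages.to_numpy() / 100.0)[:, None]
        model, val = fit_elastic_net_clock(_props(X, libs=list(ages.index)), ages,
                                           lambda_grid=[1e-10], k_folds=5,
                                           repeats=1, seed=0)
        pred = predict_epigenetic_age(model, _props(X, libs=list(ages.index)))
        np.testing.assert_allclose(pred.to_numpy(), ages.to_numpy(), atol=1e-6)

    def test_huge_lambda_gives_null_model(self):
        rng = np.random.default_rng(1)
        ages = self._ages()
        X = rng.random((20, 5))
        model, val = fit_elastic_net_clock(_props(X, libs=list(ages.index)), ages,
                                           lambda_grid=[1e6], k_folds=5,
                                           repeats=1, seed=0)
        assert model.panel() == []
        pred = predict_epigenetic_age(model, _props(X, libs=list(ages.index)))
        np.testing.assert_allclose(pred.to_numpy(), ages.mean(), atol=1e-6)
        assert val.r2 <= 0

    def test_coefficients_match_coordinate_descent_oracle(self):
        rng = np.random.default_rng(4)
        n, p = 10, 3
        libs = [f"l{i}" for i in range(n)]
        ages = pd.Series(np.linspace(6, 30, n), index=libs)
        X = rng.random((n, p)) + 0.3 * ages.to_numpy()[:, None] / 30.0
        lam = 0.05
        model, _ = fit_elastic_net_clock(_props(X, libs=libs), ages,
                                         lambda_grid=[lam], k_folds=2,
                                         repeats=1, seed=0)
        # oracle: standardise, coordinate-descend, back-transform
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        b0, b = elastic_net_cd((X - mu) / sd, ages.to_numpy(), lam, 0.5)
        coef_orig = b / sd
        got = np.array([model.coefficients[s] for s in _props(X, libs=libs).columns])
        np.testing.assert_allclose(got, coef_orig, atol=1e-6)
        expected_intercept = b0 - float(np.sum(b * mu / sd))
        assert model.intercept == pytest.approx(expected_intercept, abs=1e-6)

    def test_panel_size_nonincreasing_in_lambda(self):
        rng = np.random.default_rng(9)
        libs = [f"l{i}" for i in range(20)]
        ages = self._ages()
        X = 0.01 * ages.to_numpy()[:, None] * rng.random(10)[None, :] \
            + 0.02 * rng.random((20, 10))
        from sklearn.linear_model import enet_path
        Xs = (X - X.mean(0)) / X.std(0)
        y = ages.to_numpy()
        lam_max = np.abs(Xs.T @ (y - y.mean())).max() / (len(y) * 0.5)
        grid = np.geomspace(lam_max, 1e-3 * lam_max, 40)
        _, coefs, _ = enet_path(Xs, y - y.mean(), l1_ratio=0.5, alphas=grid)
        sizes = (np.abs(coefs) > 1e-12).sum(axis=0)
        assert (np.diff(sizes) >= 0).all()  # grid is descending in lambda

    def test_predictions_invariant_to_prestandardisation(self):
        rng = np.random.default_rng(12)
        libs = [f"l{i}" for i in range(20)]
        ages = self._ages()
        X = rng.random((20, 4)) + ages.to_numpy()[:, None] / 60.0
        Xs = (X - X.mean(0)) / X.std(0)
        m1, _ = fit_elastic_net_clock(_props(X, libs=libs), ages,
                                      lambda_grid=[0.02], k_folds=4, repeats=1, seed=1)
        m2, _ = fit_elastic_net_clock(_props(Xs, libs=libs), ages,
                                      lambda_grid=[0.02], k_folds=4, repeats=1, seed=1)
        p1 = predict_epigenetic_age(m1, _props(X, libs=libs))
        p2 = predict_epigenetic_age(m2, _props(Xs, libs=libs))
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-8)

    def test_too_many_folds_rejected(self):
        ages = self._ages()
        X = np.random.default_rng(0).random((20, 3))
        with pytest.raises(ValueError, match="k_folds"):
            fit_elastic_net_clock(_props(X, libs=list(ages.index)), ages, k_folds=25)


class TestPredict:
    def _model(self, coefs, intercept=5.0):
        return ClockModel(intercept=intercept, coefficients=coefs, alpha=0.5,
                          lam=0.1, training_libraries=[],
                          feature_means={s: 0.5 for s in coefs},
                          feature_sds={s: 0.1 for s in coefs})

    def test_zero_coefficients_predict_intercept(self):
        model = self._model({"chr1:1": 0.0})
        props = _props(np.array([[0.3], [0.9]]), sites=["chr1:1"])
        pred = predict_epigenetic_age(model, props)
        assert (pred == 5.0).all()

    def test_missing_panel_site_is_error_listing_sites(self):
        model = self._model({"chr1:1": 2.0, "chr1:2": 1.0})
        props = _props(np.array([[0.3], [0.9]]), sites=["chr1:1"])
        with pytest.raises(KeyError, match="chr1:2"):
            predict_epigenetic_age(model, props)

    def test_mean_imputation_mode(self):
        model = self._model({"chr1:1": 2.0, "chr1:2": 10.0})
        props = _props(np.array([[0.3], [0.9]]), sites=["chr1:1"])
        pred = predict_epigenetic_age(model, props, impute="mean")
        np.testing.assert_allclose(pred.to_numpy(),
                                   5.0 + 2.0 * np.array([0.3, 0.9]) + 10.0 * 0.5)

    def test_json_round_trip(self, tmp_path):
        model = self._model({"chr1:1": 2.0})
        model.save(tmp_path / "m.json")
        back = ClockModel.load(tmp_path / "m.json")
        assert back.coefficients == model.coefficients
        assert back.intercept == model.intercept
        assert back.lam == model.lam


class TestValidation:
    def test_perfect_predictions(self):
        ages = pd.Series([6.0, 12, 18, 24, 30])
        v = validate_clock(ages.copy(), ages, group="g")
        assert v.r2 == pytest.approx(1.0) and v.rmse == pytest.approx(0.0)

    def test_mean_predictions_give_zero_r2(self):
        ages = pd.Series([6.0, 12, 18, 24, 30])
        v = validate_clock(pd.Series([18.0] * 5), ages, group="g")
        assert v.r2 == pytest.approx(0.0)

    def test_hand_computed_five_point_fixture(self):
        ages = pd.Series([6.0, 12.0, 18.0, 24.0, 30.0])
        preds = pd.Series([7.0, 11.0, 19.0, 23.0, 31.0])
        # brute-force sums
        ss_res = sum((a - p) ** 2 for a, p in zip(ages, preds))
        ss_tot = sum((a - ages.mean()) ** 2 for a in ages)
        v = validate_clock(preds, ages, group="g")
        assert v.r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)
        assert v.rmse == pytest.approx(np.sqrt(ss_res / 5), abs=1e-12)

    def test_zero_age_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            validate_clock(pd.Series([1.0, 2, 3]), pd.Series([5.0, 5, 5]), group="g")
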