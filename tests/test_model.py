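import numpy as np
import pandas as pd
import pytest

from qsrrkit.model import (QSRRModel, builtin, crossvalidate, external_stats,
                           fit_ols, predict, standardized_coefficients,
                           validate, y_randomization)


class TestFitOLS:
    def test_exact_line(self):
        x = np.arange(10.0)
        model = fit_ols(x[:, None], 2.0 * x + 1.0)
        assert model.intercept == pytest.approx(1.0)
        assert model.coefficients[0] == pytest.approx(2.0)
        assert model.r2 == pytest.approx(1.0)
        assert model.rmsec == pytest.approx(0.0, abs=1e-12)

    def test_five_point_normal_equation_oracle(self):
        # closed-form simple-regression slope/intercept on a hand dataset
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 3.9, 6.2, 8.1, 9.8])
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        model = fit_ols(x[:, None], y)
        assert model.coefficients[0] == pytest.approx(slope, abs=1e-12)
        assert model.intercept == pytest.approx(intercept, abs=1e-12)

    def test_rmsec_uses_divisor_n(self, rng):
        X = rng.normal(size=(30, 2))
        y = X @ np.array([1.0, 2.0]) + rng.normal(0, 1.0, 30)
        model = fit_ols(X, y)
        resid = y - predict(model, X)
        assert model.rmsec == pytest.approx(np.sqrt((resid**2).mean()))

    def test_collinear_columns_named(self, rng):
        x = rng.normal(size=25)
        X = np.column_stack([x, 2.0 * x])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_ols(X, rng.normal(size=25))

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_ols(rng.normal(size=(3, 2)), np.zeros(3))


class TestPredict:
    def test_builtin_intercept_at_origin(self):
        model = builtin("hp5ms")
        assert predict(model, np.zeros((1, 3)))[0] == pytest.approx(428.2)

    def test_builtin_unit_eta(self):
        model = builtin("hp5ms")
        assert predict(model, np.array([[1.0, 0.0, 0.0]]))[0] \
            == pytest.approx(554.9)

    def test_duplicated_row_duplicated_prediction(self, rng):
        model = builtin("hp5ms")
        row = rng.normal(size=3)
        pred = predict(model, np.vstack([row, row]))
        assert pred[0] == pred[1]

    def test_name_matching_reorders_columns(self):
        model = builtin("hp5ms")
        df = pd.DataFrame([[0.1, 2.0, 1.0]],
                          columns=["MATS1p", "MDEC-22", "Eta_betaS"])
        expected = 428.2 + 126.7 * 1.0 + 13.8 * 2.0 + 627.1 * 0.1
        assert predict(model, df)[0] == pytest.approx(expected)

    def test_missing_descriptor_rejected(self):
        model = builtin("hp5ms")
        df = pd.DataFrame([[1.0, 2.0]], columns=["Eta_betaS", "MDEC-22"])
        with pytest.raises(KeyError):
            predict(model, df)

    def test_affine_in_inputs(self, rng):
        model = builtin("hp5ms")
        a, b = rng.normal(size=(2, 3))
        lhs = predict(model, (a + b)[None, :])[0] + model.intercept
        rhs = predict(model, a[None, :])[0] + predict(model, b[None, :])[0]
        assert lhs == pytest.approx(rhs)

    def test_unknown_builtin_rejected(self):
        with pytest.raises(KeyError):
            builtin("nope")


class TestStandardizedCoefficients:
    def test_single_predictor_equals_pearson_r(self, rng):
        x = rng.normal(size=50)
        y = 0.8 * x + rng.normal(0, 0.5, 50)
        model = fit_ols(x[:, None], y)
        beta = standardized_coefficients(model, x[:, None], y)
        r = np.corrcoef(x, y)[0, 1]
        assert beta[0] == pytest.approx(r, abs=1e-12)

    def test_scale_invariance(self, rng):
        X = rng.normal(size=(40, 2))
        y = X @ np.array([3.0, -1.0]) + rng.normal(0, 0.5, 40)
        beta1 = standardized_coefficients(fit_ols(X, y), X, y)
        X2 = X.copy()
        X2[:, 0] *= 10.0
        beta2 = standardized_coefficients(fit_ols(X2, y), X2, y)
        np.testing.assert_allclose(beta1, beta2, atol=1e-10)

    def test_zero_variance_response_rejected(self, rng):
        X = rng.normal(size=(10, 1))
        model = builtin("hp5ms")
        with pytest.raises(ValueError):
            standardized_coefficients(model, np.zeros((10, 3)), np.ones(10))


class TestCrossvalidate:
    @pytest.mark.parametrize("protocol", ["LOO", "venetian5", "blocks5",
                                          "montecarlo", "bootstrap"])
    def test_perfect_linear_data(self, protocol, rng):
        X = rng.normal(size=(30, 2))
        y = X @ np.array([2.0, 1.0]) + 5.0
        r2cv, rmsecv = crossvalidate(X, y, protocol, iterations=20, seed=1)
        assert r2cv == pytest.approx(1.0, abs=1e-8)
        assert rmsecv == pytest.approx(0.0, abs=1e-6)

    def test_loo_matches_hat_matrix_shortcut(self, rng):
        # closed form: e_i / (1 - h_ii) for OLS leave-one-out residuals
        X = rng.normal(size=(25, 2))
        y = X @ np.array([1.5, -2.0]) + rng.normal(0, 1.0, 25)
        A = np.column_stack([np.ones(25), X])
        H = A @ np.linalg.inv(A.T @ A) @ A.T
        e = y - H @ y
        loo_resid = e / (1 - np.diag(H))
        press = (loo_resid**2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2cv, rmsecv = crossvalidate(X, y, "LOO")
        assert r2cv == pytest.approx(1 - press / ss_tot, abs=1e-10)
        assert rmsecv == pytest.approx(np.sqrt(press / 25), abs=1e-10)

    def test_optimism_inequality(self, planted_small):
        mat, y = planted_small
        X = mat.values.to_numpy()[:, :2]
        model = fit_ols(X, y)
        for protocol in ("LOO", "venetian5", "blocks5"):
            _, rmsecv = crossvalidate(X, y, protocol)
            assert model.rmsec <= rmsecv

    def test_small_fold_rejected(self, rng):
        X = rng.normal(size=(6, 3))
        y = rng.normal(size=6)
        with pytest.raises(ValueError):
            crossvalidate(X, y, "venetian5")

    def test_unknown_protocol_rejected(self, rng):
        with pytest.raises(ValueError):
            crossvalidate(rng.normal(size=(20, 1)), rng.normal(size=20),
                          "leave-some-in")


class TestYRandomization:
    def test_intercept_only_model_r2_zero(self, rng):
        X = np.empty((15, 0))
        mean_r2, _ = y_randomization(X, rng.normal(size=15), iterations=5,
                                     seed=0)
        assert mean_r2 == pytest.approx(0.0, abs=1e-12)

    def test_null_expectation_k_over_n_minus_1(self, rng):
        # under permutation R^2 ~ Beta(k/2, (n-k-1)/2): mean k/(n-1)
        n, k, iters = 186, 3, 400
        X = rng.normal(size=(n, k))
        y = rng.normal(size=n)
        mean_r2, _ = y_randomization(X, y, iterations=iters, seed=3)
        expected = k / (n - 1)
        var = 2 * k * (n - k - 1) / ((n - 1) ** 2 * (n + 1))
        se = np.sqrt(var / iters)
        assert abs(mean_r2 - expected) <= 3 * se

    def test_destroys_real_correlation(self, planted_small):
        mat, y = planted_small
        X = mat.values.to_numpy()[:, :2]
        model = fit_ols(X, y)
        mean_r2, mean_rmse = y_randomization(X, y, iterations=100, seed=1)
        assert mean_r2 < 0.2 < model.r2
        assert mean_rmse > model.rmsec

    def test_zero_iterations_rejected(self, rng):
        with pytest.raises(ValueError):
            y_randomization(rng.normal(size=(10, 1)), np.zeros(10), 0)


class TestExternalStats:
    def test_perfect_predictions(self, planted_small):
        mat, y = planted_small
        X = mat.values.to_numpy()[:, :2]
        exact = fit_ols(X, X @ np.array([2.0, 3.0]) + 1.0)
        q2, rmsep = external_stats(exact, X, X @ np.array([2.0, 3.0]) + 1.0)
        assert q2 == pytest.approx(1.0)
        assert rmsep == pytest.approx(0.0, abs=1e-10)

    def test_mean_prediction_gives_zero(self, rng):
        # predicting the training mean for the training set itself
        y = rng.normal(size=20)
        model = QSRRModel(descriptor_names=("d",), intercept=float(y.mean()),
                          coefficients=np.array([0.0]), n_train=20,
                          y_train_mean=float(y.mean()),
                          y_train_ss=float(((y - y.mean()) ** 2).sum()),
                          r2=0.0, rmsec=float(y.std()))
        q2, _ = external_stats(model, rng.normal(size=(20, 1)), y)
        assert q2 == pytest.approx(0.0, abs=1e-12)

    def test_empty_external_rejected(self):
        with pytest.raises(ValueError):
            external_stats(builtin("hp5ms"), np.empty((0, 3)), np.array([]))


class TestReportAndSerialization:
    def test_model_json_round_trip(self, tmp_path, planted_small):
        mat, y = planted_small
        X = mat.values.to_numpy()[:, :2]
        model = fit_ols(X, y, ["true1", "true2"])
        path = tmp_path / "model.json"
        model.to_json(path)
        back = QSRRModel.from_json(path)
        assert back.descriptor_names == model.descriptor_names
        np.testing.assert_allclose(back.coefficients, model.coefficients)
        assert back.rmsec == pytest.approx(model.rmsec)

    def test_validate_collects_all_sections(self, tmp_path, planted_small):
        mat, y = planted_small
        X = mat.values.to_numpy()[:, :2]
        report = validate(X[:40], y[:40], ["true1", "true2"],
                          protocols=("LOO", "venetian5"), iterations=20,
                          seed=2, X_ext=X[40:], y_ext=y[40:])
        assert set(report.crossval) == {"LOO", "venetian5"}
        assert report.y_randomization["iterations"] == 20
        assert report.external["n_external"] == 20
        report.to_json(tmp_path / "report.json")
        assert (tmp_path / "report.json").exists()
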