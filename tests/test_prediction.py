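import numpy as np
import pandas as pd
import pytest

from speechtrf.prediction import (
    PredictionError,
    contributions,
    correlate,
    evaluate,
    fit_lasso,
    lasso_path,
    nested_cv_predict,
    screen_features,
    selected_columns,
    zscore,
)


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert correlate(x, 2 * x + 1).r == pytest.approx(1.0)
        assert correlate(x, -x).r == pytest.approx(-1.0)

    def test_four_point_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        assert correlate(x, y).r == pytest.approx(0.6)
        assert correlate(x, y, "spearman").rho == pytest.approx(0.6)

    def test_ci_contains_r(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        res = correlate(x, y)
        assert res.ci95[0] <= res.r <= res.ci95[1]

    def test_zero_variance_rejected(self):
        with pytest.raises(PredictionError):
            correlate(np.ones(5), np.arange(5.0))


class TestScreenFeatures:
    def _table(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
        df = pd.DataFrame({
            "featA.Cz": -0.7 * z + 0.4 * rng.standard_normal(n),
            "featA.Pz": -0.4 * z + 0.8 * rng.standard_normal(n),
            "featB.Cz": rng.standard_normal(n),
            "score": 539.1 + 67.4 * z,
        })
        return df

    def test_strong_feature_kept_best_channel(self):
        sel = screen_features(self._table(), 0.2)
        assert len(sel) == 1
        assert sel[0].feature == "featA"
        assert sel[0].channel == "Cz"  # highest |r| among passing channels

    def test_threshold_boundary_inclusive(self):
        """A feature whose |r| equals the threshold exactly is kept."""
        rng = np.random.default_rng(3)
        n = 200
        z = rng.standard_normal(n)
        zc = (z - z.mean()) / z.std()
        e = rng.standard_normal(n)
        e = e - zc * (zc @ e) / n  # orthogonalise against the score
        e = (e - e.mean()) / e.std()
        x = -0.2 * zc + np.sqrt(1 - 0.04) * e
        df = pd.DataFrame({"f.Cz": x, "score": zc})
        r_obs = correlate(x, zc).r
        assert r_obs == pytest.approx(-0.2, abs=1e-9)
        sel = screen_features(df, abs(r_obs))  # threshold == |r|: inclusive
        assert len(sel) == 1 and sel[0].feature == "f"

    def test_subthreshold_dropped(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"f.Cz": rng.standard_normal(500),
                           "score": rng.standard_normal(500)})
        assert screen_features(df, 0.2) == []


class TestZscore:
    def test_hand_computed_column(self):
        df = pd.DataFrame({"a.Cz": [1.0, 2.0, 3.0], "score": [1, 2, 3]})
        out = zscore(df, ["a.Cz"])
        np.testing.assert_allclose(out["a.Cz"], [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"a.Cz": rng.standard_normal(40)})
        once = zscore(df, ["a.Cz"])
        twice = zscore(once, ["a.Cz"])
        np.testing.assert_allclose(once["a.Cz"], twice["a.Cz"], atol=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(PredictionError):
            zscore(pd.DataFrame({"a.Cz": [1.0, 1.0, 1.0]}), ["a.Cz"])


class TestFitLasso:
    def test_lambda_zero_equals_ols(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        m = fit_lasso(X, y, 0.0)
        Xi = np.column_stack([np.ones(30), X])
        ref = np.linalg.lstsq(Xi, y, rcond=None)[0]
        np.testing.assert_allclose(m.beta, ref[1:], atol=1e-8)
        assert m.beta0 == pytest.approx(ref[0], abs=1e-8)

    def test_lambda_max_gives_null_model(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        Xc = X - X.mean(axis=0)
        lam_max = np.abs(Xc.T @ (y - y.mean())).max() / 40
        m = fit_lasso(X, y, lam_max * 1.0001)
        assert np.all(m.beta == 0.0)
        assert m.beta0 == pytest.approx(y.mean())

    def test_kkt_subgradient_conditions(self):
        """Stationarity of the 1/(2N) objective at the CD solution."""
        rng = np.random.default_rng(8)
        for trial in range(10):
            X = rng.standard_normal((20, 5))
            y = rng.standard_normal(20)
            lam = float(rng.uniform(0.02, 0.5))
            m = fit_lasso(X, y, lam)
            resid = y - m.beta0 - X @ m.beta
            grad = X.T @ resid / 20
            for j in range(5):
                if m.beta[j] != 0.0:
                    assert grad[j] == pytest.approx(
                        lam * np.sign(m.beta[j]), abs=1e-6)
                else:
                    assert abs(grad[j]) <= lam + 1e-6

    def test_matches_sklearn_objective(self):
        """Independent cross-check against scikit-learn's LASSO solver."""
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(9)
        X = rng.standard_normal((50, 8))
        y = X[:, 0] - 2 * X[:, 3] + rng.standard_normal(50)
        for lam in (0.05, 0.3, 1.0):
            ours = fit_lasso(X, y, lam)
            ref = sklearn.Lasso(alpha=lam, fit_intercept=True,
                                tol=1e-10, max_iter=100000).fit(X, y)
            np.testing.assert_allclose(ours.beta, ref.coef_, atol=1e-5)
            assert ours.beta0 == pytest.approx(ref.intercept_, abs=1e-5)

    def test_path_support_monotone_in_lambda(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((40, 6))
        y = X @ rng.standard_normal(6) + 0.1 * rng.standard_normal(40)
        Xc = X - X.mean(axis=0)
        lam_max = np.abs(Xc.T @ (y - y.mean())).max() / 40
        grid = np.linspace(1e-4, lam_max * 1.1, 30)
        betas = lasso_path(X, y, grid)
        nnz = (np.abs(betas) > 1e-10).sum(axis=1)
        # smoothed check: support size non-increasing along increasing lambda
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))


class TestNestedCv:
    def _linear_table(self, n=30, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 3))
        y = 500 + 30 * X[:, 0] - 20 * X[:, 1] + 10 * X[:, 2] \
            + noise * rng.standard_normal(n)
        df = pd.DataFrame(X, columns=["a.Cz", "b.Cz", "c.Cz"])
        df["score"] = y
        return df

    def test_single_lambda_grid_reduces_to_loocv(self):
        df = self._linear_table()
        res = nested_cv_predict(df, ["a.Cz", "b.Cz", "c.Cz"],
                                grid=np.array([0.1]), seed=1)
        assert np.all(res.fold_lambdas == 0.1)
        assert res.predicted.size == 30

    def test_noiseless_linear_recovery(self):
        df = self._linear_table(noise=0.0)
        res = nested_cv_predict(df, ["a.Cz", "b.Cz", "c.Cz"],
                                grid=np.linspace(0.0, 5.0, 50), seed=2)
        np.testing.assert_allclose(res.predicted, df["score"], atol=1e-3)

    def test_same_seed_identical(self):
        df = self._linear_table(noise=5.0)
        a = nested_cv_predict(df, ["a.Cz", "b.Cz", "c.Cz"],
                              grid=np.linspace(0.0, 5.0, 20), seed=3)
        b = nested_cv_predict(df, ["a.Cz", "b.Cz", "c.Cz"],
                              grid=np.linspace(0.0, 5.0, 20), seed=3)
        np.testing.assert_array_equal(a.predicted, b.predicted)
        np.testing.assert_array_equal(a.fold_lambdas, b.fold_lambdas)

    def test_too_few_participants_rejected(self):
        df = self._linear_table(n=8)
        with pytest.raises(PredictionError):
            nested_cv_predict(df, ["a.Cz"], inner_folds=10)


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = evaluate(y, y)
        assert m["r"] == pytest.approx(1.0) and m["mad"] == 0.0

    def test_constant_offset(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = evaluate(y, y + 10)
        assert m["mad"] == pytest.approx(10.0)
        assert m["mad_sd"] == pytest.approx(0.0)
        assert m["r"] == pytest.approx(1.0)

    def test_hand_checkable_metrics(self):
        true = np.array([0.0, 1.0, 2.0, 3.0])
        pred = np.array([1.0, 1.0, 1.0, 5.0])
        m = evaluate(true, pred)
        assert m["mad"] == pytest.approx((1 + 0 + 1 + 2) / 4)
        assert m["rmse"] == pytest.approx(np.sqrt((1 + 0 + 1 + 4) / 4))


class TestContributions:
    def _model(self, beta):
        from speechtrf.prediction import LassoModel
        return LassoModel(0.0, np.asarray(beta, float), 1.0, 10,
                          feature_names=[f"f{i}" for i in range(len(beta))])

    def test_single_model_normalised(self):
        out = contributions([self._model([2.0, -1.0])])
        assert out == {"f0": 1.0, "f1": 0.5}

    def test_never_selected_is_zero(self):
        out = contributions([self._model([2.0, 0.0]),
                             self._model([4.0, 0.0])])
        assert out["f1"] == 0.0

    def test_average_then_normalise(self):
        out = contributions([self._model([2.0, 0.0]),
                             self._model([0.0, 2.0])])
        assert out == {"f0": 1.0, "f1": 1.0}

    def test_all_zero_coefficients(self):
        out = contributions([self._model([0.0, 0.0])])
        assert out == {"f0": 0.0, "f1": 0.0}
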