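"""SIMPLS core against closed-form and NIPALS oracles."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from mirhp.pls import (
    export_coefficients,
    fit_simpls,
    predict,
    select_latent_variables,
)


def _random_problem(seed, n=20, p=8, noise=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + noise * rng.normal(size=n)
    return X, y


class TestFit:
    def test_single_column_equals_ols_slope(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = 2.5 * x + rng.normal(size=30)
        model = fit_simpls(x[:, None], y, 1)
        xc = x - x.mean()
        slope = (xc @ (y - y.mean())) / (xc @ xc)
        assert model.coefficients(1)[0] == pytest.approx(slope, rel=1e-10)

    def test_exact_fit_at_full_rank(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 7.0
        model = fit_simpls(X, y, 4)
        resid = y - predict(model, X, model.n_lv_max)
        assert np.abs(resid).max() < 1e-8

    @pytest.mark.parametrize("seed", range(50))
    def test_full_lv_matches_minimum_norm_least_squares(self, seed):
        X, y = _random_problem(seed)
        model = fit_simpls(X, y, 8)
        beta = np.linalg.pinv(X - X.mean(0)) @ (y - y.mean())
        assert np.abs(model.coefficients(model.n_lv_max) - beta).max() < 1e-8

    @pytest.mark.parametrize("seed", range(50))
    def test_predictions_match_nipals_oracle_at_every_lv(self, seed):
        X, y = _random_problem(seed)
        model = fit_simpls(X, y, 8)
        for k in range(1, model.n_lv_max + 1):
            oracle = PLSRegression(n_components=k, scale=False).fit(X, y[:, None])
            assert np.abs(predict(model, X, k) - oracle.predict(X).ravel()).max() < 1e-6

    def test_score_orthonormality(self):
        X, y = _random_problem(3, n=40, p=12)
        model = fit_simpls(X, y, 12)
        gram = model.scores.T @ model.scores
        assert np.abs(gram - np.eye(model.n_lv_max)).max() < 1e-8

    def test_training_rmse_non_increasing_in_lv(self):
        X, y = _random_problem(4, n=40, p=12)
        model = fit_simpls(X, y, 12)
        rmses = [
            np.sqrt(np.mean((y - predict(model, X, k)) ** 2))
            for k in range(1, model.n_lv_max + 1)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(rmses, rmses[1:]))

    def test_coefficient_path_reproduces_score_reconstruction(self):
        X, y = _random_problem(5)
        model = fit_simpls(X, y, 8)
        Xc = X - model.x_mean
        for k in range(1, model.n_lv_max + 1):
            via_scores = model.scores[:, :k] @ model.y_loadings[:k] + model.y_mean
            via_path = predict(model, X, k)
            assert np.abs(via_scores - via_path).max() < 1e-8

    def test_predictor_scale_equivariance_at_full_rank(self):
        # PLS latent directions are scale-dependent at intermediate LV counts;
        # equivariance holds at the full-LV solution, which equals OLS.
        X, y = _random_problem(6)
        c = 3.7
        X2 = X.copy()
        X2[:, 2] *= c
        m1, m2 = fit_simpls(X, y, 8), fit_simpls(X2, y, 8)
        k = min(m1.n_lv_max, m2.n_lv_max)
        assert np.allclose(predict(m1, X, k), predict(m2, X2, k), atol=1e-8)
        assert m2.coefficients(k)[2] == pytest.approx(m1.coefficients(k)[2] / c, rel=1e-6)

    def test_zero_variance_column_gets_zero_weight(self):
        X, y = _random_problem(7)
        X = np.hstack([X, np.full((X.shape[0], 1), 2.0)])
        model = fit_simpls(X, y, 8)
        assert np.all(model.coefficient_path[:, -1] == 0)

    def test_constant_response_rejected(self):
        X, _ = _random_problem(8)
        with pytest.raises(ValueError, match="zero variance"):
            fit_simpls(X, np.full(20, 3.0), 2)

    def test_rank_truncation_warns(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=(20, 2))
        X = base @ rng.normal(size=(2, 6))  # rank 2
        y = X @ rng.normal(size=6) + 0.1 * rng.normal(size=20)
        with pytest.warns(RuntimeWarning, match="truncating"):
            model = fit_simpls(X, y, 6)
        assert model.n_lv_max <= 2


class TestPredict:
    def test_mean_row_predicts_mean_response(self):
        X, y = _random_problem(10)
        model = fit_simpls(X, y, 4)
        assert predict(model, model.x_mean[None, :], 4)[0] == pytest.approx(
            model.y_mean, abs=1e-10
        )

    def test_affine_in_rows(self):
        X, y = _random_problem(11)
        model = fit_simpls(X, y, 4)
        a, b = X[0], X[1]
        mid = predict(model, (0.5 * (a + b))[None, :], 4)[0]
        assert mid == pytest.approx(
            0.5 * (predict(model, a[None, :], 4)[0] + predict(model, b[None, :], 4)[0]),
            rel=1e-10,
        )

    def test_dimension_mismatch_rejected(self):
        X, y = _random_problem(12)
        model = fit_simpls(X, y, 2)
        with pytest.raises(ValueError):
            predict(model, np.zeros((3, 5)), 2)


class TestLVSelection:
    @pytest.mark.parametrize(
        "curve, expected",
        [([5, 3, 4], 2), ([3, 3, 5], 1), ([9, 7, 5, 3], 4)],
        ids=["interior-min", "tie-toward-fewer", "strictly-decreasing"],
    )
    def test_global_minimum_ties_to_fewer(self, curve, expected):
        assert select_latent_variables(np.array(curve, dtype=float)) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_latent_variables(np.array([]))


class TestExportCoefficients:
    def test_single_column_slope(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=25)
        y = -1.3 * x + 0.1 * rng.normal(size=25)
        model = fit_simpls(x[:, None], y, 1)
        table = export_coefficients(model, 1, np.array([1750.0]))
        xc = x - x.mean()
        assert table["coefficient"][0] == pytest.approx(
            (xc @ (y - y.mean())) / (xc @ xc), rel=1e-10
        )

    def test_column_permutation_permutes_coefficients(self):
        X, y = _random_problem(14)
        perm = np.array([3, 1, 0, 2, 7, 6, 5, 4])
        m1 = fit_simpls(X, y, 8)
        m2 = fit_simpls(X[:, perm], y, 8)
        assert np.allclose(
            m2.coefficients(m2.n_lv_max), m1.coefficients(m1.n_lv_max)[perm], atol=1e-8
        )
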