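"""PLS (NIPALS) and LS-SVM fitting, prediction and hyperparameter selection."""

import numpy as np
import pytest

from leafspec import (
    ConfigError,
    ModelError,
    grid_search_lssvm,
    lssvm_fit,
    lssvm_predict,
    pls_fit,
    pls_predict,
    select_pcs_cv,
)
from leafspec.regression import kfold_indices, rbf_kernel


class TestPLS:
    def test_single_column_proportional_target_is_exact(self):
        X = np.array([[1.0], [2.0], [3.0], [5.0]])
        y = 3.0 * X[:, 0]
        model = pls_fit(X, y, 1)
        Xnew = np.array([[4.0], [10.0]])
        np.testing.assert_allclose(pls_predict(model, Xnew), [12.0, 30.0], atol=1e-10)

    def test_full_rank_pls_equals_ols(self, rng):
        # Normal-equations oracle on 20 random full-rank problems.
        for _ in range(20):
            n, p = rng.integers(12, 30), rng.integers(2, 8)
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            model = pls_fit(X, y, int(p))
            Xc = X - X.mean(axis=0)
            beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
            Xnew = rng.normal(size=(5, p))
            ols_pred = (Xnew - X.mean(axis=0)) @ beta + y.mean()
            np.testing.assert_allclose(pls_predict(model, Xnew), ols_pred, atol=1e-8)

    def test_training_rmse_never_increases_with_components(self, rng):
        X = rng.normal(size=(25, 10))
        y = rng.normal(size=25)
        errs = []
        model = pls_fit(X, y, 8)
        for k in range(1, model.n_components + 1):
            pred = pls_predict(model, X, n_components=k)
            errs.append(float(np.sqrt(((pred - y) ** 2).mean())))
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_latent_path_equals_coefficient_path(self, rng):
        X = rng.normal(size=(20, 12))
        y = rng.normal(size=20)
        model = pls_fit(X, y, 5)
        # Latent route: scores T = Xc W (P^T W)^-1, prediction ym + T q.
        Xc = X - model.x_mean
        T = Xc @ model.weights @ np.linalg.inv(model.x_loadings.T @ model.weights)
        latent = model.y_mean + T @ model.y_loadings
        np.testing.assert_allclose(latent, pls_predict(model, X), atol=1e-10)

    def test_matches_sklearn_pls1(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(30, 15))
        y = rng.normal(size=30)
        for k in (1, 3, 6):
            ours = pls_predict(pls_fit(X, y, k), X)
            ref = PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(ours, ref.predict(X).ravel(), atol=1e-8)

    def test_predict_at_training_mean_returns_y_mean(self, rng):
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        model = pls_fit(X, y, 3)
        assert pls_predict(model, X.mean(axis=0))[0] == pytest.approx(y.mean())

    def test_zero_variance_target_errors(self, rng):
        with pytest.raises(ModelError):
            pls_fit(rng.normal(size=(10, 3)), np.full(10, 2.0), 2)

    def test_component_budget_enforced(self, rng):
        with pytest.raises(ConfigError):
            pls_fit(rng.normal(size=(5, 10)), rng.normal(size=5), 5)  # > n-1


class TestSelectPcsCV:
    def test_perfect_one_component_data_selects_one(self, rng):
        t = rng.normal(size=30)
        X = np.outer(t, rng.uniform(0.5, 1.5, size=8))  # rank-1 design
        y = 2.0 + 3.0 * t
        best, _ = select_pcs_cv(X, y, max_pcs=6, folds=5, seed=0)
        assert best == 1

    def test_matches_bruteforce_cv_oracle(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        folds = kfold_indices(12, 4, seed=9)
        best, best_rmse = select_pcs_cv(X, y, max_pcs=4, fold_plan=folds)
        # Oracle: refit from scratch per fold and per component count.
        per_k = []
        for k in range(1, 5):
            sq = []
            for val in folds:
                train = np.setdiff1d(np.arange(12), val)
                model = pls_fit(X[train], y[train], k)
                sq.extend((pls_predict(model, X[val]) - y[val]) ** 2)
            per_k.append(float(np.sqrt(np.mean(sq))))
        assert best == int(np.argmin(per_k)) + 1
        assert best_rmse == pytest.approx(min(per_k), abs=1e-10)


class TestLSSVM:
    def test_kkt_residual_on_random_fixtures(self, rng):
        for _ in range(5):
            X = rng.normal(size=(20, 6))
            y = rng.normal(size=20)
            model = lssvm_fit(X, y, gamma=10.0, sigma2=4.0)
            K = rbf_kernel(X, X, 4.0)
            top = model.alpha.sum()
            rows = model.b + (K + np.eye(20) / 10.0) @ model.alpha - y
            assert abs(top) <= 1e-8
            assert np.abs(rows).max() <= 1e-8

    def test_interpolation_limit_at_huge_gamma(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        model = lssvm_fit(X, y, gamma=1e10, sigma2=2.0)
        np.testing.assert_allclose(lssvm_predict(model, X), y, atol=1e-4)

    def test_two_sample_fixture_against_direct_solve(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([1.0, 3.0])
        gamma, sigma2 = 2.0, 1.0
        model = lssvm_fit(X, y, gamma, sigma2)
        k = np.exp(-1.0)  # K(x0, x1) with d^2 = 1
        A = np.array([[0.0, 1.0, 1.0],
                      [1.0, 1.0 + 0.5, k],
                      [1.0, k, 1.0 + 0.5]])
        b, a0, a1 = np.linalg.solve(A, [0.0, 1.0, 3.0])
        assert model.b == pytest.approx(b, abs=1e-10)
        np.testing.assert_allclose(model.alpha, [a0, a1], atol=1e-10)
        # manual kernel arithmetic at a new point
        xnew = np.array([[0.5]])
        expect = a0 * np.exp(-0.25) + a1 * np.exp(-0.25) + b
        assert lssvm_predict(model, xnew)[0] == pytest.approx(expect, abs=1e-10)

    def test_sample_reordering_invariance(self, rng):
        X = rng.normal(size=(18, 5))
        y = rng.normal(size=18)
        perm = rng.permutation(18)
        m1 = lssvm_fit(X, y, 8.0, 2.0)
        m2 = lssvm_fit(X[perm], y[perm], 8.0, 2.0)
        Xnew = rng.normal(size=(6, 5))
        np.testing.assert_allclose(
            lssvm_predict(m1, Xnew), lssvm_predict(m2, Xnew), atol=1e-8
        )

    def test_invalid_hyperparameters_error(self, rng):
        X, y = rng.normal(size=(5, 2)), rng.normal(size=5)
        with pytest.raises(ConfigError):
            lssvm_fit(X, y, gamma=-1.0, sigma2=1.0)
        with pytest.raises(ConfigError):
            lssvm_fit(X, y, gamma=1.0, sigma2=0.0)


class TestGridSearch:
    def test_single_point_grid_returns_it(self, rng):
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        g, s2, _ = grid_search_lssvm(X, y, gamma_grid=[3.0], sigma2_grid=[7.0],
                                     folds=4, seed=0)
        assert (g, s2) == (3.0, 7.0)

    def test_returned_pair_attains_the_grid_minimum(self, rng):
        X = rng.normal(size=(24, 5))
        y = X[:, 0] ** 2 + 0.1 * rng.normal(size=24)
        gamma_grid = [0.5, 8.0, 128.0]
        sigma2_grid = [0.5, 4.0, 32.0]
        folds = kfold_indices(24, 4, seed=3)
        g, s2, best_rmse = grid_search_lssvm(
            X, y, gamma_grid, sigma2_grid, fold_plan=folds
        )
        for gg in gamma_grid:  # exhaustive recheck
            for ss in sigma2_grid:
                sq, cnt = 0.0, 0
                for val in folds:
                    train = np.setdiff1d(np.arange(24), val)
                    m = lssvm_fit(X[train], y[train], gg, ss)
                    sq += float(((lssvm_predict(m, X[val]) - y[val]) ** 2).sum())
                    cnt += val.size
                assert best_rmse <= np.sqrt(sq / cnt) + 1e-9
        assert (g, s2) in [(gg, ss) for gg in gamma_grid for ss in sigma2_grid]

    def test_smooth_planted_data_selects_interior_sigma2(self, default_swir):
        from leafspec import snv

        sm, truth = default_swir
        X = snv(sm)[0].values[:60, ::8]
        y = truth.protein_per_sample[:60]
        g, s2, _ = grid_search_lssvm(X, y, folds=5, seed=0)
        from leafspec.regression import DEFAULT_SIGMA2_GRID

        assert DEFAULT_SIGMA2_GRID[0] < s2 < DEFAULT_SIGMA2_GRID[-1]
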