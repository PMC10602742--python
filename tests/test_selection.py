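"""SPA, CARS and random frog selectors and the shared RMSECV criterion."""

import numpy as np
import pytest

from leafspec import (
    ConfigError,
    cars_retention_schedule,
    cars_select,
    frog_select,
    rmsecv,
    spa_select,
)
from leafspec.regression import kfold_indices
from leafspec.selection import spa_chain


class TestRmsecv:
    def test_noiseless_linear_band_gives_zero_error(self, rng):
        X = rng.normal(size=(20, 6))
        y = 4.0 * X[:, 2] + 1.0
        score, pcs = rmsecv(X, y, [2], max_pcs=3, folds=5, seed=0)
        assert score <= 1e-8
        assert pcs == 1

    def test_nonnegative_and_deterministic_in_seed(self, rng):
        X = rng.normal(size=(15, 8))
        y = rng.normal(size=15)
        a = rmsecv(X, y, [0, 3, 5], max_pcs=4, folds=5, seed=7)
        b = rmsecv(X, y, [0, 3, 5], max_pcs=4, folds=5, seed=7)
        assert a == b
        assert a[0] >= 0

    def test_two_fold_single_component_matches_hand_computation(self):
        # X one column [1,2,3,4], y = x^2; folds {0,1} and {2,3}.
        # Training on {2,3}: centred slope 7, predictions at 1,2 -> -5, 2.
        # Training on {0,1}: slope 3, predictions at 3,4 -> 7, 10.
        # RMSECV = sqrt((36+4+4+36)/4) = sqrt(20).
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([1.0, 4.0, 9.0, 16.0])
        fold_plan = [np.array([0, 1]), np.array([2, 3])]
        score, pcs = rmsecv(X, y, [0], max_pcs=1, fold_plan=fold_plan)
        assert score == pytest.approx(np.sqrt(20.0), abs=1e-10)
        assert pcs == 1

    def test_empty_subset_errors(self, rng):
        with pytest.raises(ConfigError):
            rmsecv(rng.normal(size=(10, 3)), rng.normal(size=10), [])


def oracle_spa_chain(X, start, k_max):
    """From-scratch orthogonalization oracle: residual norms recomputed with
    lstsq projections each step (no incremental updates)."""
    chain = [start]
    for _ in range(1, k_max):
        S = X[:, chain]
        best_j, best_norm = None, 1e-12
        for j in range(X.shape[1]):
            if j in chain:
                continue
            coef, *_ = np.linalg.lstsq(S, X[:, j], rcond=None)
            resid = X[:, j] - S @ coef
            norm = float(np.linalg.norm(resid))
            if norm > best_norm:
                best_norm, best_j = norm, j
        if best_j is None:
            break
        chain.append(best_j)
    return chain


class TestSPA:
    def test_orthogonal_columns_first_pick_is_max_norm(self):
        X = np.diag([1.0, 5.0, 2.0, 3.0])
        chain = spa_chain(X, start=0, k_max=2)
        assert chain[1] == 1  # the norm-5 column

    def test_chain_matches_orthogonalization_oracle(self, rng):
        for _ in range(8):
            n, p = int(rng.integers(6, 13)), int(rng.integers(3, 9))
            X = rng.normal(size=(n, p))
            for start in range(p):
                assert spa_chain(X, start, p) == oracle_spa_chain(X, start, p)

    def test_duplicated_column_never_selected_twice(self, rng):
        x = rng.normal(size=10)
        X = np.column_stack([x, rng.normal(size=10), x, rng.normal(size=10)])
        chain = spa_chain(X, start=0, k_max=4)
        assert 2 not in chain  # duplicate of the start column has zero residual

    def test_selects_informative_band_and_is_seed_stable(self, small_swir):
        sm, truth = small_swir
        y = truth.protein_per_sample
        a = spa_select(sm.values, y, k_min=2, k_max=6, seed=5, max_pcs=5)
        b = spa_select(sm.values, y, k_min=2, k_max=6, seed=5, max_pcs=5)
        np.testing.assert_array_equal(a.indices, b.indices)
        wl = sm.wavelengths[a.indices]
        dists = np.abs(wl[:, None] - truth.informative_centres_nm[None, :])
        assert dists.min() <= 15.0


class TestCARS:
    def test_edf_endpoints_closed_form(self):
        r = cars_retention_schedule(p=204, n_runs=1000)
        assert r[0] == pytest.approx(1.0, abs=1e-12)
        assert r[-1] == pytest.approx(2.0 / 204.0, abs=1e-12)
        assert r[-1] == pytest.approx(0.0098, abs=1e-4)

    def test_retention_counts_non_increasing(self):
        for p, n in [(204, 1000), (60, 50), (10, 7)]:
            counts = np.ceil(cars_retention_schedule(p, n) * p)
            assert np.all(np.diff(counts) <= 0)

    def test_recovers_single_signal_band_across_seeds(self):
        # y = 5*x_7, all other bands pure noise: band 7 must survive the
        # competitive elimination in at least 95 of 100 seeded repetitions.
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 12))
            y = 5.0 * X[:, 7]
            res = cars_select(X, y, n_runs=30, folds=5, seed=seed, max_pcs=3)
            hits += int(7 in res.indices)
        assert hits >= 95

    def test_seed_reproducibility(self, small_swir):
        sm, truth = small_swir
        y = truth.protein_per_sample
        a = cars_select(sm.values, y, n_runs=40, seed=11, max_pcs=5)
        b = cars_select(sm.values, y, n_runs=40, seed=11, max_pcs=5)
        np.testing.assert_array_equal(a.indices, b.indices)
        assert a.rmsecv == b.rmsecv


class TestFrog:
    def test_probabilities_are_frequencies(self, small_swir):
        sm, truth = small_swir
        y = truth.protein_per_sample
        res = frog_select(sm.values, y, n_iter=50, top_k=5, seed=2, max_pcs=5)
        assert res.n_selected == 5
        assert np.all((res.score_trace >= 0) & (res.score_trace <= 1))
        # bands never visited have probability exactly 0
        assert (res.score_trace == 0).any() or res.score_trace.min() > 0

    def test_dominant_band_attains_max_probability(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 12))
        y = 5.0 * X[:, 7] + 0.05 * rng.normal(size=40)
        res = frog_select(X, y, n_iter=150, top_k=3, seed=0, max_pcs=3)
        assert res.score_trace[7] == res.score_trace.max()
        assert 7 in res.indices

    def test_seed_reproducibility(self, small_swir):
        sm, truth = small_swir
        y = truth.protein_per_sample
        a = frog_select(sm.values, y, n_iter=60, top_k=6, seed=4, max_pcs=5)
        b = frog_select(sm.values, y, n_iter=60, top_k=6, seed=4, max_pcs=5)
        np.testing.assert_array_equal(a.indices, b.indices)
        np.testing.assert_array_equal(a.score_trace, b.score_trace)


def test_all_selectors_return_valid_unique_sorted_indices(small_swir):
    sm, truth = small_swir
    y = truth.protein_per_sample
    results = [
        spa_select(sm.values, y, k_min=2, k_max=5, seed=0, max_pcs=4),
        cars_select(sm.values, y, n_runs=30, seed=0, max_pcs=4),
        frog_select(sm.values, y, n_iter=40, top_k=6, seed=0, max_pcs=4),
    ]
    for res in results:
        idx = res.indices
        assert np.all(np.diff(idx) > 0)
        assert idx.min() >= 0 and idx.max() < sm.n_bands
        assert res.n_selected == idx.size
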