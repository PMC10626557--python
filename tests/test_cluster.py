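"""Fuzzy C-means, GA initialization, class assignment and model variants."""

import numpy as np
import pytest

import chillclass as cc
from chillclass.cluster import (
    CHLF_SUBSET, fcm_fit, fcm_objective, ga_fitness_history,
    ga_optimize_centroids, memberships_for_centroids, random_init_centroids,
)
from chillclass.errors import DomainError


def grid_search_objective_1d(x, m=2.0, grid_size=201):
    """Independent oracle: minimum of the fuzzy objective over all centroid
    pairs on a dense 1-D grid, polished by direct numerical minimization.

    For fixed centroids the optimal-U objective collapses (for m = 2) to
    J(V) = Σ_j 1 / Σ_i (1/d²_ij); a sample sitting on a centroid
    contributes 0.  The dense grid locates the global basin; Nelder–Mead
    then refines past the grid resolution.
    """
    from scipy.optimize import minimize

    assert m == 2.0
    x = np.asarray(x, dtype=float)
    lo, hi = x.min() - 0.5, x.max() + 0.5
    grid = np.linspace(lo, hi, grid_size)

    def J(v):
        d2 = np.stack([(x - v[0]) ** 2, (x - v[1]) ** 2])
        hit = (d2 == 0).any(axis=0)
        with np.errstate(divide="ignore"):
            return float(np.where(hit, 0.0, 1.0 / (1.0 / d2[0] + 1.0 / d2[1])).sum())

    best, best_v = np.inf, None
    for a in range(grid_size):
        for b in range(a + 1, grid_size):
            j = J((grid[a], grid[b]))
            if j < best:
                best, best_v = j, (grid[a], grid[b])
    refined = minimize(J, best_v, method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-12))
    return min(best, float(refined.fun))


class TestFCM:
    def test_two_isolated_points(self):
        X = np.array([[0.0], [10.0]])
        state = fcm_fit(X, cc.FCMConfig(n_clusters=2), np.array([[1.0], [9.0]]))
        V = np.sort(state.centroids.ravel())
        assert V == pytest.approx([0.0, 10.0], abs=0.05)
        assert state.membership.max(axis=1).min() > 0.95
        assert state.converged

    def test_two_pair_instance_matches_numerical_minimum(self):
        X = np.array([[0.0], [1.0], [9.0], [10.0]])
        state = fcm_fit(X, cc.FCMConfig(n_clusters=2, tol=1e-8),
                        np.array([[2.0], [8.0]]))
        V = np.sort(state.centroids.ravel())
        assert V == pytest.approx([0.5, 9.5], abs=0.2)
        oracle = grid_search_objective_1d(X.ravel())
        assert state.objective_trajectory[-1] == pytest.approx(oracle, rel=1e-3)

    @pytest.mark.parametrize("n_points", [3, 4, 5, 6])
    def test_matches_grid_search_oracle(self, n_points):
        rng = np.random.default_rng(n_points)
        x = rng.uniform(0, 10, size=n_points)
        # multi-restart: FCM is a local optimizer, the oracle is global
        best = np.inf
        for _ in range(8):
            init = random_init_centroids(x[:, None], 2, rng)
            state = fcm_fit(x[:, None], cc.FCMConfig(n_clusters=2, tol=1e-9), init)
            best = min(best, state.objective_trajectory[-1])
        oracle = grid_search_objective_1d(x)
        assert best == pytest.approx(oracle, rel=1e-3)

    def test_membership_rows_and_objective_monotone_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n, d, C = rng.integers(5, 30), rng.integers(1, 5), rng.integers(2, 5)
            X = rng.normal(size=(n, d))
            init = random_init_centroids(X, C, rng)
            state = fcm_fit(X, cc.FCMConfig(n_clusters=int(C)), init)
            sums = state.membership.sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-10)
            J = state.objective_trajectory
            assert np.all(np.diff(J) <= 1e-12)

    def test_coincident_sample_gets_crisp_membership(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        V = np.array([[0.0, 0.0], [4.0, 4.0]])
        U = memberships_for_centroids(X, V, m=2.0)
        assert U[0, 0] == 1.0 and U[0, 1] == 0.0
        np.testing.assert_allclose(U.sum(axis=1), 1.0)

    def test_initial_error_is_objective_before_any_update(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        V0 = random_init_centroids(X, 3, rng)
        state = fcm_fit(X, cc.FCMConfig(n_clusters=3), V0)
        U0 = memberships_for_centroids(X, V0, 2.0)
        assert state.initial_error == pytest.approx(fcm_objective(X, U0, V0, 2.0))
        assert state.objective_trajectory[0] == state.initial_error

    def test_invalid_inputs_rejected(self):
        X = np.array([[0.0], [1.0], [2.0]])
        with pytest.raises(DomainError, match="NaN"):
            fcm_fit(np.array([[np.nan], [1.0]]), cc.FCMConfig(n_clusters=2),
                    np.array([[0.0], [1.0]]))
        with pytest.raises(DomainError, match="distinct"):
            fcm_fit(X, cc.FCMConfig(n_clusters=2), np.array([[1.0], [1.0]]))
        with pytest.raises(DomainError):
            cc.FCMConfig(fuzzifier=1.0)


class TestGA:
    def test_recovers_planted_blob_centers(self, four_blobs):
        # four blob centers replicated 10× each; nominal blob σ = 0.5
        _, _, centers, sigma = four_blobs
        X = np.repeat(centers, 10, axis=0)
        found = ga_optimize_centroids(X, 4, cc.GAConfig(seed=0))
        # each found centroid within 0.5σ of a distinct true center
        used = set()
        for c in centers:
            dists = np.linalg.norm(found - c, axis=1)
            order = np.argsort(dists)
            pick = next(i for i in order if i not in used)
            used.add(pick)
            assert dists[pick] < 0.5 * sigma

    def test_best_fitness_nondecreasing(self, four_blobs):
        X, _, _, _ = four_blobs
        hist = ga_fitness_history(X, 4, cc.GAConfig(seed=3, generations=30))
        assert np.all(np.diff(hist) >= -1e-15)

    def test_zero_generations_returns_best_random_chromosome(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 2))
        out = ga_optimize_centroids(X, 2, cc.GAConfig(seed=9, generations=0))
        assert out.shape == (2, 2)

    def test_more_centroids_than_samples_rejected(self):
        with pytest.raises(DomainError):
            ga_optimize_centroids(np.zeros((3, 2)), 4, cc.GAConfig(seed=0))

    def test_fuzzy_fitness_option(self, four_blobs):
        X, _, centers, sigma = four_blobs
        found = ga_optimize_centroids(X, 4, cc.GAConfig(seed=1, fitness="fuzzy"))
        # still lands near the blob structure
        for c in centers:
            assert np.linalg.norm(found - c, axis=1).min() < 2.0


class TestAssignClasses:
    def _state(self, U):
        return cc.FCMState(membership=U, centroids=np.zeros((U.shape[1], 1)),
                           objective_trajectory=np.array([1.0]),
                           initial_error=1.0, iterations=1, converged=True)

    def test_already_ordered_clusters(self):
        U = np.eye(4)[[0, 1, 2, 3]]
        proxy = np.array([0.84, 0.65, 0.45, 0.15])
        res = cc.assign_classes(self._state(U), proxy)
        assert res.cluster_to_class == {0: 0, 1: 1, 2: 2, 3: 3}
        np.testing.assert_array_equal(res.class_labels, [0, 1, 2, 3])

    def test_scrambled_cluster_means_sorted_descending(self):
        # cluster-mean Fv/Fm (0.15, 0.84, 0.45, 0.65) → classes (3, 0, 2, 1)
        U = np.eye(4)[[0, 1, 2, 3]]
        proxy = np.array([0.15, 0.84, 0.45, 0.65])
        res = cc.assign_classes(self._state(U), proxy)
        assert res.cluster_to_class == {0: 3, 1: 0, 2: 2, 3: 1}

    def test_tie_broken_by_cluster_index(self):
        U = np.eye(3)[[0, 1, 2]]
        proxy = np.array([0.5, 0.5, 0.9])
        res = cc.assign_classes(self._state(U), proxy)
        # cluster 2 healthiest; tied clusters 0,1 keep index order
        assert res.cluster_to_class == {2: 0, 0: 1, 1: 2}

    def test_empty_cluster_warns(self):
        U = np.array([[0.9, 0.1, 0.0], [0.8, 0.2, 0.0], [0.1, 0.9, 0.0]])
        with pytest.warns(UserWarning, match="non-empty"):
            cc.assign_classes(self._state(U), np.array([0.8, 0.7, 0.2]))

    def test_labels_follow_argmax_memberships(self):
        rng = np.random.default_rng(2)
        U = rng.dirichlet(np.ones(4), size=30)
        proxy = rng.uniform(0, 1, 30)
        res = cc.assign_classes(self._state(U), proxy)
        hard = U.argmax(axis=1)
        expected = np.array([res.cluster_to_class[c] for c in hard])
        np.testing.assert_array_equal(res.class_labels, expected)


class TestVariants:
    def test_fcm_variant_uses_all_parameters(self, normalized_matrix):
        M, _ = normalized_matrix
        res, diag = cc.run_variant(M, "FCM", seed=0)
        assert diag["n_features"] == 15
        assert len(res.class_labels) == M.n_samples
        assert set(res.class_labels) <= {0, 1, 2, 3}

    def test_chlf_variant_restricted_to_named_parameters(self, normalized_matrix):
        M, _ = normalized_matrix
        assert CHLF_SUBSET == ("Fv_Fm", "Fo", "Y_NO", "qP")
        _, diag = cc.run_variant(M, "ChlF-FCM", seed=0)
        assert diag["n_features"] == 4

    def test_unknown_variant_rejected(self, normalized_matrix):
        M, _ = normalized_matrix
        with pytest.raises(DomainError, match="unknown variant"):
            cc.run_variant(M, "KMEANS", seed=0)

    def test_diagnostics_contract(self, normalized_matrix):
        M, _ = normalized_matrix
        _, diag = cc.run_variant(M, "PCA-FCM", seed=1)
        assert {"initial_error", "iterations", "converged",
                "objective_trajectory", "seed"} <= set(diag)
        assert diag["iterations"] == len(diag["objective_trajectory"]) - 1
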