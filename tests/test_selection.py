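"""SSPOC sensor selection: subspace fit, elastic-net recovery, top-k."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import null_space

from wingsense import (SSPOCParams, SensorWeights, fit_subspace,
                       solve_sensors_2class, solve_sensors_multiclass, top_k)
from wingsense._elastic_net import solve_constrained_elastic_net
from wingsense.encoding import FirstSpikeMatrix


def _objective(s, lam):
    return lam * np.abs(s).sum() + (1 - lam) * np.linalg.norm(s)


def _random_orthonormal(n, m, seed):
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.normal(size=(n, m)))
    return Q


class TestElasticNetSolver:
    def test_lambda_zero_matches_minimum_norm_closed_form(self):
        Psi = _random_orthonormal(30, 3, 0)
        w = np.random.default_rng(1).normal(size=3)
        s, info = solve_constrained_elastic_net(Psi, w, lam=0.0)
        np.testing.assert_allclose(s, Psi @ w, atol=1e-6)

    def test_identity_block_forces_unique_sparse_solution(self):
        Psi = np.zeros((8, 2))
        Psi[0, 0] = Psi[1, 1] = 1.0
        w = np.array([0.7, -0.3])
        s, info = solve_constrained_elastic_net(Psi, w, lam=0.9)
        np.testing.assert_allclose(s[:2], w, atol=1e-8)
        np.testing.assert_allclose(s[2:], 0.0, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_small_instance(self, seed):
        """Refined grid search over the 3-dim feasible affine set."""
        n, m, lam = 5, 2, 0.9
        Psi = _random_orthonormal(n, m, seed)
        w = np.random.default_rng(seed + 10).normal(size=m)
        s, _ = solve_constrained_elastic_net(Psi, w, lam=lam)

        N = null_space(Psi.T)
        s0 = Psi @ w
        center, width, best = np.zeros(3), 3.0, np.inf
        for _ in range(12):
            axes = [np.linspace(c - width, c + width, 13) for c in center]
            Z = np.stack(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
            S = s0[None, :] + Z @ N.T
            vals = lam * np.abs(S).sum(1) + (1 - lam) * np.linalg.norm(S, axis=1)
            i = vals.argmin()
            best, center, width = vals[i], Z[i], width * 0.35
        assert _objective(s, lam) <= best + 1e-4

    def test_constraint_residual_below_tolerance(self):
        Psi = _random_orthonormal(200, 3, 3)
        w = np.random.default_rng(4).normal(size=3)
        s, info = solve_constrained_elastic_net(Psi, w, lam=0.9)
        assert info["constraint_violation"] <= 1e-6
        np.testing.assert_allclose(Psi.T @ s, w, atol=1e-6)

    def test_relaxed_solution_matches_exact_at_tiny_eps(self):
        Psi = _random_orthonormal(40, 3, 5)
        w = np.random.default_rng(6).normal(size=3)
        s_eq, _ = solve_constrained_elastic_net(Psi, w, lam=0.9)
        s_in, _ = solve_constrained_elastic_net(Psi, w, lam=0.9, eps=1e-6)
        np.testing.assert_allclose(s_in, s_eq, atol=1e-4)

    def test_huge_eps_gives_zero_solution(self):
        Psi = _random_orthonormal(40, 3, 7)
        w = np.random.default_rng(8).normal(size=3)
        s, _ = solve_constrained_elastic_net(Psi, w, lam=0.9, eps=1e6)
        assert np.abs(s).max() == 0.0

    def test_sparsity_nonincreasing_in_lambda(self):
        Psi = _random_orthonormal(100, 3, 9)
        w = np.random.default_rng(10).normal(size=3)
        support = []
        for lam in (0.1, 0.5, 0.9, 0.99):
            s, _ = solve_constrained_elastic_net(Psi, w, lam=lam)
            support.append(int((np.abs(s) > 1e-6 * np.abs(s).max()).sum()))
        assert all(a >= b for a, b in zip(support, support[1:]))

    def test_matrix_valued_w_solved_columnwise(self):
        Psi = _random_orthonormal(30, 3, 11)
        W = np.random.default_rng(12).normal(size=(3, 2))
        S, info = solve_constrained_elastic_net(Psi, W, lam=0.9, eps=1e-6)
        assert S.shape == (30, 2)
        assert info["constraint_violation"] <= 1e-6


class TestFitSubspace:
    def test_single_informative_axis_dominates_first_component(self):
        # noiseless: every other sensor is constant, so after z-scoring all
        # variance lives on the informative axis
        n = 400
        X = np.full((n, 20), 3.7)
        y = np.repeat([0, 1], n // 2)
        X[:, 7] += np.where(y == 0, -1.0, 1.0)  # all signal on sensor 7
        jitter = np.linspace(-1e-3, 1e-3, n)    # break exact degeneracy
        X[:, 7] += jitter
        model = fit_subspace(FirstSpikeMatrix(X, y), SSPOCParams(m=3))
        assert abs(model.Psi[7, 0]) > 0.99

    def test_orthonormal_basis(self, separable_features):
        model = fit_subspace(separable_features, SSPOCParams(m=3))
        np.testing.assert_allclose(model.Psi.T @ model.Psi, np.eye(3),
                                   atol=1e-10)

    def test_full_subspace_matches_full_space_lda_ranking(self):
        """With m = n, projecting through PCA is a rotation: the recovered
        discriminant direction (mapped back) matches full-space LDA."""
        rng = np.random.default_rng(1)
        n, d = 300, 6
        X = rng.normal(size=(n, d))
        y = np.repeat([0, 1], n // 2)
        X[y == 1, :2] += [0.8, -0.5]
        feats = FirstSpikeMatrix(X, y)
        model = fit_subspace(feats, SSPOCParams(m=d))
        w_full = model.Psi @ model.w[:, 0]

        Xs = (X - X.mean(0)) / X.std(0)
        mu0, mu1 = Xs[y == 0].mean(0), Xs[y == 1].mean(0)
        Sw = np.cov(Xs[y == 0].T) + np.cov(Xs[y == 1].T)
        ref = np.linalg.solve(Sw, mu1 - mu0)
        ref /= np.linalg.norm(ref)
        cos = abs(w_full @ ref)
        assert cos > 0.99

    def test_identical_classes_raise_degenerate(self):
        X = np.zeros((40, 5))
        y = np.repeat([0, 1], 20)
        with pytest.raises(ValueError):
            fit_subspace(FirstSpikeMatrix(X, y), SSPOCParams(m=2))

    def test_requires_two_classes_and_enough_rows(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        with pytest.raises(ValueError):
            fit_subspace(FirstSpikeMatrix(X, np.zeros(10)), SSPOCParams(m=2))
        with pytest.raises(ValueError):
            fit_subspace(FirstSpikeMatrix(X[:2], np.array([0, 1])),
                         SSPOCParams(m=3))


class TestSolveSensors:
    def test_two_class_pipeline_selects_sparse_informative_set(
            self, separable_features):
        model = fit_subspace(separable_features, SSPOCParams())
        weights = solve_sensors_2class(model, SSPOCParams())
        agg = weights.aggregated()
        frac_large = (agg > 1e-6 * agg.max()).mean()
        assert frac_large < 0.5  # many near-zero entries
        assert len(weights.selected) == 10

    def test_multiclass_consistent_with_two_class(self, separable_features):
        params = SSPOCParams()
        model = fit_subspace(separable_features, params)
        s2 = solve_sensors_2class(model, params)
        sm = solve_sensors_multiclass(model, params)
        np.testing.assert_allclose(sm.s.ravel(), s2.s.ravel(), atol=1e-4)

    def test_permutation_equivariance(self, separable_features):
        params = SSPOCParams()
        rng = np.random.default_rng(5)
        perm = rng.permutation(separable_features.n_locations)
        permuted = FirstSpikeMatrix(separable_features.data[:, perm],
                                    separable_features.labels)
        s_orig = solve_sensors_2class(fit_subspace(separable_features, params),
                                      params).s
        s_perm = solve_sensors_2class(fit_subspace(permuted, params),
                                      params).s
        # PCA signs can flip; compare absolute weights
        np.testing.assert_allclose(np.abs(s_perm), np.abs(s_orig[perm]),
                                   atol=1e-4)


class TestTopK:
    def test_largest_weights_win(self):
        w = SensorWeights(s=np.array([0.9, 0.1, 0.0, 0.5]),
                          selected=np.empty(0, int))
        np.testing.assert_array_equal(top_k(w, 2), [0, 3])

    def test_all_zero_weights_rejected(self):
        w = SensorWeights(s=np.zeros(5), selected=np.empty(0, int))
        with pytest.raises(ValueError, match="zero"):
            top_k(w, 2)

    def test_k_equals_n_returns_all_sorted(self):
        w = SensorWeights(s=np.array([0.2, 0.9, 0.5]),
                          selected=np.empty(0, int))
        np.testing.assert_array_equal(top_k(w, 3), [1, 2, 0])

    def test_ties_break_to_lower_index(self):
        w = SensorWeights(s=np.array([0.5, 0.7, 0.5, 0.5]),
                          selected=np.empty(0, int))
        np.testing.assert_array_equal(top_k(w, 3), [1, 0, 2])

    def test_k_larger_than_n_rejected(self):
        w = SensorWeights(s=np.ones(3), selected=np.empty(0, int))
        with pytest.raises(ValueError):
            top_k(w, 4)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10**6))
    def test_selection_permutes_with_sensors(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.exponential(size=12)
        perm = rng.permutation(12)
        w1 = SensorWeights(s=s, selected=np.empty(0, int))
        w2 = SensorWeights(s=s[perm], selected=np.empty(0, int))
        sel1 = set(top_k(w1, 4))
        sel2 = {perm[i] for i in range(12) if i in set(top_k(w2, 4))}
        # compare as sets of weights (indices shift under permutation)
        assert {round(s[i], 12) for i in sel1} == \
               {round(s[perm[i]], 12) for i in top_k(w2, 4)}


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            SSPOCParams(m=0)
        with pytest.raises(ValueError):
            SSPOCParams(lam=1.5)
        with pytest.raises(ValueError):
            SSPOCParams(eps=0.0)
        with pytest.raises(ValueError):
            SSPOCParams(k=0)
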