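"""simpleMKL solver: gradients, simplex handling, sparsity, equivalences
with plain SVMs, grid-search oracles, prediction and primal weights."""

import numpy as np
import pytest

from mklband.kernels import KernelSet, center_and_normalize
from mklband.mkl import (MKLModel, load_model, mkl_objective_and_gradient,
                         predict, primal_feature_weights, save_model,
                         simple_mkl_fit)
from mklband.svm import svm_dual_solve
from mklband.timefreq import BandFeatureTensor


def grid_objective(kset, y, d, C):
    return mkl_objective_and_gradient(kset, y, d, C)[0]


class TestObjectiveAndGradient:
    def test_finite_difference_agreement(self, random_kernel_problem):
        """Central differences along simplex-preserving directions."""
        kset, y = random_kernel_problem
        d0 = np.array([0.5, 0.3, 0.2])
        J0, g = mkl_objective_and_gradient(kset, y, d0, C=1.0)
        eps = 1e-3
        for mm in range(3):
            other = (mm + 1) % 3
            dp, dm = d0.copy(), d0.copy()
            dp[mm] += eps; dp[other] -= eps
            dm[mm] -= eps; dm[other] += eps
            fd = (grid_objective(kset, y, dp, 1.0)
                  - grid_objective(kset, y, dm, 1.0)) / (2 * eps)
            assert abs(fd - (g[mm] - g[other])) <= 1e-4

    def test_identical_kernels_equal_gradient(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        K = X @ X.T
        kset = KernelSet(np.stack([K, K]), [("a", "delta"), ("b", "delta")])
        y = np.concatenate([np.ones(5), -np.ones(5)])
        _, g = mkl_objective_and_gradient(kset, y, np.array([0.5, 0.5]), 1.0)
        assert g[0] == pytest.approx(g[1], abs=1e-10)

    def test_zero_kernel_zero_gradient(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 3))
        kset = KernelSet(np.stack([X @ X.T, np.zeros((8, 8))]),
                         [("a", "delta"), ("b", "delta")])
        y = np.concatenate([np.ones(4), -np.ones(4)])
        _, g = mkl_objective_and_gradient(kset, y, np.array([1.0, 0.0]), 1.0)
        assert g[1] == 0.0

    def test_off_simplex_rejected(self, random_kernel_problem):
        kset, y = random_kernel_problem
        with pytest.raises(ValueError):
            mkl_objective_and_gradient(kset, y, np.array([0.5, 0.5, 0.5]), 1.0)


class TestSimpleMKLFit:
    def test_single_kernel_reduces_to_svm(self):
        rng = np.random.default_rng(2)
        X = np.concatenate([rng.normal(1, 1, (10, 4)), rng.normal(-1, 1, (10, 4))])
        y = np.concatenate([np.ones(10), -np.ones(10)])
        kset = center_and_normalize(
            KernelSet((X @ X.T)[None], [("a", "delta")]), np.arange(20))
        model = simple_mkl_fit(kset, y, C=1.0)
        assert np.array_equal(model.d, [1.0])
        a_svm, b_svm, obj_svm = svm_dual_solve(kset.kernels[0], y, 1.0)
        assert model.objective == pytest.approx(obj_svm, abs=1e-6)
        assert np.abs(model.alpha - a_svm).max() < 1e-5

    def test_two_identical_kernels_redundancy_invariance(self):
        rng = np.random.default_rng(3)
        X = np.concatenate([rng.normal(1, 1, (10, 4)), rng.normal(-1, 1, (10, 4))])
        y = np.concatenate([np.ones(10), -np.ones(10)])
        K = X @ X.T
        kset = center_and_normalize(
            KernelSet(np.stack([K, K]), [("a", "delta"), ("b", "delta")]),
            np.arange(20))
        model = simple_mkl_fit(kset, y, C=1.0)
        out = predict(model, kset.kernels)
        a_svm, b_svm, obj_svm = svm_dual_solve(kset.kernels[0], y, 1.0)
        svm_scores = kset.kernels[0] @ (a_svm * y) + b_svm
        assert np.abs(out.score - svm_scores).max() < 1e-5
        # J is invariant to how weight splits between identical kernels
        for t in (0.0, 0.3, 1.0):
            J = grid_objective(kset, y, np.array([t, 1 - t]), 1.0)
            assert J == pytest.approx(obj_svm, abs=1e-8)

    def test_informative_kernel_dominates_and_matches_grid_oracle(
            self, separable_two_kernel):
        kset, y = separable_two_kernel
        model = simple_mkl_fit(kset, y, C=1.0, tol=1e-4, stall_tol=0.0)
        assert model.d[0] > 0.9
        grid = np.arange(0.0, 1.0001, 0.05)
        J_grid = min(grid_objective(kset, y, np.array([t, 1 - t]), 1.0)
                     for t in grid)
        assert abs(model.objective - J_grid) <= 1e-3

    def test_three_kernel_exhaustive_simplex_grid_oracle(self):
        rng = np.random.default_rng(7)
        Xi = np.concatenate([rng.normal(3.0, 1, (20, 6)),
                             rng.normal(-3.0, 1, (20, 6))])
        y = np.concatenate([np.ones(20), -np.ones(20)])
        Xn1 = rng.normal(size=(40, 6))
        Xn2 = rng.normal(size=(40, 6))
        Ks = np.stack([Xi @ Xi.T, Xn1 @ Xn1.T, Xn2 @ Xn2.T])
        kset = center_and_normalize(
            KernelSet(Ks, [("a", "delta"), ("b", "delta"), ("c", "delta")]),
            np.arange(40))
        model = simple_mkl_fit(kset, y, C=1.0, tol=1e-4, stall_tol=0.0)
        best = min(grid_objective(kset, y, np.array([i, j, 20 - i - j]) / 20.0, 1.0)
                   for i in range(21) for j in range(21 - i))
        assert abs(model.objective - best) <= 1e-3

    def test_monotone_objective_descent(self, separable_two_kernel):
        kset, y = separable_two_kernel
        model = simple_mkl_fit(kset, y, C=1.0, tol=1e-4, stall_tol=0.0)
        hist = np.array(model.objective_history)
        assert len(hist) >= 1
        assert np.all(np.diff(hist) <= 1e-6 * np.abs(hist[:-1]))

    def test_simplex_constraints_exact(self, separable_two_kernel):
        kset, y = separable_two_kernel
        for C in (0.1, 1.0, 100.0):
            model = simple_mkl_fit(kset, y, C=C)
            assert np.all(model.d >= 0)
            assert abs(model.d.sum() - 1.0) <= 1e-12
        # pinned coordinates are exactly zero
        model = simple_mkl_fit(kset, y, C=1.0, tol=1e-4, stall_tol=0.0)
        assert model.d[1] == 0.0

    def test_kkt_at_convergence(self, separable_two_kernel):
        kset, y = separable_two_kernel
        tol = 1e-4
        model = simple_mkl_fit(kset, y, C=1.0, tol=tol, stall_tol=0.0)
        _, g = mkl_objective_and_gradient(kset, y, model.d, 1.0)
        mu = int(np.argmax(model.d))
        tol_kkt = tol * max(abs(model.objective), 1.0) * 2
        for mm in range(len(model.d)):
            if model.d[mm] > 0:
                assert abs(g[mm] - g[mu]) <= tol_kkt
            else:
                assert g[mm] >= g[mu] - tol_kkt

    def test_scale_invariance(self, separable_two_kernel):
        kset, y = separable_two_kernel
        c = 7.0
        scaled = KernelSet(kset.kernels * c, list(kset.index), kset.state,
                           kset.degenerate, kset.scales)
        m1 = simple_mkl_fit(kset, y, C=1.0, tol=1e-4, stall_tol=0.0)
        m2 = simple_mkl_fit(scaled, y, C=1.0 / c, tol=1e-4, stall_tol=0.0)
        assert np.abs(m1.d - m2.d).max() < 1e-6
        sv = m1.alpha > 1e-8
        assert np.abs(m2.alpha[sv] * c - m1.alpha[sv]).max() < 1e-6

    def test_nonconvergence_warns(self, separable_two_kernel):
        kset, y = separable_two_kernel
        with pytest.warns(RuntimeWarning, match="max_iter"):
            model = simple_mkl_fit(kset, y, C=1.0, tol=1e-12, max_iter=1,
                                   stall_tol=0.0)
        assert not model.converged

    def test_single_class_rejected(self, separable_two_kernel):
        kset, _ = separable_two_kernel
        with pytest.raises(ValueError):
            simple_mkl_fit(kset, np.ones(kset.n), C=1.0)


class TestPredict:
    def test_equal_contributions_match_svm_on_average_kernel(
            self, random_kernel_problem):
        """Frozen uniform d: MKL scoring equals one SVM on the mean kernel."""
        kset, y = random_kernel_problem
        kc = center_and_normalize(kset, np.arange(kset.n))
        M = kc.n_kernels
        Kbar = kc.kernels.mean(axis=0)
        alpha, b, _ = svm_dual_solve(Kbar, y, C=2.0)
        model = MKLModel(d=np.full(M, 1.0 / M), alpha=alpha, b=b, C=2.0,
                         y_train=y, objective=0.0, n_iter=0, converged=True,
                         index=list(kc.index))
        out = predict(model, kc.kernels)
        svm_scores = Kbar @ (alpha * y) + b
        assert np.abs(out.score - svm_scores).max() <= 1e-8

    def test_zero_contribution_zero_per_kernel_score(self, separable_two_kernel):
        kset, y = separable_two_kernel
        model = simple_mkl_fit(kset, y, C=1.0, tol=1e-4, stall_tol=0.0)
        out = predict(model, kset.kernels)
        assert np.all(out.per_kernel_score[model.d == 0] == 0.0)
        assert np.allclose(out.score,
                           out.per_kernel_score.sum(axis=0) + model.b)

    def test_training_margins_on_separable_problem(self, separable_two_kernel):
        kset, y = separable_two_kernel
        model = simple_mkl_fit(kset, y, C=100.0, tol=1e-4, stall_tol=0.0)
        out = predict(model, kset.kernels)
        free = (model.alpha > 1e-8) & (model.alpha < 100.0 * (1 - 1e-8))
        assert np.all(y[free] * out.score[free] >= 1 - 1e-5)

    def test_shape_mismatch_rejected(self, separable_two_kernel):
        kset, y = separable_two_kernel
        model = simple_mkl_fit(kset, y, C=1.0)
        with pytest.raises(ValueError):
            predict(model, kset.kernels[:, :, :10])


class TestPrimalWeights:
    @staticmethod
    def _fit_with_features(seed=4):
        rng = np.random.default_rng(seed)
        n, T = 24, 436
        vals = rng.normal(size=(n, 2, 1, T))
        vals[:12, 0, 0, :] += 1.0
        feats = BandFeatureTensor(vals, ["high_gamma"], ["ch0", "ch1"], 436.0)
        from mklband.kernels import build_linear_kernels

        kset = build_linear_kernels(feats)
        y = np.concatenate([np.ones(12), -np.ones(12)])
        train = np.arange(18)
        kc = center_and_normalize(kset, train)
        model = simple_mkl_fit(kc.epoch_subset(train), y[train], C=1.0,
                               train_idx=train)
        return model, feats, kc, y, train

    def test_weight_vector_length_and_zero_for_pinned(self):
        model, feats, _, _, train = self._fit_with_features()
        W = primal_feature_weights(model, feats, train)
        assert W.shape == (2, 436)
        for mm in range(2):
            if model.d[mm] == 0:
                assert np.all(W[mm] == 0.0)

    def test_scores_reconstructed_from_primal_weights(self):
        model, feats, kc, y, train = self._fit_with_features()
        W = primal_feature_weights(model, feats, train)
        test = np.arange(18, 24)
        out = predict(model, kc.epoch_block(test, train))
        # transform test features exactly like the kernels were
        recon = np.zeros(len(test))
        mm = 0
        for c in range(2):
            for b in range(1):
                X = feats.values[:, c, b, :]
                mu = X[train].mean(axis=0)
                Xt = (X[test] - mu) / np.sqrt(model.scales[mm])
                recon += Xt @ W[mm]
                mm += 1
        assert np.abs(recon + model.b - out.score).max() <= 1e-8

    def test_requires_normalization_scales(self):
        model, feats, _, _, train = self._fit_with_features()
        model.scales = None
        with pytest.raises(ValueError):
            primal_feature_weights(model, feats, train)


def test_model_serialization_roundtrip(tmp_path, separable_two_kernel):
    kset, y = separable_two_kernel
    model = simple_mkl_fit(kset, y, C=1.0, train_idx=np.arange(40))
    path = tmp_path / "model.npz"
    save_model(model, path)
    back = load_model(path)
    assert np.array_equal(back.d, model.d)
    assert np.array_equal(back.alpha, model.alpha)
    assert back.b == model.b
    assert back.C == model.C
    assert back.index == model.index
    assert np.array_equal(back.train_idx, model.train_idx)
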