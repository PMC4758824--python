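"""Nested cross-validation, metrics, C selection, leakage guards and
permutation significance."""
import numpy as np
import pytest

import mklband as m
from mklband.evaluation import (DEFAULT_C_GRID, compute_metrics, make_folds,
                                nested_cv, permutation_test)
from mklband.kernels import KernelSet, build_linear_kernels, center_and_normalize


class TestMakeFolds:
    def test_even_split(self):
        plan = make_folds(100, k=10)
        sizes = np.bincount(plan.assignments)
        assert np.array_equal(sizes, np.full(10, 10))

    def test_train_fraction_ninety_percent(self):
        plan = make_folds(103, k=10)
        for _, train, test in plan.split():
            assert abs(len(train) - 0.9 * 103) <= 1

    def test_contiguous_blocks_scan_oracle(self):
        plan = make_folds(47, k=5, scheme="contiguous_blocks")
        for f in range(5):
            idx = np.flatnonzero(plan.assignments == f)
            assert np.array_equal(idx, np.arange(idx[0], idx[-1] + 1))
        assert plan.assignments[0] == 0 and plan.assignments[-1] == 4

    def test_random_stratified_preserves_ratio(self):
        y = np.tile([1.0, 1.0, -1.0], 20)  # 40:20 imbalance
        plan = make_folds(60, k=6, scheme="random_stratified", seed=0, labels=y)
        for f in range(6):
            fold_y = y[plan.assignments == f]
            assert np.sum(fold_y > 0) == pytest.approx(40 / 6, abs=1)

    def test_too_few_epochs_rejected(self):
        with pytest.raises(ValueError):
            make_folds(5, k=10)


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 1.0, -1.0, -1.0])
        out = compute_metrics(y, y)
        assert out["balanced_acc"] == 100.0
        assert out["math_acc"] == out["nonmath_acc"] == 100.0
        assert out["ppv_math"] == out["ppv_nonmath"] == 100.0

    def test_confusion_matrix_arithmetic(self):
        # TP=8 FN=2 TN=6 FP=4
        true = np.array([1.0] * 10 + [-1.0] * 10)
        pred = np.array([1.0] * 8 + [-1.0] * 2 + [-1.0] * 6 + [1.0] * 4)
        out = compute_metrics(pred, true)
        assert out["math_acc"] == pytest.approx(80.0)
        assert out["nonmath_acc"] == pytest.approx(60.0)
        assert out["balanced_acc"] == pytest.approx(70.0)
        assert out["ppv_math"] == pytest.approx(100 * 8 / 12)

    def test_all_predicted_math(self):
        true = np.array([1.0, 1.0, -1.0, -1.0])
        out = compute_metrics(np.ones(4), true)
        assert out["math_acc"] == 100.0
        assert out["nonmath_acc"] == 0.0
        assert out["balanced_acc"] == 50.0
        assert np.isnan(out["ppv_nonmath"])

    def test_balanced_is_mean_of_class_accuracies(self):
        rng = np.random.default_rng(0)
        true = np.where(rng.random(50) < 0.5, 1.0, -1.0)
        true[:2] = [1.0, -1.0]
        pred = np.where(rng.random(50) < 0.5, 1.0, -1.0)
        out = compute_metrics(pred, true)
        assert out["balanced_acc"] == pytest.approx(
            (out["math_acc"] + out["nonmath_acc"]) / 2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            compute_metrics(np.ones(3), np.ones(3))


def test_default_C_grid_is_six_decades():
    assert DEFAULT_C_GRID == (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


def test_nested_cv_strong_effect_near_perfect_accuracy(synth_decoding_dataset):
    """A strong injected effect should be decoded almost perfectly; epochs
    whose onset rounds far from the true stimulus start carry a diluted
    effect, so a stray miss is tolerated."""
    kset, y, *_ = synth_decoding_dataset
    plan = make_folds(len(y), k=10)
    cv = nested_cv(kset, y, plan)
    assert cv.metrics["balanced_acc"] >= 97.0
    assert len(cv.chosen_C) == 10
    assert all(c in DEFAULT_C_GRID for c in cv.chosen_C)
    # every epoch predicted exactly once
    assert np.all(np.abs(cv.predictions) == 1.0)


def test_recovered_contribution_is_the_informative_kernel(synth_decoding_dataset):
    kset, y, _, _, info_idx = synth_decoding_dataset
    plan = make_folds(len(y), k=10)
    cv = nested_cv(kset, y, plan)
    mean_d = m.average_contributions(cv.per_fold_d)
    assert int(np.argmax(mean_d)) == info_idx


def _nuisance_dataset(seed):
    """Tiny C underfits here: the class-mean direction is swamped by a
    high-variance nuisance dimension; larger C recovers the weak signal."""
    rng = np.random.default_rng(seed)
    n, T = 60, 40
    X = rng.normal(size=(n, T))
    X[:, 0] *= 30.0
    y = np.concatenate([np.ones(30), -np.ones(30)])
    X[:, 1:6] += 0.8 * y[:, None]
    order = rng.permutation(n)
    X, y = X[order], y[order]
    return KernelSet((X @ X.T)[None], [("ch0", "delta")]), y


def test_inner_cv_rejects_underfitting_C():
    n_small = 0
    n_folds = 0
    for seed in range(3):
        kset, y = _nuisance_dataset(seed)
        plan = make_folds(len(y), k=10, scheme="random_stratified", seed=seed,
                          labels=y)
        cv = nested_cv(kset, y, plan, seed=seed)
        n_small += sum(1 for c in cv.chosen_C if c == 0.01)
        n_folds += len(cv.chosen_C)
        # sanity of the construction itself
        fixed_small = nested_cv(kset, y, plan, C_grid=(0.01,), seed=seed)
        fixed_mod = nested_cv(kset, y, plan, C_grid=(10.0,), seed=seed)
        assert fixed_mod.metrics["balanced_acc"] > fixed_small.metrics["balanced_acc"]
    assert n_small <= n_folds // 10  # C = 0.01 selected in at most ~10% of folds


def test_no_test_leakage_trained_models_bit_identical(synth_decoding_dataset):
    """Perturbing fold-0 test epochs must leave fold-0's trained model
    byte-identical (its training data excludes them entirely)."""
    kset, y, feats, _, _ = synth_decoding_dataset
    plan = make_folds(len(y), k=10)
    cv1 = nested_cv(kset, y, plan)
    test0 = np.flatnonzero(plan.assignments == 0)
    vals = feats.values.copy()
    vals[test0] += 37.0
    feats2 = m.BandFeatureTensor(vals, feats.band_names, feats.ch_names,
                                 feats.sfreq_hz)
    cv2 = nested_cv(build_linear_kernels(feats2), y, plan)
    m1, m2 = cv1.fold_models[0], cv2.fold_models[0]
    assert np.array_equal(m1.d, m2.d)
    assert np.array_equal(m1.alpha, m2.alpha)
    assert m1.b == m2.b
    assert m1.C == m2.C


def test_centered_train_blocks_zero_row_mean(synth_decoding_dataset):
    kset, y, *_ = synth_decoding_dataset
    plan = make_folds(len(y), k=10)
    for _, train, _ in plan.split():
        kc = center_and_normalize(kset, train)
        blk = kc.kernels[:, train[:, None], train[None, :]]
        assert np.abs(blk.mean(axis=1)).max() < 1e-10
        break  # one fold suffices; the formula is split-independent


@pytest.fixture(scope="module")
def small_problem(synth_decoding_dataset):
    kset, y, *_ = synth_decoding_dataset
    mask = np.array([b == "high_gamma" for _, b in kset.index])
    return kset.select(mask), y


class TestPermutationTest:
    def test_strong_effect_reaches_minimal_p(self, small_problem):
        """Observed accuracy above every null value gives p = 1/(n_perm+1)."""
        kset, y = small_problem
        plan = make_folds(len(y), k=5)
        perm = permutation_test(kset, y, plan, n_perm=19, seed=0,
                                C_grid=(1.0,))
        assert perm.p_values["balanced_acc"] == pytest.approx(1 / 20)
        assert np.all(perm.null["balanced_acc"]
                      < perm.observed["balanced_acc"])

    def test_p_value_bounds_and_determinism(self, small_problem):
        kset, y = small_problem
        plan = make_folds(len(y), k=5)
        p1 = permutation_test(kset, y, plan, n_perm=9, seed=3, C_grid=(1.0,))
        p2 = permutation_test(kset, y, plan, n_perm=9, seed=3, C_grid=(1.0,))
        for k in p1.p_values:
            assert 1 / 10 <= p1.p_values[k] <= 1.0
            assert p1.p_values[k] == p2.p_values[k]
        assert np.array_equal(p1.null["balanced_acc"], p2.null["balanced_acc"])

    def test_balanced_significance_needs_both_classes(self, small_problem):
        kset, y = small_problem
        plan = make_folds(len(y), k=5)
        perm = permutation_test(kset, y, plan, n_perm=19, seed=1, C_grid=(1.0,))
        expected = (perm.p_values["math_acc"] < 0.05
                    and perm.p_values["nonmath_acc"] < 0.05)
        assert perm.significant["balanced_acc"] == expected

    def test_invalid_args(self, small_problem):
        kset, y = small_problem
        plan = make_folds(len(y), k=5)
        with pytest.raises(ValueError):
            permutation_test(kset, y, plan, n_perm=0)
        with pytest.raises(ValueError):
            permutation_test(kset, y, plan, n_perm=5, scope="sideways")
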