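"""Nested cross-validation, performance metrics and permutation testing.

The outer 10-fold loop estimates generalization performance; an inner
stratified loop on each outer-training set picks the soft-margin parameter
C from a logarithmic grid (10^-2 ... 10^3).  Kernel centering statistics
are always computed on the training side of each split, so no information
leaks from test epochs.  Significance is assessed non-parametrically by
refitting the whole nested procedure on permuted training labels:
temporal autocorrelation between 1 s windows of the same stimulus breaks
the independence assumptions of parametric (binomial) tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .kernels import KernelSet, center_and_normalize
from .mkl import MKLModel, predict, simple_mkl_fit

#: Soft-margin grid: C = 10^i, i = -2 ... 3.
DEFAULT_C_GRID: tuple[float, ...] = tuple(10.0 ** i for i in range(-2, 4))
DEFAULT_K = 10
DEFAULT_INNER_K = 3


@dataclass
class FoldPlan:
    """Assignment of each epoch to one of k folds."""

    k: int
    assignments: np.ndarray
    scheme: str = "contiguous_blocks"
    seed: int = 0

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        sizes = np.bincount(self.assignments, minlength=self.k)
        if len(sizes) != self.k or sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most 1 and cover all folds")

    def split(self):
        for f in range(self.k):
            test = np.flatnonzero(self.assignments == f)
            train = np.flatnonzero(self.assignments != f)
            yield f, train, test


def make_folds(n: int, k: int = DEFAULT_K, scheme: str = "contiguous_blocks",
               seed: int = 0, labels: np.ndarray | None = None) -> FoldPlan:
    """Build a k-fold plan.

    ``contiguous_blocks`` keeps temporally adjacent epochs in the same
    fold, limiting optimistic bias from autocorrelation between
    neighbouring windows; ``random_stratified`` shuffles with class
    stratification (requires ``labels``).
    """
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} epochs")
    assignments = np.empty(n, dtype=int)
    if scheme == "contiguous_blocks":
        for f, block in enumerate(np.array_split(np.arange(n), k)):
            assignments[block] = f
    elif scheme == "random_stratified":
        if labels is None:
            raise ValueError("random_stratified requires labels")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for f, (_, test) in enumerate(skf.split(np.zeros(n), labels)):
            assignments[test] = f
    else:
        raise ValueError(f"unknown fold scheme {scheme!r}")
    return FoldPlan(k=k, assignments=assignments, scheme=scheme, seed=seed)


def compute_metrics(pred: np.ndarray, true: np.ndarray) -> dict[str, float]:
    """Class accuracies (recall), PPV (precision) and balanced accuracy, in %.

    Labels are +/-1 with +1 = math.  PPV is NaN when a class is never
    predicted.
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("pred and true must be equal-length, non-empty")
    if len(np.unique(np.sign(true))) < 2:
        raise ValueError("both classes must be present in the truth")
    tp = np.sum((true > 0) & (pred > 0))
    fn = np.sum((true > 0) & (pred <= 0))
    tn = np.sum((true <= 0) & (pred <= 0))
    fp = np.sum((true <= 0) & (pred > 0))
    math_acc = 100.0 * tp / (tp + fn)
    nonmath_acc = 100.0 * tn / (tn + fp)
    return {
        "math_acc": math_acc,
        "nonmath_acc": nonmath_acc,
        "balanced_acc": 0.5 * (math_acc + nonmath_acc),
        "ppv_math": 100.0 * tp / (tp + fp) if tp + fp else float("nan"),
        "ppv_nonmath": 100.0 * tn / (tn + fn) if tn + fn else float("nan"),
    }


@dataclass
class CVResult:
    """Outcome of one nested cross-validation run."""

    plan: FoldPlan
    chosen_C: list[float]
    fold_models: list[MKLModel]
    per_fold_d: np.ndarray            # (k, n_kernels)
    predictions: np.ndarray           # (n,) +/-1, each epoch predicted once
    scores: np.ndarray                # (n,) decision values
    metrics: dict[str, float]         # pooled over folds
    per_fold_metrics: list[dict[str, float]] = field(default_factory=list)


def _inner_select_C(ktrain_raw: KernelSet, y_train: np.ndarray,
                    C_grid: tuple[float, ...], inner_k: int, seed: int,
                    tol: float, max_iter: int, svm_tol: float) -> float:
    """Inner stratified CV on the outer-training set; smallest C wins ties."""
    if len(C_grid) == 1:
        return C_grid[0]
    classes, counts = np.unique(y_train, return_counts=True)
    k_eff = int(min(inner_k, counts.min()))
    if k_eff < 2:
        raise ValueError("inner cross-validation degenerate: a class has < 2 epochs")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    n = len(y_train)
    conf = {C: [np.zeros(n), np.zeros(n)] for C in C_grid}  # pred, mask
    for itr, ival in skf.split(np.zeros(n), y_train):
        kc = center_and_normalize(ktrain_raw, itr)
        kfit = kc.epoch_subset(itr)
        blocks = kc.epoch_block(ival, itr)
        d_warm, a_warm = None, None
        for C in sorted(C_grid):  # ascending C; warm-start along the path
            model = simple_mkl_fit(kfit, y_train[itr], C=C, tol=tol,
                                   max_iter=max_iter, svm_tol=svm_tol,
                                   d_init=d_warm, alpha_init=a_warm)
            d_warm, a_warm = model.d, model.alpha
            out = predict(model, blocks)
            conf[C][0][ival] = out.predicted
            conf[C][1][ival] = 1.0
    best_C, best_score = None, -np.inf
    for C in sorted(C_grid):
        mask = conf[C][1] > 0
        score = compute_metrics(conf[C][0][mask], y_train[mask])["balanced_acc"]
        if score > best_score + 1e-12:
            best_C, best_score = C, score
    return float(best_C)


def nested_cv(kset_raw: KernelSet, y: np.ndarray, outer: FoldPlan,
              C_grid: tuple[float, ...] = DEFAULT_C_GRID,
              inner_k: int = DEFAULT_INNER_K, tol: float = 0.01,
              max_iter: int = 200, svm_tol: float = 1e-4, seed: int = 0,
              train_label_rng: np.random.Generator | None = None,
              center_cache: dict | None = None) -> CVResult:
    """Nested cross-validation of the sparse-MKL decoder.

    Parameters
    ----------
    kset_raw
        Uncentered kernels over all epochs; centering is redone inside
        every split using that split's training epochs only.
    y
        Labels +/-1.
    outer
        Outer fold plan.
    train_label_rng
        If given, training labels are shuffled within each outer-training
        set before fitting (the permutation-test null); test labels are
        left untouched and metrics are computed against the truth.
    center_cache
        Optional dict reused across calls that share folds and kernels
        (e.g. the permutations of a permutation test): kernel centering
        depends only on the split, not on labels, so the per-fold centered
        kernels are memoized in it.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng_seeds = np.random.SeedSequence(seed).generate_state(outer.k)
    predictions = np.zeros(n)
    scores = np.zeros(n)
    chosen_C: list[float] = []
    fold_models: list[MKLModel] = []
    per_fold_metrics: list[dict[str, float]] = []
    per_fold_d = np.zeros((outer.k, kset_raw.n_kernels))

    for f, train, test in outer.split():
        y_eff = y.copy()
        if train_label_rng is not None:
            y_eff[train] = train_label_rng.permutation(y_eff[train])
        if len(np.unique(np.sign(y_eff[train]))) < 2:
            raise ValueError(f"outer fold {f}: single-class training set")
        if center_cache is not None and f in center_cache:
            ktrain_raw, kc, kfit = center_cache[f]
        else:
            ktrain_raw = kset_raw.epoch_subset(train)
            kc = center_and_normalize(kset_raw, train)
            kfit = kc.epoch_subset(train)
            if center_cache is not None:
                center_cache[f] = (ktrain_raw, kc, kfit)
        best_C = _inner_select_C(ktrain_raw, y_eff[train], tuple(C_grid),
                                 inner_k, int(rng_seeds[f] % (2 ** 31)),
                                 tol, max_iter, svm_tol)
        model = simple_mkl_fit(kfit, y_eff[train], C=best_C,
                               tol=tol, max_iter=max_iter, svm_tol=svm_tol,
                               train_idx=train)
        out = predict(model, kc.epoch_block(test, train))
        predictions[test] = out.predicted
        scores[test] = out.score
        chosen_C.append(best_C)
        fold_models.append(model)
        per_fold_d[f] = model.d
        per_fold_metrics.append(compute_metrics(out.predicted, y[test])
                                if len(np.unique(np.sign(y[test]))) > 1 else {})

    metrics = compute_metrics(predictions, y)
    return CVResult(plan=outer, chosen_C=chosen_C, fold_models=fold_models,
                    per_fold_d=per_fold_d, predictions=predictions, scores=scores,
                    metrics=metrics, per_fold_metrics=per_fold_metrics)


@dataclass
class PermutationResult:
    """Permutation null distributions and p-values per metric."""

    n_perm: int
    observed: dict[str, float]
    null: dict[str, np.ndarray]
    p_values: dict[str, float]
    significant: dict[str, bool]
    alpha: float = 0.05


def permutation_test(kset_raw: KernelSet, y: np.ndarray, outer: FoldPlan,
                     n_perm: int = 1000, seed: int = 0,
                     C_grid: tuple[float, ...] = DEFAULT_C_GRID,
                     inner_k: int = DEFAULT_INNER_K, tol: float = 0.01,
                     max_iter: int = 200, alpha: float = 0.05,
                     scope: str = "global",
                     observed: CVResult | None = None) -> PermutationResult:
    """Non-parametric significance of the nested-CV performance.

    For each of ``n_perm`` permutations the training labels are shuffled
    and the full nested CV is rerun; ``p = (1 + #{null >= observed}) /
    (1 + n_perm)``.  Balanced accuracy is flagged significant only when
    *both* class accuracies are individually significant.

    ``scope`` controls how labels are shuffled:

    * ``"global"`` (default): one label permutation per replicate, applied
      consistently to every fold's training set and to the scoring of its
      test set.  Under the null hypothesis the permuted runs are exactly
      exchangeable with the observed run, so the p-values are valid even
      with heavily overlapping training sets.
    * ``"within_train"``: labels are re-shuffled independently inside each
      outer-training set and test sets keep their true labels.  This
      destroys the between-fold correlation the observed statistic has
      (every fold shares one consistent labelling), which inflates the
      spread of the observed metric relative to this null at small sample
      sizes; it is kept for comparison.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scope not in ("global", "within_train"):
        raise ValueError(f"unknown permutation scope {scope!r}")
    if observed is None:
        observed = nested_cv(kset_raw, y, outer, C_grid=C_grid, inner_k=inner_k,
                             tol=tol, max_iter=max_iter, seed=seed)
    keys = ("balanced_acc", "math_acc", "nonmath_acc")
    null = {k: np.empty(n_perm) for k in keys}
    children = np.random.SeedSequence(seed).spawn(n_perm)
    cache: dict = {}
    y = np.asarray(y, dtype=float)
    for p in range(n_perm):
        rng = np.random.default_rng(children[p])
        if scope == "global":
            res = nested_cv(kset_raw, rng.permutation(y), outer, C_grid=C_grid,
                            inner_k=inner_k, tol=tol, max_iter=max_iter,
                            seed=seed, center_cache=cache)
        else:
            res = nested_cv(kset_raw, y, outer, C_grid=C_grid, inner_k=inner_k,
                            tol=tol, max_iter=max_iter, seed=seed,
                            train_label_rng=rng, center_cache=cache)
        for k in keys:
            null[k][p] = res.metrics[k]
    p_values = {k: float((1 + np.sum(null[k] >= observed.metrics[k] - 1e-12))
                         / (1 + n_perm)) for k in keys}
    significant = {k: p_values[k] < alpha for k in keys}
    significant["balanced_acc"] = (p_values["math_acc"] < alpha
                                   and p_values["nonmath_acc"] < alpha)
    return PermutationResult(n_perm=n_perm,
                             observed={k: observed.metrics[k] for k in keys},
                             null=null, p_values=p_values,
                             significant=significant, alpha=alpha)
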