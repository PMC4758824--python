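"""Sparse multiple kernel learning (simpleMKL-style solver).

The classifier combines M precomputed kernels with non-negative
contributions ``d`` on the probability simplex (``sum d_m = 1``), which
induces sparsity: most contributions end exactly at zero.  Training
alternates (i) an SVM dual solve on the weighted kernel sum ``K(d) =
sum_m d_m K_m`` and (ii) a reduced-gradient descent step on ``d`` over the
simplex, with a bracketing + golden-section line search.  Convergence is
declared when the relative duality gap of the kernel-combination problem
drops below ``tol``.

For linear kernels the per-kernel primal weights are recoverable from the
dual solution, giving one weight per time sample per (channel, band) pair.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kernels import KernelSet
from .svm import bias_from_gradient, solve_warm
from .timefreq import BandFeatureTensor

logger = logging.getLogger(__name__)

DEFAULT_TOL = 0.01
DEFAULT_MAX_ITER = 200


@dataclass
class MKLModel:
    """Fitted sparse-MKL classifier.

    ``d`` holds the kernel contributions on the simplex (exact zeros for
    pinned kernels); ``alpha``/``b`` the SVM dual solution on the weighted
    kernel sum; ``objective`` the final value of J(d).
    """

    d: np.ndarray
    alpha: np.ndarray
    b: float
    C: float
    y_train: np.ndarray
    objective: float
    n_iter: int
    converged: bool
    index: list[tuple[str, str]] = field(default_factory=list)
    scales: np.ndarray | None = None
    train_idx: np.ndarray | None = None
    objective_history: list[float] = field(default_factory=list)

    @property
    def support(self) -> np.ndarray:
        """Indices of training epochs with alpha > 0."""
        return np.flatnonzero(self.alpha > 1e-10 * max(self.C, 1.0))


@dataclass
class DecisionOutput:
    """Per-epoch decision values and their per-kernel breakdown."""

    score: np.ndarray                 # (n_test,)
    per_kernel_score: np.ndarray      # (n_kernels, n_test)
    predicted: np.ndarray             # +/-1

    def __post_init__(self) -> None:
        assert np.allclose(self.score,
                           self.per_kernel_score.sum(axis=0) + self._b, atol=1e-8)

    _b: float = 0.0


def _quadforms(Ks: np.ndarray, w: np.ndarray) -> np.ndarray:
    """S_m = 1/2 w^T K_m w for every kernel m (one flattened BLAS matvec)."""
    M, n = Ks.shape[0], Ks.shape[1]
    KW = (Ks.reshape(M * n, n) @ w).reshape(M, n)
    return 0.5 * (KW @ w)


def _weighted_sum(Ks: np.ndarray, w: np.ndarray) -> np.ndarray:
    M, n = Ks.shape[0], Ks.shape[1]
    return (w @ Ks.reshape(M, n * n)).reshape(n, n)


def mkl_objective_and_gradient(kset: KernelSet, y: np.ndarray, d: np.ndarray,
                               C: float, svm_tol: float = 1e-8,
                               ) -> tuple[float, np.ndarray]:
    """J(d) and its gradient over d.

    ``J(d)`` is the optimal SVM dual value on ``K(d) = sum_m d_m K_m``;
    by Danskin's theorem ``dJ/dd_m = -1/2 sum_ij a_i a_j y_i y_j K_m[i,j]``
    at the optimal ``a``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < -1e-12) or abs(d.sum() - 1.0) > 1e-8:
        raise ValueError("d must lie on the simplex")
    y = np.asarray(y, dtype=float)
    Kd = _weighted_sum(kset.kernels, d)
    alpha, G, J, _ = solve_warm(Kd, y, C, tol=svm_tol)
    S = _quadforms(kset.kernels, alpha * y)
    return J, -S


def simple_mkl_fit(kset: KernelSet, y: np.ndarray, C: float = 1.0,
                   tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
                   svm_tol: float = 1e-8, train_idx: np.ndarray | None = None,
                   d_init: np.ndarray | None = None,
                   alpha_init: np.ndarray | None = None,
                   stall_tol: float = 1e-3) -> MKLModel:
    """Fit the sparse-MKL classifier.

    Parameters
    ----------
    kset
        Centered + normalized kernels over the training epochs.
    y
        Labels in {-1, +1}.
    C
        Soft-margin parameter.
    tol
        Relative duality gap below which iteration stops.
    max_iter
        Cap on alternating iterations; non-convergence returns the best
        iterate with ``converged=False`` and a warning.
    d_init, alpha_init
        Optional warm starts (e.g. from a fit at a neighbouring C); the
        default initialization is uniform over non-degenerate kernels.
    stall_tol
        Secondary stop: iteration also ends once the relative objective
        decrease stays below this for two consecutive iterations (the
        duality gap shrinks slowly on unstructured data while the iterate
        is already stationary for practical purposes).  Set to 0 to stop
        on the duality gap alone.
    """
    Ks = kset.kernels
    M, n = Ks.shape[0], Ks.shape[1]
    y = np.asarray(y, dtype=float)
    if len(y) != n:
        raise ValueError("label length must match kernel size")
    if len(np.unique(np.sign(y))) < 2:
        raise ValueError("both classes must be present")
    active = ~kset.degenerate
    if not np.any(active):
        raise ValueError("all kernels degenerate")

    if d_init is not None and d_init.sum() > 0:
        d = np.where(active, np.clip(d_init, 0.0, None), 0.0)
        d = d / d.sum()
    else:
        d = np.zeros(M)
        d[active] = 1.0 / active.sum()
    Kd = _weighted_sum(Ks, d)
    alpha = None if alpha_init is None else alpha_init
    converged = False
    J = np.inf
    it = 0

    def evaluate(Kmat: np.ndarray, warm: np.ndarray | None):
        a, G, obj, _ = solve_warm(Kmat, y, C, alpha0=warm, tol=svm_tol)
        return a, G, obj

    J_prev = np.inf
    n_stalled = 0
    history: list[float] = []
    for it in range(1, max_iter + 1):
        alpha, G, J = evaluate(Kd, alpha)
        history.append(J)
        S = _quadforms(Ks, alpha * y)
        S[~active] = -np.inf  # degenerate kernels never attract weight
        gap = np.max(S[active]) - float(d @ np.where(np.isfinite(S), S, 0.0))
        if gap / max(abs(J), 1e-12) <= tol:
            converged = True
            break
        if stall_tol > 0 and J_prev - J <= stall_tol * max(abs(J), 1e-12):
            n_stalled += 1
            if n_stalled >= 2:
                converged = True
                break
        else:
            n_stalled = 0
        J_prev = J

        g = -S  # gradient; +inf on degenerate -> direction stays 0 there
        mu = int(np.flatnonzero(d == d.max())[0])
        r = g - g[mu]
        D = np.zeros(M)
        for m in range(M):
            if not active[m] or m == mu:
                continue
            if d[m] > 0 or r[m] < 0:
                D[m] = -r[m]
        D[mu] = -D.sum()
        if np.abs(D).max() <= 1e-12:
            converged = True
            break

        # descent along D: accept full steps while J decreases, pinning the
        # coordinate that reaches zero, then golden-section the remainder
        d_cur, J_cur, a_cur = d.copy(), J, alpha.copy()
        improved = False
        K_D = _weighted_sum(Ks, D)
        for _ in range(M + 1):
            neg = D < -1e-15
            if not np.any(neg):
                break
            steps = -d_cur[neg] / D[neg]
            gamma_max = steps.min()
            if gamma_max <= 1e-16:
                break
            d_full = d_cur + gamma_max * D
            d_full[np.abs(d_full) < 1e-15] = 0.0
            a_t, _, J_full = evaluate(Kd + gamma_max * K_D, a_cur)
            if J_full < J_cur:
                d_cur, J_cur, a_cur = d_full, J_full, a_t
                Kd = Kd + gamma_max * K_D
                improved = True
                pinned = np.flatnonzero((d_cur == 0.0) & (D < 0))
                if mu in pinned:
                    break  # reference coordinate exhausted; re-derive direction
                old_pinned = D[pinned].copy()
                old_mu = D[mu]
                D[pinned] = 0.0
                D[mu] = 0.0
                D[mu] = -D.sum()
                if np.abs(D).max() <= 1e-12:
                    break
                # incremental update: only pinned kernels and mu changed
                for p_, w_ in zip(pinned, old_pinned):
                    K_D -= w_ * Ks[p_]
                K_D += (D[mu] - old_mu) * Ks[mu]
            else:
                # golden-section search on [0, gamma_max]
                phi = (np.sqrt(5.0) - 1.0) / 2.0
                lo, hi = 0.0, gamma_max
                x1 = hi - phi * (hi - lo)
                x2 = lo + phi * (hi - lo)
                a1, _, f1 = evaluate(Kd + x1 * K_D, a_cur)
                a2, _, f2 = evaluate(Kd + x2 * K_D, a_cur)
                best_g, best_J, best_a = (x1, f1, a1) if f1 < f2 else (x2, f2, a2)
                for _ls in range(10):
                    if f1 < f2:
                        hi, x2, f2, a2 = x2, x1, f1, a1
                        x1 = hi - phi * (hi - lo)
                        a1, _, f1 = evaluate(Kd + x1 * K_D, best_a)
                        if f1 < best_J:
                            best_g, best_J, best_a = x1, f1, a1
                    else:
                        lo, x1, f1, a1 = x1, x2, f2, a2
                        x2 = lo + phi * (hi - lo)
                        a2, _, f2 = evaluate(Kd + x2 * K_D, best_a)
                        if f2 < best_J:
                            best_g, best_J, best_a = x2, f2, a2
                    if hi - lo < 5e-2 * gamma_max:
                        break
                if best_J < J_cur:
                    d_cur = d_cur + best_g * D
                    d_cur[np.abs(d_cur) < 1e-15] = 0.0
                    J_cur, a_cur = best_J, best_a
                    Kd = Kd + best_g * K_D
                    improved = True
                break
        d, alpha = d_cur, a_cur
        # simplex hygiene: exact zeros kept, renormalize the rest
        d = np.clip(d, 0.0, None)
        s = d.sum()
        if s <= 0:
            raise RuntimeError("kernel contributions collapsed to zero")
        if abs(s - 1.0) > 1e-12:
            d = d / s
            Kd = Kd / s
        if it % 8 == 0:
            Kd = _weighted_sum(Ks, d)  # counter accumulated drift
        if not improved:
            converged = True
            alpha, G, J = evaluate(Kd, alpha)
            break
    else:
        it = max_iter

    if not converged:
        warnings.warn("simple_mkl_fit: max_iter reached before duality-gap "
                      "tolerance; returning best iterate", RuntimeWarning)
    alpha, G, J = solve_warm(Kd, y, C, alpha0=alpha, tol=svm_tol)[0:3]
    b = bias_from_gradient(y, C, alpha, G)
    return MKLModel(d=d, alpha=alpha, b=b, C=C, y_train=y.copy(), objective=J,
                    n_iter=it, converged=converged, index=list(kset.index),
                    scales=getattr(kset, "scales", None),
                    train_idx=None if train_idx is None else np.asarray(train_idx),
                    objective_history=history)


def predict(model: MKLModel, test_blocks: np.ndarray) -> DecisionOutput:
    """Decision values for test epochs.

    Parameters
    ----------
    model
        A fitted model.
    test_blocks
        ``(n_kernels, n_test, n_train)`` cross-kernel blocks, centered and
        normalized with the *training* statistics.
    """
    test_blocks = np.asarray(test_blocks)
    if test_blocks.ndim != 3 or test_blocks.shape[2] != len(model.alpha):
        raise ValueError("test_blocks must be (n_kernels, n_test, n_train)")
    if test_blocks.shape[0] != len(model.d):
        raise ValueError("kernel count mismatch")
    ay = model.alpha * model.y_train
    per_kernel = model.d[:, None] * (test_blocks @ ay)
    score = per_kernel.sum(axis=0) + model.b
    out = DecisionOutput(score=score, per_kernel_score=per_kernel,
                         predicted=np.where(score >= 0, 1.0, -1.0), _b=model.b)
    return out


def predict_training(model: MKLModel, kset: KernelSet) -> DecisionOutput:
    """Decision values on the training epochs themselves."""
    return predict(model, kset.kernels)


def primal_feature_weights(model: MKLModel, features: BandFeatureTensor,
                           train_idx: np.ndarray) -> np.ndarray:
    """Per-kernel primal weight vectors ``w_m`` for linear kernels.

    ``w_m = d_m sum_i alpha_i y_i x_i^(m)`` in the train-mean-centered,
    scale-normalized feature space; ``<w_m, x~>`` reproduces the kernel
    per-kernel score for a test epoch with features ``x~`` transformed the
    same way.  Requires the centering scales recorded at kernel
    normalization time.
    """
    if model.scales is None:
        raise ValueError("model carries no normalization scales "
                         "(kernels were not centered+normalized)")
    n_ep, n_ch, n_bands, T = features.values.shape
    train_idx = np.asarray(train_idx, dtype=int)
    ay = model.alpha * model.y_train
    W = np.zeros((len(model.d), T))
    m = 0
    for c in range(n_ch):
        for b in range(n_bands):
            if model.d[m] > 0:
                X = features.values[:, c, b, :]
                mu = X[train_idx].mean(axis=0)
                Xt = (X[train_idx] - mu) / np.sqrt(model.scales[m])
                W[m] = model.d[m] * (ay @ Xt)
            m += 1
    return W


def save_model(model: MKLModel, path: str | Path) -> None:
    """Serialize a fitted model to a single ``.npz`` archive."""
    np.savez(Path(path), d=model.d, alpha=model.alpha, b=model.b, C=model.C,
             y_train=model.y_train, objective=model.objective,
             n_iter=model.n_iter, converged=model.converged,
             index_channel=np.array([i[0] for i in model.index]),
             index_band=np.array([i[1] for i in model.index]),
             scales=model.scales if model.scales is not None else np.array([]),
             train_idx=model.train_idx if model.train_idx is not None else np.array([]))


def load_model(path: str | Path) -> MKLModel:
    with np.load(Path(path)) as z:
        index = list(zip([str(c) for c in z["index_channel"]],
                         [str(b) for b in z["index_band"]]))
        scales = z["scales"] if z["scales"].size else None
        train_idx = z["train_idx"] if z["train_idx"].size else None
        return MKLModel(d=z["d"], alpha=z["alpha"], b=float(z["b"]), C=float(z["C"]),
                        y_train=z["y_train"], objective=float(z["objective"]),
                        n_iter=int(z["n_iter"]), converged=bool(z["converged"]),
                        index=index, scales=scales, train_idx=train_idx)
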