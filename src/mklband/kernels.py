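"""Linear kernels per (channel, band) with train-aware centering/normalization.

Each kernel is the epoch-by-epoch Gram matrix of one channel's log
band-power time course.  Centering removes the *training-set* feature mean
in feature space (so test epochs never influence the statistics) and
normalization divides by the mean diagonal of the train-train block, making
kernel scale irrelevant to the classifier.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timefreq import BandFeatureTensor

logger = logging.getLogger(__name__)

#: Relative threshold below which a train-block trace flags a degenerate kernel.
DEGENERATE_REL_TOL = 1e-12


@dataclass
class KernelSet:
    """An ordered stack of n x n similarity matrices.

    ``kernels`` has shape ``(n_kernels, n, n)``; ``index`` lists the
    (channel, band) pair behind each kernel, channel-major and band-minor,
    so kernel ``c * n_bands + b`` belongs to channel ``c``, band ``b``.
    ``degenerate`` marks kernels whose training block is constant; their
    contribution is forced to zero downstream.
    """

    kernels: np.ndarray
    index: list[tuple[str, str]]
    state: str = "raw"
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]
    scales: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=np.float64)
        if self.kernels.ndim != 3 or self.kernels.shape[1] != self.kernels.shape[2]:
            raise ValueError("kernels must be (n_kernels, n, n)")
        if len(self.index) != self.kernels.shape[0]:
            raise ValueError("index length must match kernel count")
        if self.degenerate is None:
            self.degenerate = np.zeros(self.kernels.shape[0], dtype=bool)

    @property
    def n_kernels(self) -> int:
        return self.kernels.shape[0]

    @property
    def n(self) -> int:
        return self.kernels.shape[1]

    def index_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.index, columns=["channel", "band"])

    def select(self, mask: np.ndarray) -> "KernelSet":
        """Subset of kernels (e.g. a single band's)."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return KernelSet(self.kernels[idx], [self.index[i] for i in idx],
                         self.state, self.degenerate[idx].copy(),
                         None if self.scales is None else self.scales[idx].copy())

    def epoch_subset(self, idx: np.ndarray) -> "KernelSet":
        """Restrict every kernel to the epochs in ``idx`` (rows and columns)."""
        idx = np.asarray(idx, dtype=int)
        sub = np.ascontiguousarray(self.kernels[:, idx[:, None], idx[None, :]])
        return KernelSet(sub, list(self.index), self.state, self.degenerate.copy(),
                         None if self.scales is None else self.scales.copy())

    def epoch_block(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Cross blocks ``(n_kernels, len(rows), len(cols))`` (e.g. test-train)."""
        rows = np.asarray(rows, dtype=int)
        cols = np.asarray(cols, dtype=int)
        return self.kernels[:, rows[:, None], cols[None, :]]


def build_linear_kernels(features: BandFeatureTensor) -> KernelSet:
    """Dot-product kernels, one per (channel, band) pair.

    ``K_m[i, j] = <x_i, x_j>`` over the band-power time course of pair m.
    """
    n_ep, n_ch, n_bands, _ = features.values.shape
    kernels = np.empty((n_ch * n_bands, n_ep, n_ep))
    index: list[tuple[str, str]] = []
    m = 0
    for c in range(n_ch):
        for b in range(n_bands):
            X = features.values[:, c, b, :]
            kernels[m] = X @ X.T
            index.append((features.ch_names[c], features.band_names[b]))
            m += 1
    return KernelSet(kernels, index, state="raw")


def center_and_normalize(kset: KernelSet, train_idx: np.ndarray) -> KernelSet:
    """Feature-space centering and scaling using training statistics only.

    ``K_c[i,j] = K[i,j] - mean_t K[i,t] - mean_t K[t,j] + mean_tt' K[t,t']``
    with t, t' ranging over ``train_idx``; each kernel is then divided by
    the mean diagonal of its centered train-train block.  A kernel whose
    train block is constant (zero trace after centering) is flagged
    degenerate and zeroed with a warning.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    if train_idx.size == 0:
        raise ValueError("train_idx must be non-empty")
    if train_idx.min() < 0 or train_idx.max() >= kset.n:
        raise ValueError("train_idx out of range")
    Ks = kset.kernels
    degenerate = kset.degenerate.copy()
    # batched over kernels: K_c = K - row - col + grand, then / trace-scale
    row = Ks[:, :, train_idx].mean(axis=2)            # (M, n)
    col = Ks[:, train_idx, :].mean(axis=1)            # (M, n)
    grand = Ks[:, train_idx[:, None], train_idx[None, :]].mean(axis=(1, 2))
    out = Ks - row[:, :, None] - col[:, None, :] + grand[:, None, None]
    diag_tt = out[:, train_idx, train_idx]
    scales = diag_tt.mean(axis=1)                     # trace/|train| per kernel
    ref = np.abs(Ks[:, train_idx, train_idx]).mean(axis=1) + 1e-300
    bad = scales <= DEGENERATE_REL_TOL * ref
    for m in np.flatnonzero(bad & ~degenerate):
        logger.warning("kernel %s degenerate on training set; zeroed", kset.index[m])
    degenerate |= bad
    scales = np.where(bad, 1.0, scales)
    out /= scales[:, None, None]
    out[bad] = 0.0
    return KernelSet(out, list(kset.index), state="centered+normalized",
                     degenerate=degenerate, scales=scales)
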