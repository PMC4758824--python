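"""Shared fixtures: small synthetic problems reused across test modules."""
from __future__ import annotations

import numpy as np
import pytest

import mklband as m
from mklband.kernels import KernelSet, center_and_normalize


@pytest.fixture(scope="session")
def separable_two_kernel():
    """One kernel with a clearly separable pattern + one pure-noise kernel.

    Returns (centered KernelSet, labels); n = 40 epochs.
    """
    rng = np.random.default_rng(7)
    Xi = np.concatenate([rng.normal(3.0, 1.0, (20, 6)),
                         rng.normal(-3.0, 1.0, (20, 6))])
    Xn = rng.normal(size=(40, 6))
    y = np.concatenate([np.ones(20), -np.ones(20)])
    ks = KernelSet(np.stack([Xi @ Xi.T, Xn @ Xn.T]),
                   [("ch_sig", "high_gamma"), ("ch_noise", "high_gamma")])
    return center_and_normalize(ks, np.arange(40)), y


@pytest.fixture(scope="session")
def random_kernel_problem():
    """Three random PSD kernels over 12 epochs, balanced labels."""
    rng = np.random.default_rng(5)
    n, M = 12, 3
    Ks = np.empty((M, n, n))
    for mm in range(M):
        X = rng.normal(size=(n, 4))
        Ks[mm] = X @ X.T
    y = np.concatenate([np.ones(6), -np.ones(6)])
    return KernelSet(Ks, [("c0", "delta"), ("c1", "theta"), ("c2", "alpha")]), y


@pytest.fixture(scope="session")
def synth_decoding_dataset():
    """Small end-to-end dataset: 4 channels, one strong informative pair.

    Yields (raw KernelSet, labels, features, epoch set, informative kernel
    index).  Built once per session; used by evaluation/pipeline tests.
    """
    cfg = m.SynthConfig(n_channels=4, sfreq_hz=512.0, n_events_per_class=40,
                        informative_pairs=((1, "high_gamma"),), effect_gain=4.0,
                        rt_range_s=(1.05, 1.95), isi_s=1.0, seed=11)
    rec, truth = m.generate_recording(cfg)
    rec = m.preprocess(rec, target_hz=256.0)
    ep = m.balance_classes(m.label_windows(truth.event_table, rec.duration_s),
                           seed=12)
    tensor = m.extract_epochs(rec, ep)
    feats = m.compute_band_features(tensor, rec.sfreq_hz, (-200.0, 1200.0),
                                    ch_names=rec.ch_names)
    kset = m.build_linear_kernels(feats)
    info_idx = next(i for i, (c, b) in enumerate(kset.index)
                    if c == "ch1" and b == "high_gamma")
    return kset, ep.y, feats, ep, info_idx
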