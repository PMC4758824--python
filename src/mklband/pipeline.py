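"""End-to-end pipeline: preprocess -> events -> features -> kernels -> CV
-> permutations -> reports, driven by a single YAML-able configuration.

One global seed expands deterministically into per-stage seeds, so a rerun
with the same configuration reproduces every CSV byte-for-byte.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, events, interpret, kernels, preprocess, timefreq
from .containers import load_coords, load_events, load_recording
from .mkl import save_model

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration of a full decoding run.

    ``mode`` is either ``"full"`` (channels x 6 kernels) or
    ``"single_band:<name>"`` (one kernel per channel, that band only).
    """

    recording: str = ""
    events: str = ""
    coords: str = ""
    out_dir: str = "mklband_run"
    # preprocessing
    line_hz: float = 60.0
    n_harmonics: int = 3
    target_hz: float = 436.0
    # epoching
    window_ms: tuple[float, float] = (-200.0, 1200.0)
    # features
    n_freqs: int = 29
    f_lo: float = 1.0
    f_hi: float = 110.0
    n_cycles: float = 7.0
    # model
    C_grid: tuple[float, ...] = evaluation.DEFAULT_C_GRID
    tol: float = 0.01
    max_iter: int = 200
    mode: str = "full"
    # cross-validation
    k: int = 10
    inner_k: int = 5
    scheme: str = "contiguous_blocks"
    # permutations (0 disables)
    n_perm: int = 0
    seed: int = 0
    top_k: int = 10

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["window_ms"] = list(self.window_ms)
        d["C_grid"] = list(self.C_grid)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "window_ms" in d:
            d["window_ms"] = tuple(d["window_ms"])
        if "C_grid" in d:
            d["C_grid"] = tuple(d["C_grid"])
        return cls(**d)


@dataclass
class PipelineResult:
    """Handles to everything a run produced."""

    config: PipelineConfig
    cv: evaluation.CVResult
    report: interpret.ContributionReport
    permutation: evaluation.PermutationResult | None
    out_dir: Path
    kset_index: list[tuple[str, str]] = field(default_factory=list)


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("balance", "folds", "cv", "perm")
    states = ss.generate_state(len(names))
    return {n: int(s % (2 ** 31)) for n, s in zip(names, states)}


def prepare_dataset(rec, event_table, *, line_hz: float = 60.0,
                    n_harmonics: int = 3, target_hz: float = 436.0,
                    window_ms: tuple[float, float] = (-200.0, 1200.0),
                    n_freqs: int = 29, f_lo: float = 1.0, f_hi: float = 110.0,
                    n_cycles: float = 7.0, balance_seed: int = 0):
    """Recording + events -> (raw KernelSet, labeled epochs, features).

    Runs the conditioning chain, window labeling, class balancing, Morlet
    band features and kernel construction — everything up to (but not
    including) the train/test-aware centering, which belongs inside the
    cross-validation loop.
    """
    rec = preprocess.preprocess(rec, line_hz=line_hz, n_harmonics=n_harmonics,
                                target_hz=target_hz)
    epochs_set = events.label_windows(event_table, rec.duration_s,
                                      rec.session_id)
    epochs_set = events.balance_classes(epochs_set, seed=balance_seed)
    tensor = events.extract_epochs(rec, epochs_set, window_ms=window_ms)
    freqs = timefreq.default_freq_grid(n_freqs, f_lo, f_hi)
    feats = timefreq.compute_band_features(tensor, rec.sfreq_hz, window_ms,
                                           freqs=freqs, n_cycles=n_cycles,
                                           ch_names=rec.ch_names)
    return kernels.build_linear_kernels(feats), epochs_set, feats


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write all outputs to ``out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("mklband")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    seeds = _stage_seeds(config.seed)
    try:
        logger.info("config: %s", dataclasses.asdict(config))
        logger.info("stage seeds: %s", seeds)

        rec = load_recording(config.recording)
        ev = load_events(config.events)
        logger.info("loaded %d channels, %.1f s, %d events",
                    rec.n_channels, rec.duration_s, len(ev))

        kset, epochs_set, feats = prepare_dataset(
            rec, ev, line_hz=config.line_hz, n_harmonics=config.n_harmonics,
            target_hz=config.target_hz, window_ms=config.window_ms,
            n_freqs=config.n_freqs, f_lo=config.f_lo, f_hi=config.f_hi,
            n_cycles=config.n_cycles, balance_seed=seeds["balance"])
        logger.info("%d balanced epochs", len(epochs_set))
        epochs_set.to_frame().to_csv(out_dir / "epochs.csv", index=False)
        if config.mode.startswith("single_band:"):
            band = config.mode.split(":", 1)[1]
            mask = np.array([b == band for _, b in kset.index])
            if not mask.any():
                raise ValueError(f"unknown band in mode: {band!r}")
            kset = kset.select(mask)
        elif config.mode != "full":
            raise ValueError(f"unknown mode {config.mode!r}")
        kset.index_frame().to_csv(out_dir / "kernel_index.csv", index=False)
        logger.info("%d kernels over %d epochs", kset.n_kernels, kset.n)

        y = epochs_set.y
        plan = evaluation.make_folds(len(y), k=config.k, scheme=config.scheme,
                                     seed=seeds["folds"], labels=y)
        cv = evaluation.nested_cv(kset, y, plan, C_grid=config.C_grid,
                                  inner_k=config.inner_k, tol=config.tol,
                                  max_iter=config.max_iter, seed=seeds["cv"])
        report = interpret.build_report(cv.per_fold_d, kset.index,
                                        top_k=config.top_k)
        interpret.write_report(report, out_dir)
        for f, model in enumerate(cv.fold_models):
            save_model(model, out_dir / f"model_fold{f}.npz")

        perm = None
        if config.n_perm > 0:
            perm = evaluation.permutation_test(
                kset, y, plan, n_perm=config.n_perm, seed=seeds["perm"],
                C_grid=config.C_grid, inner_k=config.inner_k, tol=config.tol,
                max_iter=config.max_iter, observed=cv)
            logger.info("permutation p-values: %s", perm.p_values)

        summary = {
            "metrics": cv.metrics,
            "chosen_C": cv.chosen_C,
            "stability": report.stability,
            "band_totals_pct": {str(k): float(v)
                                for k, v in report.band_totals.items()},
        }
        if perm is not None:
            summary["permutation"] = {"n_perm": perm.n_perm,
                                      "p_values": perm.p_values,
                                      "significant": perm.significant}
        (out_dir / "metrics.json").write_text(json.dumps(summary, indent=2))
        if config.coords:
            interpret.contribution_scatter(report.mean_d_pct, kset.index,
                                           load_coords(config.coords), out_dir)
        logger.info("run complete; pooled balanced accuracy %.2f%%",
                    cv.metrics["balanced_acc"])
    finally:
        root.removeHandler(handler)
        handler.close()
    return PipelineResult(config=config, cv=cv, report=report, permutation=perm,
                          out_dir=out_dir, kset_index=list(kset.index))
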