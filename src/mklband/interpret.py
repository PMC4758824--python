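"""Localization reports from per-fold kernel contributions.

The fitted contributions d_m tie each kernel to a (channel, band) pair, so
averaging them across cross-validation folds yields an anatomical x
spectral map of where the discriminating signal lives: per-kernel mean
contributions (in %, summing to 100), fold-stability counts, per-band
totals and a ranked top-k table.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BAND_NAMES

logger = logging.getLogger(__name__)


def average_contributions(per_fold_d: np.ndarray) -> np.ndarray:
    """Mean contribution per kernel across folds, in % (sums to 100)."""
    per_fold_d = np.asarray(per_fold_d, dtype=float)
    if per_fold_d.ndim != 2 or per_fold_d.shape[0] == 0:
        raise ValueError("per_fold_d must be (n_folds, n_kernels) with >= 1 fold")
    if np.any(per_fold_d < -1e-12) or not np.allclose(per_fold_d.sum(axis=1), 1.0,
                                                      atol=1e-6):
        raise ValueError("each fold's d must lie on the simplex")
    return per_fold_d.mean(axis=0) * 100.0


def stability_counts(per_fold_d: np.ndarray, frac_threshold: float = 0.8,
                     eps: float = 0.0) -> dict[str, int]:
    """How many kernels keep a non-zero contribution across folds.

    A kernel counts as selected in a fold iff ``d_m > eps`` there (the
    solver pins discarded kernels at exactly zero, so ``eps=0`` is exact).
    Returns counts for selection in >= 1 fold, in >= ceil(frac*k) folds
    and in all k folds.
    """
    per_fold_d = np.asarray(per_fold_d, dtype=float)
    k = per_fold_d.shape[0]
    n_sel = (per_fold_d > eps).sum(axis=0)
    return {
        "any_fold": int(np.sum(n_sel >= 1)),
        "frac_folds": int(np.sum(n_sel >= int(np.ceil(frac_threshold * k)))),
        "all_folds": int(np.sum(n_sel == k)),
    }


def band_summed_contributions(mean_d_pct: np.ndarray,
                              index: list[tuple[str, str]]) -> pd.Series:
    """Sum mean contributions over channels within each band (totals 100%)."""
    if len(index) != len(mean_d_pct):
        raise ValueError("index length mismatch")
    bands = [b for _, b in index]
    s = pd.Series(mean_d_pct).groupby(pd.Series(bands)).sum()
    order = [b for b in BAND_NAMES if b in s.index]
    extra = [b for b in s.index if b not in order]
    return s.reindex(order + extra)


def rank_contributions(mean_d_pct: np.ndarray, index: list[tuple[str, str]],
                       k: int = 10) -> pd.DataFrame:
    """Top-k (band, channel, mean d_m %) table, descending contribution.

    Ties break by canonical band order then channel index/name.
    """
    if k > len(mean_d_pct):
        raise ValueError("k exceeds number of kernels")
    band_order = {b: i for i, b in enumerate(BAND_NAMES)}
    rows = [(band, ch, float(v)) for (ch, band), v in zip(index, mean_d_pct)]
    rows.sort(key=lambda r: (-r[2], band_order.get(r[0], len(band_order)), r[1]))
    return pd.DataFrame(rows[:k], columns=["band", "channel", "mean_d_pct"])


@dataclass
class ContributionReport:
    """All localization outputs of one cross-validated model."""

    mean_d_pct: np.ndarray
    per_fold_d: np.ndarray
    index: list[tuple[str, str]]
    stability: dict[str, int]
    band_totals: pd.Series
    top_k: pd.DataFrame

    def contributions_frame(self) -> pd.DataFrame:
        n_sel = (self.per_fold_d > 0).sum(axis=0)
        return pd.DataFrame({
            "channel": [c for c, _ in self.index],
            "band": [b for _, b in self.index],
            "mean_d_pct": self.mean_d_pct,
            "n_folds_selected": n_sel,
        })


def build_report(per_fold_d: np.ndarray, index: list[tuple[str, str]],
                 top_k: int = 10) -> ContributionReport:
    mean_d = average_contributions(per_fold_d)
    return ContributionReport(
        mean_d_pct=mean_d, per_fold_d=np.asarray(per_fold_d, dtype=float),
        index=list(index), stability=stability_counts(per_fold_d),
        band_totals=band_summed_contributions(mean_d, index),
        top_k=rank_contributions(mean_d, index, k=min(top_k, len(index))))


def write_report(report: ContributionReport, out_dir: str | Path) -> None:
    """Write contributions.csv, band_totals.csv, stability.csv, top_k.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.contributions_frame().to_csv(out_dir / "contributions.csv", index=False)
    report.band_totals.rename_axis("band").to_frame("total_d_pct").to_csv(
        out_dir / "band_totals.csv")
    pd.DataFrame([report.stability]).to_csv(out_dir / "stability.csv", index=False)
    report.top_k.to_csv(out_dir / "top_k.csv", index=False)


def contribution_scatter(mean_d_pct: np.ndarray, index: list[tuple[str, str]],
                         coords: pd.DataFrame, out_dir: str | Path,
                         ) -> pd.DataFrame:
    """Per-band 2-D electrode maps colour-coded by contribution.

    Writes one PNG per band plus the underlying CSV (one row per channel x
    band).  Channels with exactly zero contribution get an unfilled
    marker; channels missing from the coordinate table are listed in the
    CSV but skipped in the figures with a warning.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    coord_map = {str(r["channel"]): (float(r["x"]), float(r["y"]))
                 for _, r in coords.iterrows()}
    df = pd.DataFrame({
        "channel": [c for c, _ in index],
        "band": [b for _, b in index],
        "mean_d_pct": mean_d_pct,
    })
    df.to_csv(out_dir / "contribution_scatter.csv", index=False)
    vmax = float(mean_d_pct.max()) if len(mean_d_pct) else 1.0
    for band in df["band"].unique():
        sub = df[df["band"] == band]
        fig, ax = plt.subplots(figsize=(5, 4))
        for _, row in sub.iterrows():
            if row["channel"] not in coord_map:
                logger.warning("channel %s has no coordinates; skipped in figure",
                               row["channel"])
                continue
            x, y = coord_map[row["channel"]]
            if row["mean_d_pct"] > 0:
                ax.scatter(x, y, c=[row["mean_d_pct"]], cmap="RdPu",
                           vmin=0.0, vmax=vmax, s=80, edgecolors="k")
            else:
                ax.scatter(x, y, facecolors="none", edgecolors="k", s=80)
        ax.set_title(f"contribution per electrode - {band}")
        ax.set_xlabel("x")
        ax.set_ylabel("y")
        fig.savefig(out_dir / f"scatter_{band}.png", dpi=100)
        plt.close(fig)
    return df
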