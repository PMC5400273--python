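"""Basic report figures: fold-induction profile, clustered heatmap, KM curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy

from .cluster import ClusterResult
from .differential import GroupComparison
from .score import RiskScoreResult

__all__ = ["fold_profile_plot", "heatmap_plot", "km_plot"]


def fold_profile_plot(comparison: GroupComparison, path: str | Path) -> None:
    """Bar profile of signed fold inductions, ascending, significance colored."""
    t = comparison.table
    folds = t["fold"].to_numpy()
    colors = [
        "red" if p < 0.05 else ("black" if p < 0.10 else "lightgray")
        for p in t["p"].fillna(1.0)
    ]
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.bar(range(len(t)), folds, color=colors)
    ax.set_xticks(range(len(t)))
    ax.set_xticklabels(t.index, rotation=90, fontsize=6)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("fold induction")
    ax.set_title(f"{comparison.case_label} vs {comparison.control_label}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def heatmap_plot(result: ClusterResult, path: str | Path) -> None:
    """Median-centered heatmap with patient (and gene) dendrogram ordering."""
    leaves = hierarchy.leaves_list(result.linkage)
    disp = result.display.iloc[:, leaves]
    if result.gene_linkage is not None:
        disp = disp.iloc[hierarchy.leaves_list(result.gene_linkage), :]
    fig, ax = plt.subplots(figsize=(8, 8))
    vmax = np.nanmax(np.abs(disp.to_numpy())) or 1.0
    im = ax.imshow(disp.to_numpy(), aspect="auto", cmap="RdYlGn_r", vmin=-vmax, vmax=vmax)
    ax.set_yticks(range(disp.shape[0]))
    ax.set_yticklabels(disp.index, fontsize=5)
    ax.set_xticks(range(disp.shape[1]))
    ax.set_xticklabels(disp.columns, rotation=90, fontsize=5)
    fig.colorbar(im, ax=ax, label="expression vs gene median (log2)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def km_plot(result: RiskScoreResult, path: str | Path) -> None:
    """Step KM curves for the low/high risk-score groups."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for curve, label, color in (
        (result.curve_low, f"score <= {result.s_star} (n={result.n_low})", "tab:blue"),
        (result.curve_high, f"score >= {result.s_star + 1} (n={result.n_high})", "tab:red"),
    ):
        t = np.concatenate([[0.0], np.repeat(curve.times, 2), [curve.max_observed_time]])
        s = np.concatenate([[1.0, 1.0], np.repeat(curve.survival, 2)[:-1], [curve.survival[-1] if curve.survival.size else 1.0]])
        ax.plot(t[: len(s)], s, label=label, color=color)
    ax.set_xlabel("months since diagnosis")
    ax.set_ylabel("relapse-free survival")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="lower left", fontsize=8)
    ax.set_title(f"log-rank p = {result.logrank.p_value:.3g} (in-sample)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
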