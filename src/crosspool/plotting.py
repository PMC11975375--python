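"""Figure exports: abundance bars, DE volcanoes, homology heatmap."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["abundance_barplot", "volcano_plot", "homology_heatmap"]


def abundance_barplot(da_table: pd.DataFrame, contrast: str, path=None):
    """log2 fold change per cluster, colored by -log10(FDR)."""
    tab = da_table[da_table["contrast"] == contrast].sort_values("log2_fold_change")
    fig, ax = plt.subplots(figsize=(8, max(2, 0.18 * len(tab))))
    colors = plt.cm.viridis(np.clip(-np.log10(tab["fdr"].clip(lower=1e-6)) / 6, 0, 1))
    ax.barh(tab["cluster"].astype(str), tab["log2_fold_change"], color=colors)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel(f"log2 fold change ({contrast})")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def volcano_plot(de_table: pd.DataFrame, path=None, fdr: float = 0.05):
    """log2FC vs -log10(FDR) with significant genes highlighted."""
    fig, ax = plt.subplots(figsize=(5, 4))
    q = de_table["fdr"].clip(lower=1e-300)
    sig = de_table["fdr"] < fdr
    ax.scatter(de_table["log2_fold_change"][~sig], -np.log10(q[~sig]),
               s=4, c="lightgray")
    ax.scatter(de_table["log2_fold_change"][sig], -np.log10(q[sig]),
               s=6, c="crimson")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 FDR")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def homology_heatmap(proportions: pd.DataFrame, path=None):
    """Cluster x reference-label mapping proportions."""
    fig, ax = plt.subplots(figsize=(max(4, 0.25 * proportions.shape[1]),
                                    max(3, 0.2 * proportions.shape[0])))
    im = ax.imshow(proportions.to_numpy(), aspect="auto", cmap="magma",
                   vmin=0, vmax=1)
    ax.set_xticks(range(proportions.shape[1]),
                  labels=proportions.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(proportions.shape[0]),
                  labels=proportions.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="proportion of cluster")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
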