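"""Simple figure exports: replicate-correlation heatmap, co-expression
region bars, DEG scatter and qPCR concordance scatter.

Matplotlib is imported lazily with the Agg backend so the plotting module
never needs a display.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def correlation_heatmap(corr: pd.DataFrame, path) -> None:
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(corr)), corr.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r of log10(FPKM+1)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def venn_region_bars(venn, path) -> None:
    """Bar chart of the exclusive membership-region counts."""
    plt = _pyplot()
    frame = venn.to_frame().sort_values(["n_groups", "region"])
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(frame["region"], frame["count"], color="#4878d0")
    ax.set_ylabel("genes")
    plt.setp(ax.get_xticklabels(), rotation=90, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def deg_scatter(contrast_result, degs, path) -> None:
    """log10 expression of group A vs group B, DEGs coloured by direction."""
    plt = _pyplot()
    t = contrast_result.table
    x = np.log10(t["mean_fpkm_b"] + 1)
    y = np.log10(t["mean_fpkm_a"] + 1)
    color = pd.Series("0.6", index=t.index)
    color.loc[list(degs.up)] = "#e6b800"
    color.loc[list(degs.down)] = "#2d5fa8"
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=4, c=color, linewidths=0)
    ax.set_xlabel(f"log10 FPKM+1, {contrast_result.group_b}")
    ax.set_ylabel(f"log10 FPKM+1, {contrast_result.group_a}")
    ax.set_title(contrast_result.contrast_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def concordance_scatter(pairs: pd.DataFrame, path) -> None:
    """qPCR vs RNA-seq log2 fold-changes with the least-squares line."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pairs["rnaseq"], pairs["qpcr"], s=14, color="#4878d0")
    if len(pairs) >= 2:
        coeffs = np.polyfit(pairs["rnaseq"], pairs["qpcr"], 1)
        xs = np.linspace(pairs["rnaseq"].min(), pairs["rnaseq"].max(), 10)
        ax.plot(xs, np.polyval(coeffs, xs), color="0.3", lw=1)
    ax.set_xlabel("RNA-seq log2 fold-change")
    ax.set_ylabel("qPCR log2 fold-change")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
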