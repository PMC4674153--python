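"""Figure helpers: PCA scatter, per-gene violin plots, clustered heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
import seaborn as sns

from .expression import ExpressionMatrix
from .qpcr_io import SUBSETS
from .subgroups import PcaModel, cluster_heatmap_order

_SUBSET_COLORS = {"classical": "tab:red", "intermediate": "tab:green",
                  "non_classical": "tab:blue"}


def pca_scatter(
    pca: PcaModel, meta: pd.DataFrame, path: str | Path,
    highlight: list[str] | None = None,
) -> Path:
    """PC1/PC2 scores coloured by subset; optional highlighted subgroup."""
    labels = meta.set_index("cell_id")["subset"].reindex(pca.scores.index)
    fig, ax = plt.subplots(figsize=(5, 4))
    for s in SUBSETS:
        pts = pca.scores.loc[labels == s]
        ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], s=12, alpha=0.7,
                   color=_SUBSET_COLORS[s], label=s)
    if highlight:
        pts = pca.scores.loc[[c for c in highlight if c in pca.scores.index]]
        ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], s=40, facecolors="none",
                   edgecolors="black", label="subgroup")
    vf = pca.variance_fraction
    ax.set_xlabel(f"PC1 ({vf[0]:.0%})")
    ax.set_ylabel(f"PC2 ({vf[1]:.0%})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def violin_by_subset(
    expr: ExpressionMatrix, meta: pd.DataFrame, genes: list[str], path: str | Path
) -> Path:
    """Violin plots of Log2Ex per subset for the selected genes."""
    labels = meta.set_index("cell_id")["subset"].reindex(expr.log2ex.index)
    long = (
        expr.log2ex[genes]
        .assign(subset=labels.values)
        .melt(id_vars="subset", var_name="gene", value_name="log2ex")
    )
    g = sns.catplot(
        data=long, x="subset", y="log2ex", col="gene", kind="violin",
        col_wrap=min(4, len(genes)), height=2.5, aspect=0.9,
        palette=_SUBSET_COLORS, hue="subset", legend=False, cut=0,
        density_norm="width", inner="quartile",
    )
    g.set_xticklabels(rotation=45)
    g.savefig(path, dpi=150)
    plt.close(g.figure)
    return Path(path)


def clustered_heatmap(expr: ExpressionMatrix, path: str | Path) -> Path:
    """Cells x genes heatmap in hierarchical-clustering leaf order."""
    order = cluster_heatmap_order(expr)
    mat = expr.log2ex.loc[order["cell_order"], order["gene_order"]]
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xlabel("genes (clustered)")
    ax.set_ylabel("cells (clustered)")
    fig.colorbar(im, ax=ax, label="Log2Ex")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
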