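"""Subset-level contrasts and expression-presence summaries.

Pairwise two-sample t-tests between the three monocyte subsets per gene,
three-level expression-rank labels, functional-category grouping, and the
presence filters (never-expressed genes, genes unexpressed exclusively in
one subset, count of expressed genes).

"Not expressed" at the subset level means a mean Log2Ex of exactly 0,
i.e. every cell of the subset was below the detection limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .qpcr_io import SUBSETS

#: subset pairs in reporting order
PAIRS = (("classical", "intermediate"),
         ("classical", "non_classical"),
         ("intermediate", "non_classical"))

_PAIR_NAMES = {("classical", "intermediate"): "C_vs_I",
               ("classical", "non_classical"): "C_vs_NC",
               ("intermediate", "non_classical"): "I_vs_NC"}


@dataclass
class ContrastResult:
    gene_id: str
    pair: str
    mean_a: float
    mean_b: float
    t: float
    p: float
    log2fc: float          # mean_a - mean_b, log2 units
    degenerate: bool = False


def _ttest(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float, bool]:
    """Two-sided two-sample t-test with explicit zero-variance handling.

    Both groups constant: equal means give (t=0, p=1); different means are a
    separation no t-test can quantify, reported as the smallest positive
    float and flagged degenerate.
    """
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0, True
        return np.inf if a[0] > b[0] else -np.inf, float(np.finfo(float).tiny), True
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), False


def pairwise_subset_tests(
    expr: ExpressionMatrix, meta: pd.DataFrame, equal_var: bool = True
) -> list[ContrastResult]:
    """Per gene, t-tests for the three subset pairs on zero-inclusive Log2Ex.

    Student (equal-variance) by default; set ``equal_var=False`` for Welch.
    """
    labels = meta.set_index("cell_id")["subset"].reindex(expr.cell_ids)
    groups = {}
    for s in SUBSETS:
        cells = labels.index[labels == s]
        if len(cells) < 2:
            raise ValueError(f"subset {s!r} needs >= 2 cells")
        groups[s] = expr.log2ex.loc[cells]
    out: list[ContrastResult] = []
    for gene in expr.gene_ids:
        for a, b in PAIRS:
            va = groups[a][gene].to_numpy()
            vb = groups[b][gene].to_numpy()
            t, p, degen = _ttest(va, vb, equal_var)
            out.append(ContrastResult(
                gene_id=gene, pair=_PAIR_NAMES[(a, b)],
                mean_a=float(va.mean()), mean_b=float(vb.mean()),
                t=t, p=p, log2fc=float(va.mean() - vb.mean()), degenerate=degen,
            ))
    return out


def contrasts_table(results: Iterable[ContrastResult]) -> pd.DataFrame:
    """Wide per-gene table with one p-value column per subset pair."""
    df = pd.DataFrame([(r.gene_id, r.pair, r.p) for r in results],
                      columns=["gene", "pair", "p"])
    wide = df.pivot(index="gene", columns="pair", values="p")
    return wide.reindex(columns=["C_vs_I", "C_vs_NC", "I_vs_NC"])


def rank_labels(means: pd.DataFrame) -> pd.DataFrame:
    """Three-level {highest, medium, lowest} labels per gene.

    A subset's mean equal to the gene's maximum is 'highest'; equal to the
    minimum (without being the maximum) is 'lowest'; the remaining level is
    'medium'.  Tied subsets share the higher label and the gene is flagged.
    """
    means = means[list(SUBSETS)]
    labels = pd.DataFrame(index=means.index, columns=list(SUBSETS), dtype=object)
    tied = pd.Series(False, index=means.index)
    for gene, row in means.iterrows():
        hi, lo = row.max(), row.min()
        for s in SUBSETS:
            if row[s] == hi:
                labels.loc[gene, s] = "highest"
            elif row[s] == lo:
                labels.loc[gene, s] = "lowest"
            else:
                labels.loc[gene, s] = "medium"
        tied[gene] = row.duplicated().any()
    labels["tied"] = tied
    return labels


def never_expressed(means: pd.DataFrame) -> set[str]:
    """Genes whose mean Log2Ex is 0 in all three subsets."""
    m = means[list(SUBSETS)]
    return set(m.index[(m == 0).all(axis=1)])


def exclusively_unexpressed_in(means: pd.DataFrame, subset: str) -> set[str]:
    """Genes unexpressed in ``subset`` but expressed in both other subsets."""
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}")
    m = means[list(SUBSETS)]
    others = [s for s in SUBSETS if s != subset]
    mask = (m[subset] == 0) & (m[others] > 0).all(axis=1)
    return set(m.index[mask])


def expressed_gene_count(means: pd.DataFrame) -> int:
    """Number of genes with a positive mean in at least one subset."""
    m = means[list(SUBSETS)]
    return int((m > 0).any(axis=1).sum())


def categorize(
    means: pd.DataFrame, category_map: Mapping[str, Iterable[str]]
) -> tuple[pd.DataFrame, list[str]]:
    """Category-grouped view of subset means with rank labels.

    Returns a long table (category, gene, subset means, rank labels) plus
    the list of genes absent from every category.  Genes may belong to
    several categories; genes in the map but not in ``means`` are ignored.
    """
    ranks = rank_labels(means)
    rows = []
    categorized: set[str] = set()
    for cat, genes in category_map.items():
        for g in genes:
            if g not in means.index:
                continue
            categorized.add(g)
            rows.append({
                "category": cat, "gene": g,
                **{s: means.loc[g, s] for s in SUBSETS},
                **{f"rank_{s}": ranks.loc[g, s] for s in SUBSETS},
            })
    table = pd.DataFrame(rows)
    uncategorized = sorted(set(means.index) - categorized)
    return table, uncategorized
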