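#!/usr/bin/env python
"""Subset expression profile: means, pairwise t-tests, presence filters.

Computes the per-gene subset mean table, Student t-tests for the three
subset pairs, the three-level expression-rank labels with functional
categories, and the presence summaries (never-expressed genes, genes
unexpressed exclusively in one subset, expressed-gene count).

Writes results/expression/*.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from scqpcr.contrasts import (
    categorize,
    contrasts_table,
    exclusively_unexpressed_in,
    expressed_gene_count,
    never_expressed,
    pairwise_subset_tests,
    rank_labels,
)
from scqpcr.expression import ExpressionMatrix, subset_mean_table
from scqpcr.fixtures import load_categories
from scqpcr.qpcr_io import SUBSETS, read_cell_meta

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    pre = ROOT / "preprocess"
    if not (pre / "log2ex.tsv").exists():
        sys.exit("missing results/preprocess/log2ex.tsv - run 02_preprocess.py first")
    expr = ExpressionMatrix(pd.read_csv(pre / "log2ex.tsv", sep="\t", index_col=0))
    meta = read_cell_meta(pre / "meta.tsv")

    means = subset_mean_table(expr, meta)
    tests = contrasts_table(pairwise_subset_tests(expr, meta))
    ranks = rank_labels(means)
    cats, uncategorized = categorize(means, load_categories())

    out = ROOT / "expression"
    out.mkdir(parents=True, exist_ok=True)
    means.join(tests).to_csv(out / "subset_profile.tsv", sep="\t")
    ranks.to_csv(out / "rank_labels.tsv", sep="\t")
    cats.to_csv(out / "categories.tsv", sep="\t", index=False)

    ne = sorted(never_expressed(means))
    print(f"expressed genes: {expressed_gene_count(means)} of {len(means)}")
    print(f"never expressed: {len(ne)} ({', '.join(ne) if ne else '-'})")
    for s in SUBSETS:
        ex = sorted(exclusively_unexpressed_in(means, s))
        print(f"unexpressed exclusively in {s}: {len(ex)} ({', '.join(ex) if ex else '-'})")
    print(f"uncategorized genes: {len(uncategorized)}")


if __name__ == "__main__":
    sys.exit(main())
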