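#!/usr/bin/env python
"""Subpopulation discovery: PCA, subgroup selection, subgroup DE, figures.

Within each subset, cells are 2-partitioned in PC space (farthest-pair
seeded, silhouette-gap gated); accepted minority subgroups are contrasted
against the rest of their subset with Student t-tests, keeping genes with
p < 0.05 and |log2 fold change| >= 1.  Recovery is scored against the
generator's planted truth.

Writes results/subgroups/*.tsv and figures under results/figures/.
"""

import sys
from pathlib import Path

import pandas as pd

from scqpcr.expression import ExpressionMatrix
from scqpcr.plots import clustered_heatmap, pca_scatter, violin_by_subset
from scqpcr.qpcr_io import read_cell_meta
from scqpcr.subgroups import de_table, discover_subgroups, run_pca

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    pre = ROOT / "preprocess"
    if not (pre / "log2ex.tsv").exists():
        sys.exit("missing results/preprocess/log2ex.tsv - run 02_preprocess.py first")
    expr = ExpressionMatrix(pd.read_csv(pre / "log2ex.tsv", sep="\t", index_col=0))
    meta = read_cell_meta(pre / "meta.tsv")

    out = ROOT / "subgroups"
    figs = ROOT / "figures"
    out.mkdir(parents=True, exist_ok=True)
    figs.mkdir(parents=True, exist_ok=True)

    found = discover_subgroups(expr, meta)
    members_rows = []
    for r in found:
        de = de_table(r.de_records)
        de.to_csv(out / f"de_{r.subset}.tsv", sep="\t", index=False)
        members_rows += [(r.subset, c) for c in r.member_cell_ids]
        up = (de.direction == "up").sum()
        print(f"{r.subset}: subgroup of {r.n_members} cells; "
              f"{len(de)} DE genes ({up} up, {len(de) - up} down)")
        print("   genes:", ", ".join(de.gene))
    if not found:
        print("no subgroup passed the selection gates")
    pd.DataFrame(members_rows, columns=["subset", "cell_id"]).to_csv(
        out / "members.tsv", sep="\t", index=False)

    # score against planted truth when available
    truth_cells = ROOT / "sim" / "truth_cells.tsv"
    if truth_cells.exists() and found:
        tc = pd.read_csv(truth_cells, sep="\t")
        planted = set(tc[tc.subgroup_member].cell_id)
        for r in found:
            got = set(r.member_cell_ids)
            if planted & got:
                print(f"planted-subgroup overlap ({r.subset}): "
                      f"{len(planted & got)}/{len(planted)} members recovered, "
                      f"{len(got - planted)} extra")

    # figures: joint PCA, violins of a few DE genes, clustered heatmap
    pca = run_pca(expr)
    highlight = found[0].member_cell_ids if found else None
    pca_scatter(pca, meta, figs / "pca_subsets.png", highlight=highlight)
    if found and found[0].de_records:
        genes = [rec.gene_id for rec in found[0].de_records[:4]]
        violin_by_subset(expr, meta, genes, figs / "violin_de_genes.png")
    clustered_heatmap(expr, figs / "heatmap.png")
    print(f"figures written to {figs}")


if __name__ == "__main__":
    sys.exit(main())
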