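#!/usr/bin/env python
"""Empty-well filtering and the Ct -> Log2Ex transform.

Reads results/sim/ (from 01_simulate.py), removes wells whose 18S control
is missing or above 40 cycles, drops the control assay, and converts the
remaining Ct values to nonnegative Log2Ex (LoD Ct = 24, nondetect -> 0).

Writes results/preprocess/log2ex.tsv and removed_cells.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from scqpcr.expression import ct_to_log2ex
from scqpcr.qpcr_io import PanelSpec, read_cell_meta, read_ct_table, filter_empty_wells

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sim = ROOT / "sim"
    if not (sim / "ct.tsv").exists():
        sys.exit("missing results/sim/ct.tsv - run 01_simulate.py first")
    table = read_ct_table(sim / "ct.tsv", "wide")
    meta = read_cell_meta(sim / "meta.tsv")
    targets = [a for a in table.assay_ids if a != "18S"]
    panel = PanelSpec(targets, "ACTB", "18S", 40.0)
    filtered, removed = filter_empty_wells(table, panel)
    expr = ct_to_log2ex(filtered)

    out = ROOT / "preprocess"
    out.mkdir(parents=True, exist_ok=True)
    expr.log2ex.to_csv(out / "log2ex.tsv", sep="\t")
    pd.DataFrame({"removed_cell_id": removed}).to_csv(
        out / "removed_cells.tsv", sep="\t", index=False)
    meta[meta.cell_id.isin(expr.cell_ids)].to_csv(out / "meta.tsv", sep="\t", index=False)
    print(f"removed {len(removed)} empty wells; kept {len(expr.cell_ids)} cells "
          f"x {len(expr.gene_ids)} genes")
    nondetect = float((expr.log2ex.to_numpy() == 0).mean())
    print(f"nondetect fraction after transform: {nondetect:.1%}")


if __name__ == "__main__":
    sys.exit(main())
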