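"""Reading, writing and quality-filtering of single-cell qPCR Ct matrices.

A BioMark-style experiment yields one cycle-threshold (Ct) value per
(cell, assay) pair.  Wells that failed to amplify carry no Ct; export
software encodes this variously as an empty field, ``NA`` or the sentinel
999.  All of these map to a single internal nondetect marker (``NaN``).

Empty wells (no cell captured) are identified by an 18S rRNA control assay:
a well with no 18S signal, or with an 18S Ct above the control cutoff
(default 40 cycles), is considered empty and removed before any analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical monocyte subset labels, in reporting order
SUBSETS = ("classical", "intermediate", "non_classical")

#: on-disk encodings that map to the internal nondetect marker (NaN)
DEFAULT_NONDETECT_SENTINELS = ("", "NA", "NaN", "nan", "999", "999.0")


class CtTableError(ValueError):
    """Raised for malformed Ct tables or metadata."""


@dataclass
class CtTable:
    """Cells x assays matrix of raw Ct values.

    ``ct`` is a float DataFrame indexed by cell id with assay ids as
    columns; ``NaN`` encodes a nondetect.  Every non-missing value must be
    finite and strictly positive (a Ct of 0 or less is physically
    meaningless).
    """

    ct: pd.DataFrame

    def __post_init__(self) -> None:
        self.ct = self.ct.astype(float)
        self.validate()

    def validate(self) -> None:
        if self.ct.index.duplicated().any():
            dupes = self.ct.index[self.ct.index.duplicated()].tolist()
            raise CtTableError(f"duplicate cell ids: {dupes}")
        if self.ct.columns.duplicated().any():
            dupes = self.ct.columns[self.ct.columns.duplicated()].tolist()
            raise CtTableError(f"duplicate assay ids: {dupes}")
        vals = self.ct.to_numpy()
        detected = ~np.isnan(vals)
        if np.any(~np.isfinite(vals[detected])):
            raise CtTableError("non-finite Ct value")
        if np.any(vals[detected] <= 0):
            raise CtTableError("Ct values must be strictly positive")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def assay_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.ct.shape

    def equals(self, other: "CtTable") -> bool:
        return self.ct.equals(other.ct)


@dataclass
class PanelSpec:
    """Assay panel description: targets, housekeeping and well control."""

    target_genes: Sequence[str]
    housekeeping_gene: str = "ACTB"
    well_control_gene: str = "18S"
    control_max_ct: float = 40.0

    def __post_init__(self) -> None:
        if self.housekeeping_gene not in self.target_genes:
            raise CtTableError(
                f"housekeeping gene {self.housekeeping_gene!r} not in target panel"
            )
        if self.well_control_gene in self.target_genes:
            raise CtTableError(
                f"well control {self.well_control_gene!r} must not be a target gene"
            )
        if self.control_max_ct <= 0:
            raise CtTableError("control_max_ct must be positive")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _clean_ct_values(raw: pd.DataFrame, sentinels: Iterable[str]) -> pd.DataFrame:
    """Map sentinel encodings to NaN and coerce everything else to float."""
    sentinels = {str(s).strip() for s in sentinels}

    def clean(v: object) -> float:
        s = "" if v is None else str(v).strip()
        if s in sentinels or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        try:
            x = float(s)
        except ValueError as exc:
            raise CtTableError(f"unparseable Ct value {v!r}") from exc
        # numeric sentinel (e.g. 999) may arrive as a float
        if any(_num_eq(x, t) for t in sentinels):
            return np.nan
        return x

    return raw.map(clean).astype(float)


def _num_eq(x: float, token: str) -> bool:
    try:
        return x == float(token)
    except ValueError:
        return False


def read_ct_table(
    path: str | Path,
    dialect: Literal["wide", "long"] = "wide",
    nondetect_sentinels: Iterable[str] = DEFAULT_NONDETECT_SENTINELS,
) -> CtTable:
    """Read a Ct matrix from CSV/TSV.

    ``wide``: header row of assay ids, first column cell ids.
    ``long``: three columns (cell_id, assay_id, ct), one row per well;
    duplicate (cell, assay) pairs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sep_for(path)
    if dialect == "wide":
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
        raw.index.name = None
        raw.columns.name = None
        return CtTable(_clean_ct_values(raw, nondetect_sentinels))
    if dialect == "long":
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        if raw.shape[1] < 3:
            raise CtTableError("long format needs columns cell_id, assay_id, ct")
        raw = raw.iloc[:, :3]
        raw.columns = ["cell_id", "assay_id", "ct"]
        dup = raw.duplicated(subset=["cell_id", "assay_id"])
        if dup.any():
            pairs = raw.loc[dup, ["cell_id", "assay_id"]].values.tolist()
            raise CtTableError(f"duplicate (cell, assay) pairs: {pairs[:5]}")
        wide = raw.pivot(index="cell_id", columns="assay_id", values="ct")
        # preserve first-appearance order of ids
        wide = wide.reindex(
            index=raw["cell_id"].drop_duplicates(),
            columns=raw["assay_id"].drop_duplicates(),
        )
        wide.index.name = None
        wide.columns.name = None
        return CtTable(_clean_ct_values(wide, nondetect_sentinels))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_ct_table(
    table: CtTable, path: str | Path, dialect: Literal["wide", "long"] = "wide"
) -> Path:
    """Write a Ct matrix; nondetects are written as ``NA``.

    Values round-trip bit-exactly through :func:`read_ct_table` (floats are
    serialised with full repr precision).
    """
    path = Path(path)
    sep = _sep_for(path)

    def fmt(x: float) -> str:
        return "NA" if np.isnan(x) else repr(x)

    with open(path, "w") as fh:
        if dialect == "wide":
            fh.write(sep.join(["cell_id", *map(str, table.assay_ids)]) + "\n")
            for cell, row in table.ct.iterrows():
                fh.write(sep.join([str(cell), *[fmt(v) for v in row]]) + "\n")
        elif dialect == "long":
            fh.write(sep.join(["cell_id", "assay_id", "ct"]) + "\n")
            for cell, row in table.ct.iterrows():
                for assay, v in row.items():
                    fh.write(sep.join([str(cell), str(assay), fmt(v)]) + "\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    return path


def filter_empty_wells(
    table: CtTable, spec: PanelSpec, drop_control: bool = True
) -> tuple[CtTable, list[str]]:
    """Drop cells whose well-control Ct is missing or above the cutoff.

    The rule is exclusive: a control Ct exactly equal to ``control_max_ct``
    is kept.  With ``drop_control`` (the default) the control assay column
    is removed from the returned table, since downstream analysis uses the
    target genes only.  The operation is idempotent: with ``drop_control``
    off, re-applying it removes nothing further.
    """
    ctrl = spec.well_control_gene
    if ctrl not in table.ct.columns:
        raise CtTableError(f"well control assay {ctrl!r} not in table")
    ctrl_ct = table.ct[ctrl]
    empty = ctrl_ct.isna() | (ctrl_ct > spec.control_max_ct)
    removed = list(table.ct.index[empty])
    kept = table.ct.loc[~empty]
    if drop_control:
        kept = kept.drop(columns=[ctrl])
    return CtTable(kept), removed


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    """Read a cell metadata table (columns cell_id, subset, optional batch)."""
    path = Path(path)
    meta = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    return validate_cell_meta(meta)


def validate_cell_meta(meta: pd.DataFrame) -> pd.DataFrame:
    required = {"cell_id", "subset"}
    missing = required - set(meta.columns)
    if missing:
        raise CtTableError(f"metadata missing columns {sorted(missing)}")
    if meta["cell_id"].duplicated().any():
        dupes = meta.loc[meta["cell_id"].duplicated(), "cell_id"].tolist()
        raise CtTableError(f"duplicate metadata rows for cells: {dupes}")
    bad = set(meta["subset"]) - set(SUBSETS)
    if bad:
        raise CtTableError(f"unknown subset labels {sorted(bad)}; expected {SUBSETS}")
    if "batch" not in meta.columns:
        meta = meta.assign(batch="batch0")
    return meta.reset_index(drop=True)


def join_metadata(
    table: CtTable, meta: pd.DataFrame, strict: bool = True
) -> pd.DataFrame:
    """Return metadata aligned to the table's cells (one row per cell).

    In strict mode a cell without metadata is fatal; otherwise unmatched
    cells are dropped from the result and logged.
    """
    meta = validate_cell_meta(meta)
    lookup = meta.set_index("cell_id")
    unmatched = [c for c in table.cell_ids if c not in lookup.index]
    if unmatched:
        if strict:
            raise CtTableError(f"cells without metadata: {unmatched}")
        log.warning("dropping %d cells without metadata: %s", len(unmatched), unmatched)
    cells = [c for c in table.cell_ids if c in lookup.index]
    out = lookup.loc[cells].reset_index()
    return out
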