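"""Ct to Log2Ex conversion, normalization, and per-subset summaries.

Log2Ex is a nonnegative log2-scale expression value anchored at a limit of
detection (LoD): ``Log2Ex = max(0, lod_ct - Ct)``.  A well with no signal
is interpreted as expression at or below the detection limit and assigned
0.  One qPCR cycle corresponds to one log2 unit, so differences of Log2Ex
values are log2 fold changes.

The LoD Ct is a convention, not a measurement; every downstream statistic
in this package (dip test, t-tests, fold changes) is invariant to it up to
an additive shift of the detected values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .qpcr_io import SUBSETS, CtTable

log = logging.getLogger(__name__)


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Cells x genes matrix of nonnegative Log2Ex values (0 = nondetect)."""

    log2ex: pd.DataFrame

    def __post_init__(self) -> None:
        self.log2ex = self.log2ex.astype(float)
        vals = self.log2ex.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ExpressionError("Log2Ex values must be finite")
        if np.any(vals < 0):
            raise ExpressionError("Log2Ex values must be nonnegative")
        if self.log2ex.index.duplicated().any() or self.log2ex.columns.duplicated().any():
            raise ExpressionError("duplicate cell or gene ids")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.log2ex.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.log2ex.columns)


@dataclass
class NormalizationConfig:
    """LoD anchor and normalization mode.

    mode ``none``            : identity (the default; see docs/methods.md).
    mode ``per_cell_delta``  : classic per-cell dCt against the reference
                               gene; the reference becomes 0 in every cell
                               and values are re-clamped at 0.
    mode ``global_scale``    : per-batch additive shift aligning each
                               batch's median reference value with the
                               global median; within-cell differences are
                               preserved exactly.
    """

    lod_ct: float = 24.0
    mode: Literal["none", "per_cell_delta", "global_scale"] = "none"
    reference_gene: str = "ACTB"

    def __post_init__(self) -> None:
        if self.lod_ct <= 0:
            raise ExpressionError("lod_ct must be positive")
        if self.mode not in {"none", "per_cell_delta", "global_scale"}:
            raise ExpressionError(f"unknown normalization mode {self.mode!r}")


def ct_to_log2ex(ct: CtTable, cfg: NormalizationConfig | None = None) -> ExpressionMatrix:
    """``Log2Ex = max(0, lod_ct - Ct)``; nondetects map to 0.

    Antitone in Ct: a larger Ct never yields a larger Log2Ex.
    """
    cfg = cfg or NormalizationConfig()
    vals = cfg.lod_ct - ct.ct
    vals = vals.clip(lower=0.0).fillna(0.0)
    return ExpressionMatrix(vals)


def normalize(
    expr: ExpressionMatrix,
    cfg: NormalizationConfig,
    batch: pd.Series | None = None,
) -> ExpressionMatrix:
    """Apply the configured normalization mode.

    ``per_cell_delta`` drops (and logs) cells in which the reference gene
    was not detected, since their dCt is undefined.  ``global_scale``
    requires a per-cell batch assignment; with a single batch it is the
    identity.
    """
    if cfg.mode == "none":
        return ExpressionMatrix(expr.log2ex.copy())

    if cfg.reference_gene not in expr.log2ex.columns:
        raise ExpressionError(f"reference gene {cfg.reference_gene!r} missing")

    if cfg.mode == "per_cell_delta":
        ref = expr.log2ex[cfg.reference_gene]
        if (ref == 0).all():
            # reference identically 0 means the matrix is already
            # reference-normalized; re-applying is the identity
            return ExpressionMatrix(expr.log2ex.copy())
        ok = ref > 0
        dropped = list(expr.log2ex.index[~ok])
        if dropped:
            log.warning(
                "per_cell_delta: excluding %d cells with nondetect reference: %s",
                len(dropped), dropped,
            )
        shifted = expr.log2ex.loc[ok].sub(ref[ok], axis=0).clip(lower=0.0)
        return ExpressionMatrix(shifted)

    # global_scale
    if batch is None:
        batch = pd.Series("batch0", index=expr.log2ex.index)
    batch = batch.reindex(expr.log2ex.index)
    if batch.isna().any():
        raise ExpressionError("every cell needs a batch label for global_scale")
    ref = expr.log2ex[cfg.reference_gene]
    global_med = float(ref.median())
    out = expr.log2ex.copy()
    for b, cells in expr.log2ex.index.groupby(batch).items():
        shift = global_med - float(ref.loc[cells].median())
        out.loc[cells] = (out.loc[cells] + shift).clip(lower=0.0)
    return ExpressionMatrix(out)


def subset_mean_table(expr: ExpressionMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-gene arithmetic mean Log2Ex within each monocyte subset.

    Zeros (nondetects) are included in the averages, matching the
    zero-inclusive convention of the reference summary table.  Output is
    genes x subsets, subsets in canonical order.
    """
    lookup = meta.set_index("cell_id")["subset"]
    missing = [c for c in expr.cell_ids if c not in lookup.index]
    if missing:
        raise ExpressionError(f"cells without subset label: {missing}")
    labels = lookup.reindex(expr.cell_ids)
    out = {}
    for s in SUBSETS:
        cells = labels.index[labels == s]
        if len(cells) == 0:
            raise ExpressionError(f"subset {s!r} has no cells")
        out[s] = expr.log2ex.loc[cells].mean(axis=0)
    table = pd.DataFrame(out, columns=list(SUBSETS))
    table.index.name = "gene"
    return table
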