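"""Hartigan's dip statistic and per-gene multimodality screening.

The dip of a sample is the smallest sup-norm distance between its
empirical CDF and any unimodal CDF (a CDF that is convex up to some mode
and concave beyond it).  Large dips indicate departure from unimodality,
e.g. bimodal on/off expression of a gene across single cells.

The implementation follows the iterative greatest-convex-minorant /
least-concave-majorant algorithm of Hartigan & Hartigan: working on the
sorted sample, it alternately fits the GCM and LCM of the ECDF on a
shrinking interval, records the largest deviation, and stops when no
interval can improve it.  Ties are handled through the ECDF directly
(jumps of k/n at tied values); nothing is jittered.

Significance is calibrated by Monte Carlo against samples from
Uniform(0, 1) — the classical least-favourable unimodal null — with the
add-one correction ``p = (1 + #{D_b >= D}) / (B + 1)``.  Null tables are
cached per sample size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix
from .qpcr_io import SUBSETS

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# dip statistic
# ---------------------------------------------------------------------------

def dip_statistic(x: Sequence[float] | np.ndarray) -> float:
    """Hartigan's dip statistic of a 1-d sample (n >= 2).

    Bounded by ``1/(2n) <= D <= 1/4``; invariant under positive affine
    transforms of the data.  For n <= 3, and for constant samples, the
    lower bound 1/(2n) is returned directly (any such ECDF is within
    1/(2n) of a unimodal CDF).
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("dip_statistic expects a 1-d sample")
    n = arr.size
    if n < 2:
        raise ValueError("dip_statistic needs at least 2 observations")
    if not np.all(np.isfinite(arr)):
        raise ValueError("dip_statistic: non-finite values in sample")
    xs = np.sort(arr).tolist()
    return _dip_sorted(xs)


def _dip_sorted(x: list[float]) -> float:
    n = len(x)
    if n <= 3 or x[0] == x[-1]:
        return 0.5 / n

    # mn[j]: previous touch point of the greatest convex minorant at j
    mn = [0] * n
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    # mj[k]: next touch point of the least concave majorant at k
    mj = [0] * n
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 0, n - 1
    dip = 1.0  # in ECDF-count units; final statistic is dip / (2n)
    for _ in range(n + 2):  # the interval shrinks; n+2 cycles is a safe cap
        # GCM touch points on [low, high], from high down to low
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(mn[gcm[-1]])
        # LCM touch points, from low up to high
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(mj[lcm[-1]])
        l_gcm, l_lcm = len(gcm), len(lcm)

        ig, ih = l_gcm - 1, l_lcm - 1
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            # largest gap between the two envelopes, swept low -> high
            ix, iv = l_gcm - 2, 1
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    # next envelope point comes from the LCM
                    gcmi1 = gcm[ix + 1]
                    den = x[gcmix] - x[gcmi1]
                    frac = (x[lcmiv] - x[gcmi1]) * (gcmix - gcmi1) / den if den > 0 else 0.0
                    dx = (lcmiv - gcmi1 + 1) - frac
                    iv += 1
                    if dx >= d:
                        d, ig, ih = dx, ix + 1, iv - 1
                else:
                    # next envelope point comes from the GCM
                    lcmiv1 = lcm[iv - 1]
                    den = x[lcmiv] - x[lcmiv1]
                    frac = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / den if den > 0 else 0.0
                    dx = frac - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d, ig, ih = dx, ix + 1, iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm - 1:
                    iv = l_lcm - 1
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d <= dip:
            break

        # largest deviation of the ECDF from the GCM over [gcm[ig], high]
        dip_l = 0.0
        for j in range(ig, l_gcm - 1):
            max_t = 1.0
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        # largest deviation of the ECDF from the LCM over [low, lcm[ih]]
        dip_u = 0.0
        for j in range(ih, l_lcm - 1):
            max_t = 1.0
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = max(dip_l, dip_u)
        if dip < dipnew:
            dip = dipnew
        new_low, new_high = gcm[ig], lcm[ih]
        if new_low == low and new_high == high:
            break
        low, high = new_low, new_high
    return dip / (2.0 * n)


# ---------------------------------------------------------------------------
# Monte-Carlo null calibration
# ---------------------------------------------------------------------------

@dataclass
class DipNullConfig:
    """Monte-Carlo null settings: B replicates, seed, flag threshold."""

    B: int = 10_000
    seed: int = 17
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


_NULL_TABLE_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def null_dip_table(n: int, cfg: DipNullConfig) -> np.ndarray:
    """Sorted dip statistics of B Uniform(0,1) samples of size n (cached)."""
    key = (n, cfg.B, cfg.seed)
    tab = _NULL_TABLE_CACHE.get(key)
    if tab is None:
        rng = np.random.default_rng([cfg.seed, n])
        u = rng.random((cfg.B, n))
        u.sort(axis=1)
        tab = np.sort([_dip_sorted(row.tolist()) for row in u])
        _NULL_TABLE_CACHE[key] = tab
    return tab


def dip_pvalue(D: float, n: int, cfg: DipNullConfig | None = None) -> float:
    """Monte-Carlo p-value ``(1 + #{D_b >= D}) / (B + 1)``.

    Deterministic for a fixed (n, B, seed); non-increasing in D.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if D < 0:
        raise ValueError("D must be nonnegative")
    cfg = cfg or DipNullConfig()
    tab = null_dip_table(n, cfg)
    exceed = tab.size - int(np.searchsorted(tab, D, side="left"))
    return (1 + exceed) / (cfg.B + 1)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

@dataclass
class DipResult:
    """Dip-test outcome for one (gene, subset) stratum."""

    gene_id: str
    subset: str
    n: int
    D: float
    p: float
    multimodal: bool


def screen_modality(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    cfg: DipNullConfig | None = None,
    expressed_only: bool = False,
) -> list[DipResult]:
    """Dip-test every gene within every subset.

    By default the test runs on all cells of the stratum, zeros included:
    detection-limited cells form a point mass at 0 which is part of the
    expression distribution being screened.  ``expressed_only`` restricts
    to cells with Log2Ex > 0 (strata left with < 2 such cells are skipped
    and logged).  A gene is flagged multimodal when ``p < alpha`` strictly.
    """
    cfg = cfg or DipNullConfig()
    labels = meta.set_index("cell_id")["subset"].reindex(expr.cell_ids)
    present = [s for s in SUBSETS if (labels == s).any()]
    results: list[DipResult] = []
    for s in present:
        cells = labels.index[labels == s]
        block = expr.log2ex.loc[cells]
        if len(cells) < 2:
            raise ValueError(f"subset {s!r} has fewer than 2 cells")
        for gene in expr.gene_ids:
            vals = block[gene].to_numpy()
            if expressed_only:
                vals = vals[vals > 0]
                if vals.size < 2:
                    log.info("skipping %s/%s: <2 expressing cells", gene, s)
                    continue
            D = dip_statistic(vals)
            p = dip_pvalue(D, vals.size, cfg)
            results.append(
                DipResult(gene, s, int(vals.size), float(D), float(p), bool(p < cfg.alpha))
            )
    return results


def results_table(results: Iterable[DipResult]) -> pd.DataFrame:
    """Tidy per-(gene, subset) table of dip-test results."""
    return pd.DataFrame(
        [(r.gene_id, r.subset, r.n, r.D, r.p, r.multimodal) for r in results],
        columns=["gene", "subset", "n", "D", "p", "multimodal"],
    )


@dataclass
class DropoutBiasReport:
    """Comparison of expressing-cell mean expression, unimodal vs multimodal genes."""

    n_unimodal: int
    n_multimodal: int
    mean_unimodal: float
    mean_multimodal: float
    t: float
    p: float
    excluded_genes: list[str] = field(default_factory=list)


def dropout_bias_check(
    expr: ExpressionMatrix, results: Iterable[DipResult]
) -> DropoutBiasReport:
    """Test whether multimodal genes are simply the weakly expressed ones.

    If multimodality were a dropout artefact, low-expression genes would be
    over-represented among the flagged ones.  For each screened gene the
    mean Log2Ex over expressing cells only (Log2Ex > 0) is computed; the
    unimodal and multimodal groups of genes are then compared with a
    two-sided two-sample Student t-test.  A large p-value is reassuring.

    A gene counts as multimodal when flagged in at least one screened
    stratum.  Genes with no expressing cells are excluded and logged.
    """
    flagged: dict[str, bool] = {}
    for r in results:
        flagged[r.gene_id] = flagged.get(r.gene_id, False) or r.multimodal
    if not flagged:
        raise ValueError("no dip results supplied")

    means: dict[str, float] = {}
    excluded: list[str] = []
    for gene in flagged:
        vals = expr.log2ex[gene].to_numpy()
        vals = vals[vals > 0]
        if vals.size == 0:
            excluded.append(gene)
            continue
        means[gene] = float(vals.mean())
    if excluded:
        log.info("dropout_bias_check: excluding genes with no expressing cells: %s", excluded)

    uni = np.array([means[g] for g in means if not flagged[g]])
    multi = np.array([means[g] for g in means if flagged[g]])
    if uni.size == 0 or multi.size == 0:
        raise ValueError("need at least one unimodal and one multimodal gene")
    t, p = stats.ttest_ind(uni, multi, equal_var=True)
    return DropoutBiasReport(
        n_unimodal=int(uni.size),
        n_multimodal=int(multi.size),
        mean_unimodal=float(uni.mean()),
        mean_multimodal=float(multi.mean()),
        t=float(t),
        p=float(p),
        excluded_genes=excluded,
    )
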