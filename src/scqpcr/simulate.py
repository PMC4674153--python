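"""Seeded generator of synthetic single-cell qPCR experiments.

Emulates the statistical structure of a three-subset monocyte panel
measured on a microfluidic qPCR chip: per-subset mean expression,
optionally bimodal genes (two-component Gaussian mixtures on the Log2Ex
scale), expression-dependent dropout, empty wells flagged by an 18S
control, and an optional planted minority subgroup with a coherent
expression shift.  Ground truth is recorded at the Log2Ex scale so that
recovery metrics do not depend on the limit-of-detection convention.

Generative model per cell i and gene g (all on the Log2Ex scale):

    x_ig ~ Normal(mu_gs, sigma_g^2)            unimodal gene, subset s
    x_ig ~ pi * N(mu2) + (1-pi) * N(mu1)       bimodal gene
    x_ig += delta_g                            subgroup members, affected genes
    x_ig <- max(x_ig, 0)
    dropout with prob 1 / (1 + exp(slope * (x_ig - midpoint)))
    detected:  Ct_ig = lod_ct - x_ig + Normal(0, ct_noise_sd^2)
    nondetect: no Ct

The dropout curve is logistic and decreasing in true expression — weakly
expressed transcripts are the ones that fail to amplify, which reproduces
the observed concentration of non-expression among low-mean genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fixtures import load_table2
from .modality import DipResult
from .qpcr_io import SUBSETS, CtTable
from .subgroups import DeRecord, SubgroupResult


@dataclass
class GeneSpec:
    """Per-gene generative parameters (Log2Ex scale)."""

    gene_id: str
    mu: dict[str, float]                  # subset -> mean
    sigma: float = 1.0
    modality: str = "unimodal"            # "unimodal" | "bimodal"
    mu1: float | None = None              # bimodal low component
    mu2: float | None = None              # bimodal high component
    weight: float | None = None           # P(high component)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"{self.gene_id}: sigma must be positive")
        if self.modality not in {"unimodal", "bimodal"}:
            raise ValueError(f"{self.gene_id}: unknown modality {self.modality!r}")
        if self.modality == "bimodal":
            if self.mu1 is None or self.mu2 is None or self.weight is None:
                raise ValueError(f"{self.gene_id}: bimodal gene needs mu1, mu2, weight")
            if not self.mu1 < self.mu2:
                raise ValueError(f"{self.gene_id}: need mu1 < mu2")
            if not 0 < self.weight < 1:
                raise ValueError(f"{self.gene_id}: weight must be in (0, 1)")


@dataclass
class SubgroupSpec:
    """A planted minority subgroup within one subset."""

    subset: str
    fraction: float
    genes: Sequence[str]
    shift: float                          # log2 units added for members

    def __post_init__(self) -> None:
        if self.subset not in SUBSETS:
            raise ValueError(f"unknown subset {self.subset!r}")
        if not 0 < self.fraction < 0.5:
            raise ValueError("subgroup fraction must be in (0, 0.5)")


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults mirror the profiled experiment: 94/92/90 cells per subset and
    an 85-gene panel (pass ``genes=panel_from_table2()``).
    """

    genes: Sequence[GeneSpec]
    n_cells: dict[str, int] = field(
        default_factory=lambda: {"classical": 94, "intermediate": 92, "non_classical": 90}
    )
    lod_ct: float = 24.0
    ct_noise_sd: float = 0.5
    empty_well_rate: float = 0.02
    dropout_midpoint: float = 3.0
    dropout_slope: float = 1.5
    subgroup: SubgroupSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("need at least one gene")
        if not 0 <= self.empty_well_rate <= 1:
            raise ValueError("empty_well_rate must be a probability")
        if any(n <= 0 for n in self.n_cells.values()):
            raise ValueError("cell counts must be positive")
        if self.subgroup is not None:
            known = {g.gene_id for g in self.genes}
            missing = set(self.subgroup.genes) - known
            if missing:
                raise ValueError(f"subgroup genes not in panel: {sorted(missing)}")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the Ct table."""

    log2ex: pd.DataFrame          # cells x genes, true values (clamped at 0)
    dropout: pd.DataFrame         # cells x genes, bool: emitted as nondetect
    cells: pd.DataFrame           # cell_id, subset, subgroup_member, empty_well
    gene_specs: list[GeneSpec]
    subgroup_genes: list[str] = field(default_factory=list)


def panel_from_table2(
    sigma: float = 1.0,
    bimodal: dict[str, tuple[float, float, float]] | None = None,
) -> list[GeneSpec]:
    """85-gene panel seeded from the packaged per-subset mean table.

    ``bimodal`` optionally maps gene ids to (mu1, mu2, weight); those genes
    are generated from the mixture in every subset instead of their means.
    """
    t2 = load_table2()
    bimodal = bimodal or {}
    specs = []
    for gene, row in t2.iterrows():
        if gene in bimodal:
            mu1, mu2, w = bimodal[gene]
            specs.append(GeneSpec(gene, {s: row[s] for s in SUBSETS}, sigma,
                                  "bimodal", mu1, mu2, w))
        else:
            specs.append(GeneSpec(gene, {s: float(row[s]) for s in SUBSETS}, sigma))
    return specs


def recovery_scenario(seed: int, subset: str = "classical",
                      fraction: float = 0.15, n_genes: int = 20,
                      shift: float = -2.0) -> SimConfig:
    """Canonical planted-subgroup experiment for recovery benchmarking.

    The shift lands on genes whose mean in the target subset is at least 6
    Log2Ex: perturbing a gene at or below the detection limit is
    unobservable by construction, so the plant goes on expressed genes.
    """
    genes = panel_from_table2()
    affected = [g.gene_id for g in genes if g.mu[subset] >= 6][:n_genes]
    return SimConfig(
        genes=genes, seed=seed,
        subgroup=SubgroupSpec(subset, fraction, affected, shift),
    )


def dropout_probability(x: np.ndarray, midpoint: float, slope: float) -> np.ndarray:
    """Logistic dropout curve, decreasing in true Log2Ex.

    ``midpoint = -inf`` disables dropout entirely.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(midpoint):
        return np.zeros_like(x) if midpoint < 0 else np.ones_like(x)
    z = np.clip(slope * (x - midpoint), -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(z))


def simulate_experiment(cfg: SimConfig) -> tuple[CtTable, pd.DataFrame, SimTruth]:
    """Draw one experiment: (CtTable incl. 18S control, metadata, truth).

    Fully reproducible for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [g.gene_id for g in cfg.genes]

    cell_ids: list[str] = []
    subsets: list[str] = []
    for s in SUBSETS:
        for i in range(cfg.n_cells.get(s, 0)):
            cell_ids.append(f"{s}_{i:03d}")
            subsets.append(s)
    n_cells = len(cell_ids)
    subset_arr = np.array(subsets)

    # planted subgroup membership
    member = np.zeros(n_cells, dtype=bool)
    if cfg.subgroup is not None:
        idx = np.flatnonzero(subset_arr == cfg.subgroup.subset)
        k = max(1, int(round(cfg.subgroup.fraction * idx.size)))
        member[rng.choice(idx, size=k, replace=False)] = True

    # true expression
    X = np.zeros((n_cells, len(gene_ids)))
    for gi, spec in enumerate(cfg.genes):
        if spec.modality == "bimodal":
            comp = rng.random(n_cells) < spec.weight
            mu = np.where(comp, spec.mu2, spec.mu1)
        else:
            mu = np.array([spec.mu[s] for s in subsets])
        X[:, gi] = rng.normal(mu, spec.sigma)
    if cfg.subgroup is not None:
        gidx = [gene_ids.index(g) for g in cfg.subgroup.genes]
        X[np.ix_(member, gidx)] += cfg.subgroup.shift
    X = np.clip(X, 0.0, None)

    # expression-dependent dropout
    p_drop = dropout_probability(X, cfg.dropout_midpoint, cfg.dropout_slope)
    drop = rng.random(X.shape) < p_drop

    # emitted Ct for detected wells
    ct = cfg.lod_ct - X + rng.normal(0.0, cfg.ct_noise_sd, size=X.shape)
    ct = np.clip(ct, 0.01, None)  # Ct must stay positive
    ct[drop] = np.nan

    # 18S well control; empty wells get a control Ct above the cutoff
    empty = rng.random(n_cells) < cfg.empty_well_rate
    ctrl = rng.normal(12.0, 0.3, size=n_cells)
    ctrl[empty] = rng.uniform(40.5, 45.0, size=int(empty.sum()))

    ct_df = pd.DataFrame(ct, index=cell_ids, columns=gene_ids)
    ct_df["18S"] = ctrl
    table = CtTable(ct_df)

    meta = pd.DataFrame({"cell_id": cell_ids, "subset": subsets, "batch": "chip0"})
    truth = SimTruth(
        log2ex=pd.DataFrame(X, index=cell_ids, columns=gene_ids),
        dropout=pd.DataFrame(drop, index=cell_ids, columns=gene_ids),
        cells=pd.DataFrame({
            "cell_id": cell_ids,
            "subset": subsets,
            "subgroup_member": member,
            "empty_well": empty,
        }),
        gene_specs=list(cfg.genes),
        subgroup_genes=list(cfg.subgroup.genes) if cfg.subgroup else [],
    )
    return table, meta, truth


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------

def _adjusted_rand(a: np.ndarray, b: np.ndarray) -> float:
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(a, b))


def evaluate_recovery(
    truth: SimTruth,
    dip_results: Iterable[DipResult] | None = None,
    subgroup: SubgroupResult | None = None,
    de_records: Iterable[DeRecord] | None = None,
) -> dict:
    """Score predictions against the generator's ground truth.

    Returns modality sensitivity/specificity (per screened (gene, subset)
    stratum against the gene's true class), an adjusted Rand index for
    subgroup membership within the planted subset, and precision/recall of
    the DE gene list against the planted shifted genes.
    """
    out: dict = {}
    modality_truth = {g.gene_id: g.modality for g in truth.gene_specs}

    if dip_results is not None:
        tp = fp = tn = fn = 0
        for r in dip_results:
            is_bi = modality_truth.get(r.gene_id) == "bimodal"
            if is_bi and r.multimodal:
                tp += 1
            elif is_bi:
                fn += 1
            elif r.multimodal:
                fp += 1
            else:
                tn += 1
        out["modality_sensitivity"] = tp / (tp + fn) if tp + fn else np.nan
        out["modality_specificity"] = tn / (tn + fp) if tn + fp else np.nan
        out["modality_confusion"] = {"tp": tp, "fp": fp, "tn": tn, "fn": fn}

    planted = truth.cells["subgroup_member"].to_numpy()
    if subgroup is not None and planted.any():
        subset = truth.cells.loc[planted, "subset"].iloc[0]
        in_subset = truth.cells["subset"] == subset
        cells = truth.cells.loc[in_subset, "cell_id"]
        true_lab = planted[in_subset.to_numpy()].astype(int)
        pred_lab = cells.isin(subgroup.member_cell_ids).to_numpy().astype(int)
        out["subgroup_ari"] = _adjusted_rand(true_lab, pred_lab)

    if de_records is not None and planted.any():
        shifted = set(truth.subgroup_genes)
        predicted = {r.gene_id for r in de_records}
        tp = len(shifted & predicted)
        out["de_precision"] = tp / len(predicted) if predicted else (1.0 if not shifted else 0.0)
        out["de_recall"] = tp / len(shifted) if shifted else np.nan
    return out
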