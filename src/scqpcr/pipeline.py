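"""End-to-end orchestration of the analysis stages.

``run_pipeline`` drives: read Ct + metadata -> empty-well filter ->
Log2Ex transform (+ optional normalization) -> subset means and pairwise
contrasts -> presence filters -> dip-test modality screen -> subgroup
discovery.  Every stage writes a TSV into the run directory, and a
manifest records SHA-256 hashes of the configuration and of each output,
so identical configurations produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import contrasts as ct_mod
from . import fixtures
from .expression import NormalizationConfig, ct_to_log2ex, normalize, subset_mean_table
from .modality import DipNullConfig, dropout_bias_check, results_table, screen_modality
from .qpcr_io import (
    PanelSpec,
    filter_empty_wells,
    join_metadata,
    read_cell_meta,
    read_ct_table,
)
from .subgroups import SubgroupConfig, discover_subgroups

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    ct_path: str
    meta_path: str
    out_dir: str
    dialect: str = "wide"
    well_control_gene: str = "18S"
    control_max_ct: float = 40.0
    housekeeping_gene: str = "ACTB"
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    dip: DipNullConfig = field(default_factory=DipNullConfig)
    subgroups: SubgroupConfig = field(default_factory=SubgroupConfig)
    run_modality: bool = True
    run_subgroups: bool = True


def _config_hash(cfg: PipelineConfig) -> str:
    d = dataclasses.asdict(cfg)
    d.pop("out_dir")  # the destination is not part of the analysis identity
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
    manifest["outputs"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written as JSON)."""
    ct_path, meta_path = Path(cfg.ct_path), Path(cfg.meta_path)
    for p in (ct_path, meta_path):
        if not p.exists():
            raise FileNotFoundError(f"pipeline input missing: {p}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_sha256": _config_hash(cfg), "outputs": {}}

    table = read_ct_table(ct_path, dialect=cfg.dialect)  # type: ignore[arg-type]
    meta = read_cell_meta(meta_path)

    target_genes = [a for a in table.assay_ids if a != cfg.well_control_gene]
    panel = PanelSpec(
        target_genes=target_genes,
        housekeeping_gene=cfg.housekeeping_gene,
        well_control_gene=cfg.well_control_gene,
        control_max_ct=cfg.control_max_ct,
    )
    table, removed = filter_empty_wells(table, panel)
    pd.DataFrame({"removed_cell_id": removed}).to_csv(
        out / "removed_cells.tsv", sep="\t", index=False
    )
    manifest["outputs"]["removed_cells.tsv"] = hashlib.sha256(
        (out / "removed_cells.tsv").read_bytes()
    ).hexdigest()
    meta = join_metadata(table, meta)

    expr = ct_to_log2ex(table, cfg.normalization)
    expr = normalize(expr, cfg.normalization, meta.set_index("cell_id").get("batch"))
    _write(expr.log2ex, out / "log2ex.tsv", manifest)

    means = subset_mean_table(expr, meta)
    _write(means, out / "subset_means.tsv", manifest)

    contrast_results = ct_mod.pairwise_subset_tests(expr, meta)
    _write(ct_mod.contrasts_table(contrast_results), out / "contrasts.tsv", manifest)

    presence = pd.DataFrame({
        "metric": ["never_expressed", "exclusively_unexpressed_non_classical",
                   "expressed_genes"],
        "value": [
            ";".join(sorted(ct_mod.never_expressed(means))),
            ";".join(sorted(ct_mod.exclusively_unexpressed_in(means, "non_classical"))),
            str(ct_mod.expressed_gene_count(means)),
        ],
    })
    _write(presence, out / "presence.tsv", manifest, index=False)

    if cfg.run_modality:
        dips = screen_modality(expr, meta, cfg.dip)
        _write(results_table(dips), out / "modality.tsv", manifest, index=False)
        try:
            bias = dropout_bias_check(expr, dips)
            _write(
                pd.DataFrame([dataclasses.asdict(bias)]),
                out / "dropout_bias.tsv", manifest, index=False,
            )
        except ValueError as exc:
            log.warning("dropout bias check skipped: %s", exc)

    if cfg.run_subgroups:
        found = discover_subgroups(expr, meta, cfg.subgroups)
        rows = []
        for r in found:
            for rec in r.de_records:
                rows.append((r.subset, r.n_members, rec.gene_id, rec.log2fc,
                             rec.p, rec.direction))
        _write(
            pd.DataFrame(rows, columns=["subset", "n_members", "gene",
                                        "log2fc", "p", "direction"]),
            out / "subgroup_de.tsv", manifest, index=False,
        )
        members = pd.DataFrame(
            [(r.subset, c) for r in found for c in r.member_cell_ids],
            columns=["subset", "cell_id"],
        )
        _write(members, out / "subgroup_members.tsv", manifest, index=False)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def check_fixtures_report() -> fixtures.FixtureReport:
    """Thin pass-through so the CLI and tests share one entry point."""
    return fixtures.check_fixtures()
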