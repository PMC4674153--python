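import numpy as np
import pandas as pd
import pytest

from scqpcr.expression import ct_to_log2ex, subset_mean_table
from scqpcr.modality import DipResult
from scqpcr.qpcr_io import PanelSpec, filter_empty_wells
from scqpcr.simulate import (
    GeneSpec,
    SimConfig,
    SubgroupSpec,
    dropout_probability,
    evaluate_recovery,
    panel_from_table2,
    simulate_experiment,
)
from scqpcr.subgroups import DeRecord, SubgroupResult


def _simple_genes(n=4, mu=8.0, sigma=0.5):
    return [GeneSpec(f"g{i}", {s: mu for s in ("classical", "intermediate", "non_classical")},
                     sigma) for i in range(n)]


class TestSimulateExperiment:
    def test_same_seed_is_byte_identical(self):
        cfg = SimConfig(genes=_simple_genes(), seed=42,
                        n_cells={"classical": 10, "intermediate": 10, "non_classical": 10})
        t1, m1, tr1 = simulate_experiment(cfg)
        t2, m2, tr2 = simulate_experiment(cfg)
        pd.testing.assert_frame_equal(t1.ct, t2.ct)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(tr1.log2ex, tr2.log2ex)

    def test_default_cell_counts_match_study(self):
        cfg = SimConfig(genes=_simple_genes())
        _, meta, _ = simulate_experiment(cfg)
        counts = meta["subset"].value_counts()
        assert counts["classical"] == 94
        assert counts["intermediate"] == 92
        assert counts["non_classical"] == 90

    def test_no_dropout_no_empty_wells_all_detected(self):
        cfg = SimConfig(genes=_simple_genes(mu=10.0), seed=1, empty_well_rate=0.0,
                        dropout_midpoint=-1e9,
                        n_cells={"classical": 20, "intermediate": 20, "non_classical": 20})
        table, _, truth = simulate_experiment(cfg)
        targets = table.ct.drop(columns=["18S"])
        assert not targets.isna().any().any()
        assert not truth.dropout.any().any()
        assert not truth.cells["empty_well"].any()

    def test_bimodal_component_fraction(self):
        spec = GeneSpec("bi", {s: 0.0 for s in ("classical", "intermediate", "non_classical")},
                        0.3, "bimodal", mu1=2.0, mu2=10.0, weight=0.5)
        cfg = SimConfig(genes=[spec], seed=2, empty_well_rate=0.0,
                        dropout_midpoint=-1e9,
                        n_cells={"classical": 400, "intermediate": 300, "non_classical": 300})
        _, _, truth = simulate_experiment(cfg)
        frac_high = (truth.log2ex["bi"] > 6).mean()
        sd = np.sqrt(0.25 / 1000)
        assert abs(frac_high - 0.5) <= 3 * sd

    def test_monotone_dropout_in_expression(self):
        genes = [GeneSpec(f"g{i}", {s: m for s in ("classical", "intermediate", "non_classical")},
                          1.0) for i, m in enumerate([1.0, 3.0, 5.0, 7.0, 9.0])]
        cfg = SimConfig(genes=genes, seed=3, empty_well_rate=0.0,
                        n_cells={"classical": 700, "intermediate": 700, "non_classical": 600})
        _, _, truth = simulate_experiment(cfg)
        x = truth.log2ex.to_numpy().ravel()
        d = truth.dropout.to_numpy().ravel()
        bins = np.digitize(x, [2, 4, 6, 8])
        rates = [d[bins == b].mean() for b in range(5) if np.any(bins == b)]
        assert all(r1 >= r2 - 1e-9 for r1, r2 in zip(rates, rates[1:]))

    def test_empty_wells_have_high_control_ct(self):
        cfg = SimConfig(genes=_simple_genes(), seed=4, empty_well_rate=0.5,
                        n_cells={"classical": 40, "intermediate": 40, "non_classical": 40})
        table, _, truth = simulate_experiment(cfg)
        empty = truth.cells.set_index("cell_id")["empty_well"]
        assert (table.ct.loc[empty[empty].index, "18S"] > 40).all()
        assert (table.ct.loc[empty[~empty].index, "18S"] <= 40).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(genes=[])
        with pytest.raises(ValueError):
            GeneSpec("g", {"classical": 1.0}, sigma=0.0)
        with pytest.raises(ValueError):
            GeneSpec("g", {"classical": 1.0}, modality="bimodal")  # missing mixture
        with pytest.raises(ValueError):
            SubgroupSpec("classical", 0.7, ["g"], 2.0)
        with pytest.raises(ValueError):
            SimConfig(genes=_simple_genes(),
                      subgroup=SubgroupSpec("classical", 0.2, ["absent"], 2.0))


class TestPipelineClosure:
    def test_log2ex_recovered_within_noise(self):
        """simulate -> filter -> ct_to_log2ex recovers truth on detected entries."""
        cfg = SimConfig(genes=panel_from_table2(), seed=5)
        table, meta, truth = simulate_experiment(cfg)
        panel = PanelSpec([g.gene_id for g in cfg.genes], "ACTB", "18S", 40.0)
        filtered, removed = filter_empty_wells(table, panel)
        expr = ct_to_log2ex(filtered)
        cells = expr.cell_ids
        detected = ~truth.dropout.loc[cells]
        err = (expr.log2ex - truth.log2ex.loc[cells])[detected]
        rmse = float(np.sqrt(np.nanmean(np.square(err.to_numpy()))))
        assert rmse <= 2 * cfg.ct_noise_sd

    def test_subset_means_recovered(self):
        """Configured subset means recovered within 0.1 at n=2000/subset, dropout off."""
        genes = [GeneSpec(f"g{i}", {"classical": m, "intermediate": m + 1,
                                    "non_classical": m + 2}, 0.8)
                 for i, m in enumerate([5.0, 8.0, 11.0])]
        cfg = SimConfig(genes=genes, seed=6, empty_well_rate=0.0, dropout_midpoint=-1e9,
                        n_cells={"classical": 2000, "intermediate": 2000,
                                 "non_classical": 2000})
        table, meta, _ = simulate_experiment(cfg)
        panel = PanelSpec([g.gene_id for g in genes], "g0", "18S", 40.0)
        filtered, _ = filter_empty_wells(table, panel)
        means = subset_mean_table(ct_to_log2ex(filtered), meta)
        for g in genes:
            for s in ("classical", "intermediate", "non_classical"):
                assert means.loc[g.gene_id, s] == pytest.approx(g.mu[s], abs=0.1)


class TestEvaluateRecovery:
    def _truth(self):
        cells = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(10)],
            "subset": ["classical"] * 10,
            "subgroup_member": [True] * 3 + [False] * 7,
            "empty_well": False,
        })
        specs = [GeneSpec("uni", {"classical": 5.0}, 1.0),
                 GeneSpec("bi", {"classical": 5.0}, 1.0, "bimodal", 2.0, 8.0, 0.5)]
        return type("T", (), {
            "cells": cells, "gene_specs": specs, "subgroup_genes": ["uni"],
            "log2ex": pd.DataFrame(np.ones((10, 2)), index=cells.cell_id,
                                   columns=["uni", "bi"]),
        })()

    def test_perfect_predictions_score_one(self):
        truth = self._truth()
        dips = [DipResult("uni", "classical", 10, 0.02, 0.9, False),
                DipResult("bi", "classical", 10, 0.09, 0.001, True)]
        sg = SubgroupResult("classical", ["c0", "c1", "c2"], 3, [])
        de = [DeRecord("uni", 2.0, 0.001, "up")]
        m = evaluate_recovery(truth, dips, sg, de)
        assert m["modality_sensitivity"] == 1.0
        assert m["modality_specificity"] == 1.0
        assert m["subgroup_ari"] == 1.0
        assert m["de_precision"] == 1.0 and m["de_recall"] == 1.0

    def test_empty_prediction_zero_recall(self):
        truth = self._truth()
        m = evaluate_recovery(truth, None, None, [])
        assert m["de_precision"] == 0.0
        assert m["de_recall"] == 0.0


def test_dropout_probability_shape():
    x = np.array([0.0, 3.0, 10.0])
    p = dropout_probability(x, midpoint=3.0, slope=1.5)
    assert p[1] == pytest.approx(0.5)
    assert p[0] > p[1] > p[2]
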