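import numpy as np
import pandas as pd
import pytest

from scqpcr.expression import ExpressionMatrix
from scqpcr.subgroups import (
    PcaModel,
    SubgroupConfig,
    cluster_heatmap_order,
    discover_subgroups,
    run_pca,
    select_subgroup,
    subgroup_de,
)


def _pca_from_points(pts: np.ndarray, cells: list[str]) -> PcaModel:
    d = pts.shape[1]
    return PcaModel(
        scores=pd.DataFrame(pts, index=cells, columns=[f"PC{i+1}" for i in range(d)]),
        loadings=pd.DataFrame(np.eye(d), index=[f"g{i}" for i in range(d)],
                              columns=[f"PC{i+1}" for i in range(d)]),
        variance_fraction=np.full(d, 1 / d),
    )


class TestRunPca:
    def test_duplicated_cell_gets_identical_scores(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.uniform(0, 10, (6, 4)),
                          index=[f"c{i}" for i in range(6)],
                          columns=list("abcd"))
        df.loc["c5"] = df.loc["c0"]
        pca = run_pca(ExpressionMatrix(df))
        assert np.allclose(pca.scores.loc["c0"], pca.scores.loc["c5"])

    def test_variance_fractions(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.uniform(0, 10, (8, 3)),
                          index=[f"c{i}" for i in range(8)], columns=list("abc"))
        pca = run_pca(ExpressionMatrix(df))
        vf = pca.variance_fraction
        assert np.all(vf >= 0) and np.all(np.diff(vf) <= 1e-12)
        assert vf.sum() == pytest.approx(1.0)

    def test_perfectly_correlated_genes_put_all_variance_on_pc1(self):
        x = np.linspace(0, 5, 10)
        df = pd.DataFrame({"a": x, "b": 2 * x}, index=[f"c{i}" for i in range(10)])
        pca = run_pca(ExpressionMatrix(df))
        assert pca.variance_fraction[0] == pytest.approx(1.0)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.uniform(0, 10, (9, 5)),
                          index=[f"c{i}" for i in range(9)], columns=list("abcde"))
        p1 = run_pca(ExpressionMatrix(df))
        p2 = run_pca(ExpressionMatrix(df))
        pd.testing.assert_frame_equal(p1.scores, p2.scores)
        for col in p1.loadings.columns:
            imax = p1.loadings[col].abs().idxmax()
            assert p1.loadings.loc[imax, col] > 0

    def test_constant_matrix_is_error(self):
        df = pd.DataFrame(np.full((4, 3), 2.0),
                          index=[f"c{i}" for i in range(4)], columns=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            run_pca(ExpressionMatrix(df))


class TestClusterHeatmapOrder:
    def test_identical_cells_merge_first(self):
        df = pd.DataFrame(
            {"a": [1.0, 1.0, 9.0, 5.0], "b": [2.0, 2.0, 8.0, 4.0]},
            index=["c1", "c2", "far", "mid"])
        out = cluster_heatmap_order(ExpressionMatrix(df))
        link = out["cell_linkage"]
        i1, i2 = sorted(out["cell_ids"].index(c) for c in ("c1", "c2"))
        assert {int(link[0, 0]), int(link[0, 1])} == {i1, i2}
        assert link[0, 2] == 0.0

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.uniform(0, 9, (7, 4)),
                          index=[f"c{i}" for i in range(7)], columns=list("abcd"))
        out1 = cluster_heatmap_order(ExpressionMatrix(df))
        out2 = cluster_heatmap_order(ExpressionMatrix(df.sample(frac=1, random_state=1)))
        assert out1["cell_order"] == out2["cell_order"]
        assert out1["gene_order"] == out2["gene_order"]

    def test_three_point_merge_heights(self):
        # points 0, 1, 5 on a line: first merge {0,1} at distance 1, then
        # complete linkage joins 5 at max(|5-0|, |5-1|) = 5
        df = pd.DataFrame({"a": [0.0, 1.0, 5.0], "b": [0.0, 0.0, 0.0]},
                          index=["p0", "p1", "p5"])
        link = cluster_heatmap_order(ExpressionMatrix(df))["cell_linkage"]
        assert link[0, 2] == pytest.approx(1.0)
        assert link[1, 2] == pytest.approx(5.0)


class TestSelectSubgroup:
    def test_planted_blobs_recovered_exactly(self):
        rng = np.random.default_rng(10)
        big = rng.normal(0, 1, (80, 2))
        small = rng.normal([10 / np.sqrt(2)] * 2, 1, (14, 2))
        cells = [f"c{i:03d}" for i in range(94)]
        pca = _pca_from_points(np.vstack([big, small]), cells)
        members = select_subgroup(pca, cells)
        assert members == cells[80:]

    def test_single_gaussian_cloud_rejected(self):
        rng = np.random.default_rng(11)
        nones = 0
        reps = 40
        for _ in range(reps):
            pts = rng.normal(size=(90, 2))
            cells = [f"c{i:03d}" for i in range(90)]
            nones += select_subgroup(pca := _pca_from_points(pts, cells), cells) is None
        assert nones / reps >= 0.95

    def test_order_invariance(self):
        rng = np.random.default_rng(12)
        pts = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(8, 0.5, (8, 2))])
        cells = [f"c{i:03d}" for i in range(48)]
        pca = _pca_from_points(pts, cells)
        a = select_subgroup(pca, cells)
        b = select_subgroup(pca, cells[::-1])
        assert a == b

    def test_too_few_cells_is_error(self):
        cells = [f"c{i}" for i in range(8)]
        pca = _pca_from_points(np.random.default_rng(0).normal(size=(8, 2)), cells)
        with pytest.raises(ValueError, match="at least"):
            select_subgroup(pca, cells, SubgroupConfig(min_subgroup_size=5))


class TestSubgroupDe:
    def _expr(self, member_vals, rest_vals, gene="g"):
        members = [f"m{i}" for i in range(len(member_vals))]
        rest = [f"r{i}" for i in range(len(rest_vals))]
        df = pd.DataFrame({gene: list(member_vals) + list(rest_vals)},
                          index=members + rest)
        return ExpressionMatrix(df), members, rest

    def test_identical_groups_yield_no_records(self):
        expr, m, r = self._expr([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert subgroup_de(expr, m, r) == []

    def test_planted_two_log2_shift_flagged_up(self):
        rng = np.random.default_rng(5)
        expr, m, r = self._expr(np.abs(rng.normal(8, 0.2, 14)),
                                np.abs(rng.normal(6, 0.2, 80)))
        recs = subgroup_de(expr, m, r)
        assert len(recs) == 1
        assert recs[0].direction == "up"
        assert recs[0].log2fc == pytest.approx(2.0, abs=0.3)

    def test_small_but_significant_shift_excluded(self):
        rng = np.random.default_rng(6)
        expr, m, r = self._expr(rng.normal(6.5, 0.01, 14), rng.normal(6.0, 0.01, 80))
        assert subgroup_de(expr, m, r) == []  # p tiny but |log2fc| < 1

    def test_every_record_satisfies_rule(self):
        rng = np.random.default_rng(7)
        cells = [f"m{i}" for i in range(10)] + [f"r{i}" for i in range(40)]
        df = pd.DataFrame(
            {f"g{j}": np.abs(rng.normal(5 + (j % 3), 1.0, 50)) for j in range(12)},
            index=cells)
        df.iloc[:10, :4] += 2.5
        expr = ExpressionMatrix(df)
        cfg = SubgroupConfig()
        for rec in subgroup_de(expr, cells[:10], cells[10:], cfg):
            assert rec.p < cfg.alpha and abs(rec.log2fc) >= cfg.min_abs_log2fc
            assert rec.direction == ("up" if rec.log2fc > 0 else "down")

    def test_group_too_small_is_error(self):
        expr, m, r = self._expr([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match=">= 2"):
            subgroup_de(expr, m, r)


def test_discover_subgroups_end_to_end_smoke():
    """Planted subgroup in one subset is found; unplanted subsets stay clean."""
    from scqpcr.expression import ct_to_log2ex
    from scqpcr.qpcr_io import PanelSpec, filter_empty_wells
    from scqpcr.simulate import recovery_scenario, simulate_experiment

    cfg = recovery_scenario(seed=0)
    table, meta, truth = simulate_experiment(cfg)
    panel = PanelSpec([g.gene_id for g in cfg.genes], "ACTB", "18S", 40.0)
    filtered, _ = filter_empty_wells(table, panel)
    expr = ct_to_log2ex(filtered)
    found = discover_subgroups(expr, meta[meta.cell_id.isin(expr.cell_ids)])
    assert [r.subset for r in found] == ["classical"]
    assert found[0].n_members >= 10
    assert len(found[0].de_records) >= 15
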