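"""Interaction mapping, edge classification, stoichiometry in both modes,
mode-recovery, and network-position analyses of gene loss."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allodiverge.core_model import InteractionEdge
from allodiverge.stoichiometry_network import (
    StoichiometryRecord,
    classify_edges,
    conservation_ratio,
    edge_stoichiometry,
    identity_vs_conservation,
    local_clustering_coefficient,
    loss_expression_preference,
    loss_position_test,
    map_interactions,
    mode_comparison,
    stoichiometry_table,
)
from allodiverge.synthetic_hybrid import (
    SimulationConfig,
    generate_genome,
    simulate_network,
)


def group_expr_table(rows):
    return pd.DataFrame(rows).set_index("group_id")


WORKED = group_expr_table(
    [
        # homeolog pair at 10 (A) and 20 (B) FPKM; subgenome-A single partner at 5
        {"group_id": "pair", "status": "two_copy", "fpkm_a": 10.0, "fpkm_b": 20.0,
         "ref_fpkm": 6.0},
        {"group_id": "single", "status": "single_A", "fpkm_a": 5.0, "fpkm_b": np.nan,
         "ref_fpkm": 1.0},
    ]
)


class TestMapInteractions:
    def test_dedup_and_self_loop_rules(self):
        mapping = {"r1": "x", "r2": "y", "r3": "x"}
        edges, report = map_interactions(
            [("r1", "r2"), ("r2", "r1"), ("r1", "r3")], mapping
        )
        assert [e.key for e in edges] == [("x", "y")]
        assert report["dropped_duplicate"] == 1
        assert report["dropped_self_loop"] == 1

    def test_absent_group_excluded_per_hybrid(self):
        mapping = {"r1": "x", "r2": "y"}
        edges, report = map_interactions(
            [("r1", "r2")], mapping, present_groups={"x"}
        )
        assert edges == [] and report["dropped_absent_group"] == 1
        edges2, _ = map_interactions([("r1", "r2")], mapping, present_groups={"x", "y"})
        assert len(edges2) == 1

    def test_unmapped_gene_dropped_with_count(self):
        edges, report = map_interactions([("r1", "zz")], {"r1": "x"})
        assert edges == [] and report["dropped_unmapped"] == 1

    def test_empty_edge_list(self):
        edges, _ = map_interactions([], {})
        assert edges == []


class TestClassify:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [
            ("two_copy", "single_A", "two_one_A"),
            ("two_copy", "single_B", "two_one_B"),
            ("single_A", "single_B", "one_one"),
            ("two_copy", "two_copy", "two_two"),
        ],
    )
    def test_classes(self, s1, s2, expected):
        df = classify_edges([InteractionEdge("x", "y")], {"x": s1, "y": s2})
        assert df["edge_class"].iloc[0] == expected


class TestEdgeStoichiometry:
    def test_worked_total_example(self):
        rec = edge_stoichiometry(InteractionEdge("pair", "single"), WORKED, "total")
        assert rec.hybrid_stoichiometry == pytest.approx(6.0)  # 30-to-5

    def test_worked_subgenome_example(self):
        rec = edge_stoichiometry(InteractionEdge("pair", "single"), WORKED, "subgenome")
        assert rec.hybrid_stoichiometry == pytest.approx(2.0)  # 10-to-5

    def test_one_one_edge_equal_expression(self):
        table = group_expr_table(
            [
                {"group_id": "u", "status": "single_A", "fpkm_a": 5.0,
                 "fpkm_b": np.nan, "ref_fpkm": 2.0},
                {"group_id": "v", "status": "single_B", "fpkm_a": np.nan,
                 "fpkm_b": 5.0, "ref_fpkm": 2.0},
            ]
        )
        rec = edge_stoichiometry(InteractionEdge("u", "v"), table, "total")
        assert rec.hybrid_stoichiometry == pytest.approx(1.0)
        assert rec.conservation_ratio == pytest.approx(1.0)

    def test_subgenome_mode_undefined_for_symmetric_edges(self):
        table = group_expr_table(
            [
                {"group_id": "u", "status": "two_copy", "fpkm_a": 1.0, "fpkm_b": 1.0,
                 "ref_fpkm": 1.0},
                {"group_id": "v", "status": "two_copy", "fpkm_a": 1.0, "fpkm_b": 1.0,
                 "ref_fpkm": 1.0},
            ]
        )
        out = edge_stoichiometry(InteractionEdge("u", "v"), table, "subgenome")
        assert out == "subgenome_mode_undefined_for_symmetric_edge"

    def test_zero_expression_skipped_with_reason(self):
        table = WORKED.copy()
        table.loc["single", "fpkm_a"] = 0.0
        out = edge_stoichiometry(InteractionEdge("pair", "single"), table, "total")
        assert out == "zero_hybrid_expression"
        table2 = WORKED.copy()
        table2.loc["single", "ref_fpkm"] = 0.0
        out2 = edge_stoichiometry(InteractionEdge("pair", "single"), table2, "total")
        assert out2 == "zero_reference_expression"

    def test_total_exceeds_subgenome_when_off_copy_expressed(self):
        rec_t = edge_stoichiometry(InteractionEdge("pair", "single"), WORKED, "total")
        rec_s = edge_stoichiometry(InteractionEdge("pair", "single"), WORKED, "subgenome")
        assert rec_t.hybrid_stoichiometry > rec_s.hybrid_stoichiometry
        silent_b = WORKED.copy()
        silent_b.loc["pair", "fpkm_b"] = 0.0
        rec_t2 = edge_stoichiometry(InteractionEdge("pair", "single"), silent_b, "total")
        rec_s2 = edge_stoichiometry(InteractionEdge("pair", "single"), silent_b, "subgenome")
        assert rec_t2.hybrid_stoichiometry == pytest.approx(rec_s2.hybrid_stoichiometry)

    def test_orientation_flip_leaves_abs_log_ratio_unchanged(self):
        table = group_expr_table(
            [
                {"group_id": "u", "status": "single_A", "fpkm_a": 8.0,
                 "fpkm_b": np.nan, "ref_fpkm": 3.0},
                {"group_id": "v", "status": "single_B", "fpkm_a": np.nan,
                 "fpkm_b": 2.0, "ref_fpkm": 5.0},
            ]
        )
        r1 = edge_stoichiometry(InteractionEdge("u", "v"), table, "total")
        flipped = table.rename(index={"u": "v", "v": "u"})
        r2 = edge_stoichiometry(InteractionEdge("u", "v"), flipped, "total")
        assert abs(r1.log2_ratio) == pytest.approx(abs(r2.log2_ratio))


class TestConservationRatio:
    def test_identity(self):
        assert conservation_ratio(3.0, 3.0) == (1.0, 0.0)

    def test_twofold(self):
        r, lg = conservation_ratio(6.0, 3.0)
        assert r == 2.0 and lg == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            conservation_ratio(6.0, 0.0)


class TestModeComparison:
    def _records(self, mode, seed, noise, n_groups=1500):
        cfg = SimulationConfig(seed=seed, n_groups=n_groups,
                               stoichiometry_mode=mode, stoich_noise_sd=noise)
        _, groups, _ = generate_genome(cfg)
        edges, gexpr = simulate_network(groups, cfg)
        recs, _ = stoichiometry_table(edges, gexpr)
        return recs

    def test_noiseless_winner_has_zero_iqr(self):
        recs = self._records("total", seed=1, noise=0.0, n_groups=400)
        out = mode_comparison(recs)
        assert out["verdict"] == "total"
        assert out["per_class"]["two_one_A"]["total"]["iqr"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("mode", ["total", "subgenome"])
    def test_generating_mode_recovered_across_seeds(self, mode):
        hits = sum(
            mode_comparison(self._records(mode, seed, 0.3, n_groups=600))["verdict"] == mode
            for seed in range(10)
        )
        assert hits >= 9

    def test_empty_mixed_edges_gives_no_verdict(self):
        recs = pd.DataFrame(
            columns=["edge_class", "mode", "log2_ratio"]
        ).astype({"log2_ratio": float})
        assert mode_comparison(recs)["verdict"] is None


class TestIdentityVsConservation:
    def _records_with_identity(self, coupled, n=1000, seed=3):
        rng = np.random.default_rng(seed)
        ident = rng.uniform(70, 100, n)
        noise_sd = (100 - ident) / 30.0 if coupled else np.full(n, 0.3)
        lr = rng.normal(0, noise_sd)
        recs = pd.DataFrame(
            {
                "group_numerator": [f"p{i}" for i in range(n)],
                "group_denominator": "s",
                "edge_class": "two_one_A",
                "mode": "total",
                "log2_ratio": lr,
            }
        )
        return recs, {f"p{i}": ident[i] for i in range(n)}

    def test_independent_identity_flat(self):
        recs, ident = self._records_with_identity(coupled=False)
        _, rho = identity_vs_conservation(recs, ident)
        assert abs(rho) < 0.1

    def test_injected_coupling_detected(self):
        recs, ident = self._records_with_identity(coupled=True)
        _, rho = identity_vs_conservation(recs, ident)
        assert rho < -0.3  # higher identity -> tighter conservation

    def test_degenerate_identities_rejected(self):
        recs, _ = self._records_with_identity(coupled=False, n=10)
        with pytest.raises(ValueError):
            identity_vs_conservation(recs, {f"p{i}": 90.0 for i in range(10)})


class TestLossExpressionPreference:
    def _table(self, ref_single, ref_two):
        return group_expr_table(
            [
                {"group_id": "s", "status": "single_A", "fpkm_a": 1.0,
                 "fpkm_b": np.nan, "ref_fpkm": ref_single},
                {"group_id": "t", "status": "two_copy", "fpkm_a": 1.0,
                 "fpkm_b": 1.0, "ref_fpkm": ref_two},
            ]
        )

    def test_single_side_always_higher(self):
        out = loss_expression_preference(
            [InteractionEdge("s", "t")], self._table(10.0, 2.0)
        )
        assert out["fraction"] == 1.0

    def test_tie_counts_half(self):
        out = loss_expression_preference(
            [InteractionEdge("s", "t")], self._table(5.0, 5.0)
        )
        assert out["fraction"] == 0.5

    def test_no_mixed_edges_rejected(self):
        table = group_expr_table(
            [
                {"group_id": "u", "status": "single_A", "fpkm_a": 1.0,
                 "fpkm_b": np.nan, "ref_fpkm": 1.0},
                {"group_id": "v", "status": "single_A", "fpkm_a": 1.0,
                 "fpkm_b": np.nan, "ref_fpkm": 1.0},
            ]
        )
        with pytest.raises(ValueError):
            loss_expression_preference([InteractionEdge("u", "v")], table)

    def test_symmetric_expression_near_half(self):
        cfg = SimulationConfig(seed=9, n_groups=3000)
        _, groups, _ = generate_genome(cfg)
        edges, gexpr = simulate_network(groups, cfg)
        out = loss_expression_preference(edges, gexpr)
        assert abs(out["fraction"] - 0.5) < 0.05


class TestClusteringAndLossPosition:
    def test_triangle_node(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert local_clustering_coefficient(g, "a") == 1.0

    def test_star_center(self):
        g = nx.star_graph(5)
        assert local_clustering_coefficient(g, 0) == 0.0

    def test_one_of_three_neighbor_pairs(self):
        g = nx.Graph([("x", "a"), ("x", "b"), ("x", "c"), ("a", "b")])
        assert local_clustering_coefficient(g, "x") == pytest.approx(1 / 3)

    def test_doubled_coefficients_detected(self):
        rng = np.random.default_rng(10)
        base = rng.uniform(0.05, 0.4, 300)
        coeffs = {f"a{i}": min(1.0, 2 * base[i]) for i in range(300)}
        coeffs |= {f"b{i}": base[i] for i in range(300)}
        out = loss_position_test(
            coeffs, [f"a{i}" for i in range(300)], [f"b{i}" for i in range(300)]
        )
        assert out["p"] < 0.01
        assert out["median_fold_A_over_B"] == pytest.approx(2.0, rel=0.2)

    def test_identical_distributions_null(self):
        ps = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            vals = rng.uniform(0, 1, 400)
            coeffs = {f"g{i}": vals[i] for i in range(400)}
            out = loss_position_test(
                coeffs, [f"g{i}" for i in range(200)],
                [f"g{i}" for i in range(200, 400)]
            )
            ps.append(out["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            loss_position_test({"a": 0.5}, ["a"], [])
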