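"""Ligand-receptor network construction, sign split, degrees, rankings."""

import numpy as np
import pandas as pd
import pytest

from cscore import (
    CCCNetwork,
    LRPair,
    build_network,
    degrees,
    rank_genes,
    read_lr_resource,
    split_by_sign,
    write_lr_resource,
)
from cscore.network import CCCEdge


def scores(rows):
    """rows: (feature, c_score, perm_p)"""
    return pd.DataFrame(rows, columns=["feature", "c_score", "perm_p"])


@pytest.fixture
def two_celltype_scores():
    return {
        "A": scores([("L1", 2.0, 0.01), ("R1", 0.5, 0.3), ("L2", -1.0, 0.04)]),
        "B": scores([("R1", -0.5, 0.2), ("L1", 1.0, 0.05), ("R2", 1.0, 0.1)]),
    }


class TestBuildNetwork:
    def test_hand_computed_edge(self, two_celltype_scores):
        net = build_network(
            two_celltype_scores, [LRPair("L1->R1", ("L1",), ("R1",))]
        )
        edge = {(e.sender, e.receiver): e for e in net.edges}[("A", "B")]
        # C(L1 in A) = 2 (p .01), C(R1 in B) = -0.5 (p .2)
        assert edge.weight == pytest.approx(1.5)
        assert edge.mean_p == pytest.approx(0.105)
        assert edge.n_genes_contributing == 2

    def test_receptor_complex_sums_subunits(self):
        tabs = {
            "A": scores([("L", 1.0, 0.01)]),
            "B": scores([("R1", 1.0, 0.02), ("R2", 1.0, 0.03)]),
        }
        net = build_network(tabs, [LRPair("L->R1_R2", ("L",), ("R1", "R2"))])
        edge = {(e.sender, e.receiver): e for e in net.edges}[("A", "B")]
        assert edge.weight == pytest.approx(3.0)
        assert edge.n_genes_contributing == 3

    def test_missing_ligand_emits_no_edge(self):
        tabs = {"A": scores([("X", 1.0, 0.1)]), "B": scores([("R", 1.0, 0.1)])}
        net = build_network(tabs, [LRPair("L->R", ("L",), ("R",))])
        assert len(net) == 0

    def test_partial_complex_kept_unless_require_all(self):
        tabs = {
            "A": scores([("L", 1.0, 0.01)]),
            "B": scores([("R1", 2.0, 0.02)]),  # R2 missing from receiver
        }
        pair = [LRPair("L->R1_R2", ("L",), ("R1", "R2"))]
        lenient = build_network(tabs, pair)
        assert len(lenient) == 1  # only A->B: B carries no ligand L
        assert lenient.edges[0].n_genes_contributing == 2
        strict = build_network(tabs, pair, require_all_subunits=True)
        assert len(strict) == 0

    def test_self_edges_excluded_by_default(self):
        tabs = {"A": scores([("L", 1.0, 0.1), ("R", 1.0, 0.1)]),
                "B": scores([("L", 1.0, 0.1), ("R", 1.0, 0.1)])}
        pair = [LRPair("L->R", ("L",), ("R",))]
        default = build_network(tabs, pair)
        assert {(e.sender, e.receiver) for e in default.edges} == {("A", "B"), ("B", "A")}
        with_self = build_network(tabs, pair, include_self_edges=True)
        assert len(with_self) == 4

    def test_max_mean_p_filter(self, two_celltype_scores):
        pair = [LRPair("L1->R1", ("L1",), ("R1",))]
        assert len(build_network(two_celltype_scores, pair, max_mean_p=0.05)) == 0
        assert len(build_network(two_celltype_scores, pair, max_mean_p=0.2)) >= 1

    def test_row_order_invariance(self, two_celltype_scores):
        pairs = [
            LRPair("L1->R1", ("L1",), ("R1",)),
            LRPair("L2->R2", ("L2",), ("R2",)),
        ]
        net1 = build_network(two_celltype_scores, pairs)
        shuffled = {
            ct: df.iloc[::-1].reset_index(drop=True)
            for ct, df in two_celltype_scores.items()
        }
        net2 = build_network(shuffled, pairs[::-1])
        pd.testing.assert_frame_equal(net1.to_frame(), net2.to_frame())

    def test_duplicate_gene_in_table_rejected(self):
        tabs = {"A": scores([("L", 1.0, 0.1), ("L", 2.0, 0.2)]),
                "B": scores([("R", 1.0, 0.1)])}
        with pytest.raises(ValueError, match="twice"):
            build_network(tabs, [LRPair("L->R", ("L",), ("R",))])

    def test_empty_inputs_rejected(self):
        tabs = {"A": scores([("L", 1.0, 0.1)]), "B": scores([("R", 1.0, 0.1)])}
        with pytest.raises(ValueError):
            build_network(tabs, [])
        with pytest.raises(ValueError):
            build_network({"A": tabs["A"]}, [LRPair("L->R", ("L",), ("R",))])


def _net(weights):
    pairs = [LRPair(f"p{i}", (f"L{i}",), (f"R{i}",)) for i in range(len(weights))]
    edges = tuple(
        CCCEdge("A" if i % 2 == 0 else "B", "B" if i % 2 == 0 else "C",
                pairs[i], w, 0.1, 1)
        for i, w in enumerate(weights)
    )
    return CCCNetwork(edges, frozenset({"A", "B", "C"}))


class TestSplitAndDegrees:
    def test_sign_partition_counts_zero_drops(self):
        split = split_by_sign(_net([1.5, -0.2, 0.0]))
        assert len(split.shared) == 1 and len(split.different) == 1
        assert split.n_zero_dropped == 1

    def test_all_positive_gives_empty_different(self):
        split = split_by_sign(_net([1.0, 2.0]))
        assert len(split.different) == 0

    def test_single_negative_edge_degrees_absolute(self):
        net = _net([-2.0])
        deg = degrees(net).set_index("cell_type")
        assert deg.loc["A", "out_degree"] == 2.0
        assert deg.loc["B", "in_degree"] == 2.0
        assert deg.loc["C", "out_degree"] == 0.0

    def test_empty_network_all_zero(self):
        deg = degrees(CCCNetwork((), frozenset({"A", "B"})))
        assert (deg[["out_degree", "in_degree"]] == 0).all().all()

    def test_toy_degrees_match_hand_summation(self):
        # A->B: +1.0, -3.0 ; B->C: +2.0, -0.5
        net = _net([1.0, 2.0, -3.0, -0.5])
        deg = degrees(net).set_index("cell_type")
        assert deg.loc["A", "out_degree"] == pytest.approx(4.0)
        assert deg.loc["B", "out_degree"] == pytest.approx(2.5)
        assert deg.loc["B", "in_degree"] == pytest.approx(4.0)
        assert deg.loc["C", "in_degree"] == pytest.approx(2.5)

    def test_conservation_and_split_reconstruction(self):
        rng = np.random.default_rng(0)
        net = _net(list(rng.normal(0, 2, 11)))
        deg = degrees(net)
        total = sum(abs(e.weight) for e in net.edges)
        assert deg["out_degree"].sum() == pytest.approx(total)
        assert deg["in_degree"].sum() == pytest.approx(total)
        split = split_by_sign(net)
        recon = (
            degrees(split.shared).set_index("cell_type")
            + degrees(split.different).set_index("cell_type")
        )
        pd.testing.assert_frame_equal(recon, deg.set_index("cell_type"))

    def test_edge_removal_monotonicity(self):
        net = _net([1.0, 2.0, -3.0])
        removed = CCCNetwork(net.edges[:-1], net.cell_types)
        d0 = degrees(net).set_index("cell_type")
        d1 = degrees(removed).set_index("cell_type")
        sender = net.edges[-1].sender
        assert d0.loc[sender, "out_degree"] - d1.loc[sender, "out_degree"] == pytest.approx(
            abs(net.edges[-1].weight)
        )


class TestRankGenes:
    def test_ligand_in_two_edges_accumulates(self):
        pair = LRPair("L->R", ("L",), ("R",))
        edges = (
            CCCEdge("A", "B", pair, 1.0, 0.1, 2),
            CCCEdge("A", "C", pair, -2.0, 0.1, 2),
        )
        net = CCCNetwork(edges, frozenset({"A", "B", "C"}))
        tab = rank_genes(net, "ligand")
        assert tab.iloc[0].tolist() == ["A", "L", 3.0]
        rec = rank_genes(net, "receptor")
        assert set(rec["cell_type"]) == {"B", "C"}

    def test_absent_gene_absent_from_table(self):
        net = _net([1.0])
        tab = rank_genes(net, "ligand")
        assert "L9" not in set(tab["gene"])

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(4)
        net = _net(list(rng.normal(0, 1, 9)))
        tab = rank_genes(net, "receptor")
        brute = {}
        for e in net.edges:
            for g in e.pair.receptor_subunits:
                brute[(e.receiver, g)] = brute.get((e.receiver, g), 0.0) + abs(e.weight)
        got = {(r.cell_type, r.gene): r.score for r in tab.itertuples(index=False)}
        assert got == pytest.approx(brute)
        assert (tab["score"].diff().dropna() <= 1e-12).all()  # descending

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError):
            rank_genes(_net([1.0]), "cofactor")


class TestResourceIO:
    def test_round_trip_with_complexes(self, tmp_path):
        pairs = [
            LRPair("FN1->ITGA3_ITGB1", ("FN1",), ("ITGA3", "ITGB1")),
            LRPair("BMP6->BMPR1A", ("BMP6",), ("BMPR1A",)),
        ]
        path = tmp_path / "resource.csv"
        write_lr_resource(pairs, path)
        assert read_lr_resource(path) == pairs

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("pair_name,ligand\nx,L\n")
        with pytest.raises(ValueError, match="receptor"):
            read_lr_resource(p)
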