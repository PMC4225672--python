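"""FF/CFF enumeration, switching null, significance, embedding and roles."""

import numpy as np
import pytest

from trnkit.module_detection import ModulePartition
from trnkit.motif_census import (
    count_by_type,
    embedding_fractions,
    enumerate_motifs,
    ff_pair_summary,
    motif_significance,
    regulator_role_profile,
    switching_null,
)

from conftest import (
    all_three_node_digraphs,
    net_from_edges,
    oracle_motifs,
    random_digraph,
)


def as_tuples(instances):
    return {(i.motif_type, i.master, i.local, i.target) for i in instances}


class TestEnumeration:
    def test_minimal_ff(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        inst = enumerate_motifs(net)
        assert as_tuples(inst) == {("FF", "a", "b", "c")}

    def test_minimal_cff(self):
        net = net_from_edges([("a", "b"), ("b", "a"), ("b", "c"), ("a", "c")])
        inst = enumerate_motifs(net)
        assert as_tuples(inst) == {("CFF", "a", "b", "c")}

    def test_target_feedback_disqualifies(self):
        # C -> A closes a cycle; the triple is neither FF nor CFF (induced match)
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c"), ("c", "a")])
        assert enumerate_motifs(net) == []

    def test_self_loops_ignored(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c"), ("a", "a")])
        assert as_tuples(enumerate_motifs(net)) == {("FF", "a", "b", "c")}

    def test_all_three_node_digraphs_match_oracle(self):
        for edges in all_three_node_digraphs():
            if not edges:
                continue
            net = net_from_edges(edges)
            assert as_tuples(enumerate_motifs(net)) == oracle_motifs(net), edges

    @pytest.mark.parametrize("seed", range(5))
    def test_random_eight_node_graphs_match_oracle(self, seed):
        net = random_digraph(8, 0.25, seed)
        assert as_tuples(enumerate_motifs(net)) == oracle_motifs(net)

    def test_ff_and_cff_disjoint_and_relabel_invariant(self):
        net = random_digraph(10, 0.2, seed=13)
        inst = enumerate_motifs(net)
        keys = as_tuples(inst)
        assert len(keys) == len(inst)  # no duplicates
        # relabel every node; instance count is isomorphism-invariant
        mapping = {n: f"x_{n}" for n in net.graph.nodes}
        relabeled = net_from_edges(
            [(mapping[u], mapping[v]) for u, v in net.graph.edges]
        )
        assert len(enumerate_motifs(relabeled)) == len(inst)


class TestSwitchingNull:
    def test_two_edge_graph_keeps_degree_sequence(self):
        net = net_from_edges([("a", "b"), ("c", "d")])
        out = switching_null(net, n_swaps_per_edge=50, seed=1)
        assert dict(out.graph.out_degree()) == dict(net.graph.out_degree())
        assert dict(out.graph.in_degree()) == dict(net.graph.in_degree())
        assert set(out.graph.edges) in (
            {("a", "b"), ("c", "d")}, {("a", "d"), ("c", "b")},
        ) or set(out.graph.edges) == {("a", "b"), ("c", "d")}

    @pytest.mark.parametrize("seed", range(10))
    def test_degree_pairs_conserved(self, seed):
        net = random_digraph(20, 0.15, seed=seed)
        out = switching_null(net, n_swaps_per_edge=20, seed=seed + 100)
        for n in net.graph.nodes:
            assert out.graph.in_degree(n) == net.graph.in_degree(n)
            assert out.graph.out_degree(n) == net.graph.out_degree(n)

    def test_randomization_actually_moves_ff_counts(self):
        from trnkit.synthetic_networks import SyntheticSpec, generate

        net, _ = generate(SyntheticSpec(
            seed=5, n_regulators=30, n_targets=120, n_modules=3,
            intra_module_edge_prob=0.2, inter_module_edge_prob=0.02,
            n_planted_ff=15, n_planted_cff=0, include_hub=False,
        ))
        counts = [
            count_by_type(enumerate_motifs(
                switching_null(net, n_swaps_per_edge=10, seed=s)
            ))["FF"]
            for s in range(25)
        ]
        assert np.var(counts) > 0

    def test_single_edge_returns_copy_with_warning(self, caplog):
        net = net_from_edges([("a", "b")])
        with caplog.at_level("WARNING"):
            out = switching_null(net, seed=0)
        assert set(out.graph.edges) == {("a", "b")}


class TestSignificance:
    def test_planted_excess_flagged(self):
        from trnkit.synthetic_networks import SyntheticSpec, generate

        net, _ = generate(SyntheticSpec(
            seed=11, n_regulators=40, n_targets=150, n_modules=4,
            intra_module_edge_prob=0.1, inter_module_edge_prob=0.01,
            n_planted_ff=30, n_planted_cff=0, include_hub=False,
        ))
        sig = {s.motif_type: s for s in motif_significance(
            net, n_random=200, n_swaps_per_edge=10, seed=1
        )}
        assert sig["FF"].significant
        assert sig["FF"].z_score > 3
        # pseudocount keeps p strictly positive
        assert sig["FF"].empirical_p >= 1 / 201

    def test_low_n_random_warns(self, caplog):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        with caplog.at_level("WARNING"):
            motif_significance(net, n_random=10, n_swaps_per_edge=5, seed=0)
        assert any("coarse" in r.message for r in caplog.records)


class TestPairSummaryAndEmbedding:
    @staticmethod
    def partition(assignment):
        return ModulePartition(assignment=assignment, method="external", cut="test")

    def test_single_ff_one_row(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        rows = ff_pair_summary(enumerate_motifs(net), self.partition({"a": 1, "b": 1}))
        assert len(rows) == 1
        assert rows[0].n_targets == 1

    def test_two_locals_three_targets_each(self):
        edges = []
        for local in ("b1", "b2"):
            edges.append(("a", local))
            for t in range(3):
                edges += [("a", f"{local}t{t}"), (local, f"{local}t{t}")]
        net = net_from_edges(edges)
        rows = ff_pair_summary(
            enumerate_motifs(net), self.partition({"a": 1, "b1": 1, "b2": 2})
        )
        assert [(r.master, r.local, r.n_targets) for r in rows] == [
            ("a", "b1", 3), ("a", "b2", 3),
        ]
        assert rows[1].local_module == 2

    def test_unassigned_regulator_labelled(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        rows = ff_pair_summary(enumerate_motifs(net), self.partition({"a": 1}))
        assert rows[0].local_module == "unassigned"

    def test_single_module_fully_embedded(self):
        net = net_from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"),
             ("a", "d"), ("d", "a"), ("d", "e"), ("a", "e")]
        )
        rep = embedding_fractions(
            enumerate_motifs(net), self.partition({"a": 1, "b": 1, "d": 1})
        )
        assert rep.fractions["FF"] == pytest.approx(1.0)
        assert rep.fractions["CFF"] == pytest.approx(1.0)
        assert rep.cross_talk == []

    def test_three_intra_one_inter_gives_three_quarters(self):
        edges = []
        for i, local in enumerate(["b1", "b2", "b3", "z"]):
            edges.append(("a", local))
            edges += [("a", f"t{i}"), (local, f"t{i}")]
        net = net_from_edges(edges)
        part = self.partition({"a": 1, "b1": 1, "b2": 1, "b3": 1, "z": 2})
        rep = embedding_fractions(enumerate_motifs(net), part)
        assert rep.fractions["FF"] == pytest.approx(0.75)
        assert rep.embedded["FF"] + len(rep.cross_talk) == rep.totals["FF"]
        assert [c.local for c in rep.cross_talk] == ["z"]


class TestRoleProfile:
    def test_single_ff_roles(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        roles = regulator_role_profile(enumerate_motifs(net))
        assert (roles["a"].n_master, roles["a"].n_local) == (1, 0)
        assert roles["a"].dominant_role == "master"
        assert roles["b"].dominant_role == "local"

    def test_shared_middle_node_is_mixed(self):
        # a -> b -> c chain of two overlapping FFs: b is master once, local once
        net = net_from_edges(
            [("a", "b"), ("b", "t1"), ("a", "t1"),
             ("b", "d"), ("d", "t2"), ("b", "t2")]
        )
        roles = regulator_role_profile(enumerate_motifs(net))
        assert (roles["b"].n_master, roles["b"].n_local) == (1, 1)
        assert roles["b"].dominant_role == "mixed"
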