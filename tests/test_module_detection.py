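"""Association matrix, hierarchical and Girvan-Newman modules, comparison."""

import numpy as np
import pytest

from trnkit.errors import CutError, IncomparablePartitionsError
from trnkit.module_detection import (
    ModulePartition,
    association_matrix,
    compare_partitions,
    girvan_newman_modules,
    hclust_modules,
    merge_heights,
    read_partition,
    write_partition,
)

from conftest import net_from_edges, oracle_ari, oracle_distances, random_digraph


def two_cliques_with_bridge():
    """Two 4-node cliques joined by a single bridge edge."""
    left = ["a1", "a2", "a3", "a4"]
    right = ["b1", "b2", "b3", "b4"]
    edges = [(u, v) for grp in (left, right) for u in grp for v in grp if u < v]
    edges.append(("a1", "b1"))
    return net_from_edges(edges), left, right


class TestAssociationMatrix:
    def test_path_graph_distances(self):
        am = association_matrix(net_from_edges([("a", "b"), ("b", "c")]))
        i, j, k = (am.index(x) for x in "abc")
        assert am.association[i, j] == 1.0       # d=1
        assert am.association[i, k] == 0.25      # d=2 -> 1/4
        assert am.association[i, i] == 1.0

    def test_disconnected_pairs_are_zero(self):
        am = association_matrix(net_from_edges([("a", "b"), ("c", "d")]))
        assert am.association[am.index("a"), am.index("c")] == 0.0
        assert np.isinf(am.distance[am.index("a"), am.index("d")])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_floyd_warshall_oracle(self, seed):
        net = random_digraph(10, 0.2, seed)
        am = association_matrix(net)
        oracle = oracle_distances(net, am.node_order)
        assert np.array_equal(
            np.where(np.isinf(am.distance), -1, am.distance),
            np.where(np.isinf(oracle), -1, oracle),
        )

    def test_symmetry_and_range(self):
        am = association_matrix(random_digraph(12, 0.2, seed=9))
        assert np.array_equal(am.association, am.association.T)
        assert am.association.min() >= 0.0 and am.association.max() <= 1.0

    def test_adding_edge_never_decreases_association(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d")]
        before = association_matrix(net_from_edges(edges))
        after = association_matrix(net_from_edges(edges + [("a", "d")]))
        assert (after.association >= before.association - 1e-15).all()


class TestHclustModules:
    def test_two_cliques_split_at_auto_cut(self):
        net, left, right = two_cliques_with_bridge()
        part = hclust_modules(association_matrix(net), cut="auto")
        assert part.n_modules == 2
        mods = part.modules()
        assert set(left) in mods.values() and set(right) in mods.values()

    def test_explicit_cut_count_honoured(self):
        net, _, _ = two_cliques_with_bridge()
        part = hclust_modules(association_matrix(net), cut=4)
        assert part.n_modules == 4

    def test_cut_larger_than_network_rejected(self):
        net, *_ = two_cliques_with_bridge()
        with pytest.raises(CutError):
            hclust_modules(association_matrix(net), cut=99)

    def test_merge_heights_non_decreasing(self):
        # average linkage on a fixed dissimilarity is monotone
        net = random_digraph(15, 0.2, seed=21)
        part = hclust_modules(association_matrix(net), cut=3)
        assert part.merge_tree is not None
        hs = merge_heights(part)
        assert all(h >= -1e-12 for h in hs)

    def test_isolated_nodes_become_singletons_outside_cut(self):
        net, *_ = two_cliques_with_bridge()
        net.graph.add_node("loner", cls="TF")
        part = hclust_modules(association_matrix(net), cut="auto")
        assert part.singletons == ["loner"]
        # the singleton holds its own module index above the cut modules
        assert part.assignment["loner"] == max(part.assignment.values())

    def test_deterministic(self):
        net = random_digraph(15, 0.2, seed=5)
        p1 = hclust_modules(association_matrix(net), cut=4)
        p2 = hclust_modules(association_matrix(net), cut=4)
        assert p1.assignment == p2.assignment
        assert p1.merge_tree == p2.merge_tree

    def test_both_metrics_split_planted_cliques(self):
        net, left, right = two_cliques_with_bridge()
        am = association_matrix(net)
        for metric in ("profile_correlation", "one_minus_association"):
            part = hclust_modules(am, cut=2, metric=metric)
            assert set(left) in part.modules().values()


class TestGirvanNewman:
    def test_barbell_bridge_removed_first(self):
        edges = [("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
                 ("b1", "b2"), ("b2", "b3"), ("b1", "b3"),
                 ("a1", "b1")]
        net = net_from_edges(edges)
        part = girvan_newman_modules(net, cut=2)
        mods = part.modules()
        assert {"a1", "a2", "a3"} in mods.values()
        assert {"b1", "b2", "b3"} in mods.values()

    def test_auto_cut_maximizes_modularity(self):
        net, left, right = two_cliques_with_bridge()
        part = girvan_newman_modules(net, cut="auto")
        assert set(left) in part.modules().values()
        assert set(right) in part.modules().values()

    def test_planted_two_block_recovered_exactly(self):
        from trnkit.synthetic_networks import SyntheticSpec, generate

        spec = SyntheticSpec(
            seed=2, n_regulators=16, n_targets=0, n_modules=2,
            intra_module_edge_prob=0.6, inter_module_edge_prob=0.02,
            n_planted_ff=0, n_planted_cff=0, include_hub=False,
        )
        net, truth = generate(spec)
        part = girvan_newman_modules(net, cut=2)
        labels_true = [truth.module_assignment[r] for r in sorted(part.assignment)]
        labels_got = [part.assignment[r] for r in sorted(part.assignment)]
        assert oracle_ari(labels_true, labels_got) == pytest.approx(1.0)


class TestComparePartitions:
    @staticmethod
    def partition(assignment):
        return ModulePartition(assignment=assignment, method="external", cut="test")

    def test_identity_gives_ari_one_all_equal(self):
        p = self.partition({"a": 1, "b": 1, "c": 2, "d": 2})
        cmp = compare_partitions(p, p)
        assert cmp.ari == pytest.approx(1.0)
        assert cmp.nmi == pytest.approx(1.0)
        assert set(cmp.relations.values()) == {"equal"}

    def test_refinement_marks_split_module_superset(self):
        a = self.partition({"a": 1, "b": 1, "c": 1, "d": 1, "e": 2, "f": 2})
        b = self.partition({"a": 1, "b": 1, "c": 2, "d": 2, "e": 3, "f": 3})
        cmp = compare_partitions(a, b)
        assert cmp.relations[1] == "superset"
        assert cmp.relations[2] == "equal"
        assert cmp.ari < 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_ari_matches_contingency_formula(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(40)]
        a = self.partition({n: int(rng.integers(1, 5)) for n in nodes})
        b = self.partition({n: int(rng.integers(1, 4)) for n in nodes})
        cmp = compare_partitions(a, b)
        la = [a.assignment[n] for n in cmp.common_nodes]
        lb = [b.assignment[n] for n in cmp.common_nodes]
        assert cmp.ari == pytest.approx(oracle_ari(la, lb), abs=1e-12)

    def test_partial_overlap_drops_with_warning(self, caplog):
        a = self.partition({"a": 1, "b": 1, "c": 2})
        b = self.partition({"b": 1, "c": 1, "d": 2})
        with caplog.at_level("WARNING"):
            cmp = compare_partitions(a, b)
        assert cmp.common_nodes == ["b", "c"]
        assert cmp.dropped_from_a == ["a"] and cmp.dropped_from_b == ["d"]

    def test_disjoint_node_sets_rejected(self):
        a = self.partition({"a": 1})
        b = self.partition({"z": 1})
        with pytest.raises(IncomparablePartitionsError):
            compare_partitions(a, b)


def test_partition_tsv_round_trip(tmp_path):
    part = ModulePartition(
        assignment={"tnrA": 1, "glpR": 1, "kipR": 1, "pyrR": 2},
        method="association_hclust", cut="count=2",
    )
    path = tmp_path / "partition.tsv"
    write_partition(part, path)
    back = read_partition(path)
    assert back.assignment == part.assignment
    assert back.method == "external"
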