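"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own code paths: degrees
are counted straight off the edge list, all-pairs distances come from
scipy's Floyd-Warshall, motif triples are checked by exhaustive enumeration
of the induced definition, and the adjusted Rand index is computed from the
contingency-table formula.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pytest

from trnkit.network_io import Interaction, RegulatoryNetwork, TF


def net_from_edges(edges, classes=None, evidence=None, modes=None) -> RegulatoryNetwork:
    """Build a network from (u, v) pairs; every source defaults to class TF."""
    classes = classes or {}
    evidence = evidence or {}
    modes = modes or {}
    net = RegulatoryNetwork(provenance="fixture")
    for u, v in edges:
        net.add_interaction(
            Interaction(
                u,
                v,
                regulator_class=classes.get(u, TF),
                mode=modes.get((u, v), "unknown"),
                evidence=evidence.get((u, v), "unknown"),
            )
        )
    return net


def random_digraph(n: int, p: float, seed: int, allow_self_loops: bool = False):
    """Seeded Erdos-Renyi digraph as a RegulatoryNetwork, nodes n00..n<n-1>."""
    rng = np.random.default_rng(seed)
    names = [f"n{i:02d}" for i in range(n)]
    edges = [
        (names[i], names[j])
        for i in range(n)
        for j in range(n)
        if (i != j or allow_self_loops) and rng.random() < p
    ]
    if not edges:  # keep fixtures non-empty
        edges = [(names[0], names[-1])]
    return net_from_edges(edges)


# ---------------------------------------------------------------------------
# independent oracles


def oracle_degrees(net: RegulatoryNetwork, direction: str) -> dict[str, int]:
    """Degree per node counted directly off the edge list."""
    counts = {n: 0 for n in net.graph.nodes}
    for u, v in net.graph.edges:
        if direction in ("out", "total"):
            counts[u] += 1
        if direction in ("in", "total"):
            counts[v] += 1
    return counts


def oracle_distances(net: RegulatoryNetwork, node_order: list[str]) -> np.ndarray:
    """All-pairs shortest paths on the undirected projection via
    scipy.sparse.csgraph.floyd_warshall."""
    from scipy.sparse.csgraph import floyd_warshall

    idx = {n: i for i, n in enumerate(node_order)}
    n = len(node_order)
    adj = np.zeros((n, n))
    for u, v in net.graph.edges:
        if u == v:
            continue
        adj[idx[u], idx[v]] = 1
        adj[idx[v], idx[u]] = 1
    return floyd_warshall(adj, directed=False, unweighted=True)


def oracle_motifs(net: RegulatoryNetwork) -> set[tuple[str, str, str, str]]:
    """All FF/CFF triples by literal check of every ordered (a, b, c).

    Returns tuples (type, master, local, target); CFF is canonicalized to
    the lexicographically smaller master.
    """
    g = net.graph
    has = lambda u, v: g.has_edge(u, v) and u != v
    found = set()
    for a, b, c in itertools.permutations(g.nodes, 3):
        if not (has(a, b) and has(b, c) and has(a, c)):
            continue
        if has(c, a) or has(c, b):
            continue
        if has(b, a):
            m, l = min(a, b), max(a, b)
            # CFF needs both regulators pointing at the target
            if has(m, c) and has(l, c):
                found.add(("CFF", m, l, c))
        else:
            found.add(("FF", a, b, c))
    return found


def oracle_ari(labels_a, labels_b) -> float:
    """Adjusted Rand index from the contingency-table formula."""
    a_vals = sorted(set(labels_a))
    b_vals = sorted(set(labels_b))
    table = np.zeros((len(a_vals), len(b_vals)), dtype=int)
    for la, lb in zip(labels_a, labels_b):
        table[a_vals.index(la), b_vals.index(lb)] += 1
    n = len(labels_a)
    sum_ij = sum(comb(int(x), 2) for x in table.ravel())
    sum_a = sum(comb(int(x), 2) for x in table.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in table.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def all_three_node_digraphs():
    """Every loop-free digraph on nodes {a, b, c} (64 of them)."""
    nodes = ["a", "b", "c"]
    arcs = [(u, v) for u in nodes for v in nodes if u != v]
    for mask in range(2 ** len(arcs)):
        edges = [arcs[i] for i in range(len(arcs)) if mask >> i & 1]
        yield edges


@pytest.fixture
def tiny_tsv(tmp_path):
    """5-row file: one duplicated interaction and one self-loop."""
    text = (
        "# curated fixture\n"
        "regulator\ttarget\tregulator_class\tmode\tevidence\n"
        "ccpA\tgntR\tTF\trepression\tstrong\n"
        "ccpA\tgntR\tTF\tactivation\tstrong\n"
        "hrcA\thrcA\tTF\trepression\tstrong\n"
        "sigB\tctsR\tsigma\tactivation\tweak\n"
        "ccpA\tackA\tTF\tactivation\tstrong\n"
    )
    path = tmp_path / "tiny.tsv"
    path.write_text(text)
    return path
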