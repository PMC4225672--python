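"""Feed-forward motif census with a degree-preserving switching null model.

Two three-node motif classes are handled, matched as *induced* subgraphs
(mfinder convention — any extra edge inside the triple disqualifies it):

FF  (feed-forward):          A -> B, B -> C, A -> C; no B -> A.
CFF (complex feed-forward):  an FF whose two regulators also form a two-node
                             feedback circuit, i.e. additionally B -> A.

A is the master regulator, B the local regulator, C the target.  The two
classes are disjoint by construction.  In a CFF the mutual edge makes the
two regulator roles symmetric; the instance is emitted once, with the
lexicographically smaller regulator recorded as master.

Over-representation is assessed against random networks produced by repeated
double-edge swaps (u->v, x->y  becomes  u->y, x->v) that preserve every
node's in- and out-degree exactly; swaps creating self-loops or duplicate
edges are rejected.  The empirical p-value uses a +1 pseudocount:
p = (1 + #null counts >= observed) / (1 + n_randomizations), and motif types
with p < 0.01 are flagged significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import EmptyNetworkError
from .module_detection import ModulePartition
from .network_io import RegulatoryNetwork

logger = logging.getLogger(__name__)

MotifType = Literal["FF", "CFF"]

SIGNIFICANCE_ALPHA = 0.01


@dataclass(frozen=True)
class MotifInstance:
    """One FF/CFF occurrence with its three roles."""

    motif_type: MotifType
    master: str
    local: str
    target: str


@dataclass
class MotifSignificance:
    """Null-model statistics for one motif type."""

    motif_type: MotifType
    observed_count: int
    null_mean: float
    null_sd: float
    z_score: float
    empirical_p: float
    n_randomizations: int

    @property
    def significant(self) -> bool:
        return self.empirical_p < SIGNIFICANCE_ALPHA


@dataclass
class FFPairSummary:
    """Distinct-target count for one (master, local) regulator pair."""

    master: str
    master_module: int | str
    local: str
    local_module: int | str
    n_targets: int


def enumerate_motifs(net: RegulatoryNetwork) -> list[MotifInstance]:
    """Enumerate every FF and CFF instance exactly once.

    Self-loops are ignored for motif membership.  Induced-subgraph matching:
    for FF the triple must contain exactly {A->B, B->C, A->C}; for CFF
    exactly {A->B, B->A, B->C, A->C}.  Any edge from the target back to a
    regulator, or an edge pattern beyond the definition, disqualifies the
    triple from both classes.
    """
    g = net.graph
    succ = {
        u: {v for v in g.successors(u) if v != u} for u in g.nodes
    }
    has = lambda u, v: v in succ[u]

    out: list[MotifInstance] = []
    for a in sorted(succ):
        for b in sorted(succ[a]):
            mutual = has(b, a)
            if mutual and a > b:
                continue  # CFF pair handled once, from its smaller endpoint
            common = succ[a] & succ[b]
            for c in sorted(common):
                if c == a or c == b:
                    continue
                if has(c, a) or has(c, b):
                    continue  # target feeds back: not an FF/CFF induced triple
                if mutual:
                    out.append(MotifInstance("CFF", master=a, local=b, target=c))
                else:
                    out.append(MotifInstance("FF", master=a, local=b, target=c))
    return out


def count_by_type(instances: Iterable[MotifInstance]) -> dict[MotifType, int]:
    counts: dict[MotifType, int] = {"FF": 0, "CFF": 0}
    for inst in instances:
        counts[inst.motif_type] += 1
    return counts


# ---------------------------------------------------------------------------
# switching null model


def switching_null(
    net: RegulatoryNetwork,
    n_swaps_per_edge: int = 100,
    seed: int | np.random.Generator = 0,
) -> RegulatoryNetwork:
    """Degree-preserving randomization by repeated double-edge swaps.

    ``n_swaps_per_edge * n_edges`` swap attempts are made; each picks two
    distinct edges u->v, x->y and rewires them to u->y, x->v unless that
    would create a self-loop or a duplicate edge.  Every node's (in, out)
    degree pair is preserved exactly.  Deterministic for a given seed.
    """
    if net.n_edges < 2:
        logger.warning("switching_null: fewer than 2 edges; returning input unchanged")
        return net.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    edges = sorted((u, v) for u, v in net.graph.edges)
    edge_set = set(edges)
    m = len(edges)
    n_attempts = n_swaps_per_edge * m
    n_done = 0
    # draw indices in blocks: cheaper than per-attempt rng calls
    picks = rng.integers(0, m, size=(n_attempts, 2))
    for i1, i2 in picks:
        if i1 == i2:
            continue
        u, v = edges[i1]
        x, y = edges[i2]
        if u == y or x == v:
            continue  # would create a self-loop
        if (u, y) in edge_set or (x, v) in edge_set:
            continue  # would create a duplicate edge
        edge_set.discard((u, v))
        edge_set.discard((x, y))
        edge_set.add((u, y))
        edge_set.add((x, v))
        edges[i1] = (u, y)
        edges[i2] = (x, v)
        n_done += 1
    if n_done == 0:
        logger.warning(
            "switching_null: no valid swap found in %d attempts; "
            "degree sequence may admit a unique realization", n_attempts,
        )

    out = RegulatoryNetwork(provenance=f"{net.provenance}|switched")
    out.graph.add_nodes_from(net.graph.nodes(data=True))
    out._display = dict(net._display)
    for u, v in edges:
        out.graph.add_edge(u, v, mode="unknown", evidence="unknown")
    # conservation law, cheap enough to assert on every call
    assert dict(out.graph.in_degree()) == dict(net.graph.in_degree())
    assert dict(out.graph.out_degree()) == dict(net.graph.out_degree())
    return out


def motif_significance(
    net: RegulatoryNetwork,
    n_random: int = 1000,
    n_swaps_per_edge: int = 100,
    seed: int = 0,
) -> list[MotifSignificance]:
    """Observed FF/CFF counts versus the switching-null ensemble.

    Each of the ``n_random`` randomizations gets an independent child seed
    spawned from ``seed``.  Reports z-score and pseudocounted empirical
    p-value per motif type.
    """
    if net.n_nodes == 0:
        raise EmptyNetworkError("motif significance of an empty network")
    if n_random < 100:
        logger.warning(
            "n_random=%d < 100: empirical p-values will be coarse", n_random
        )
    observed = count_by_type(enumerate_motifs(net))
    null_counts: dict[str, list[int]] = {"FF": [], "CFF": []}
    master_rng = np.random.default_rng(seed)
    for _ in range(n_random):
        child = np.random.default_rng(master_rng.integers(0, 2**31 - 1))
        rand_net = switching_null(net, n_swaps_per_edge=n_swaps_per_edge, seed=child)
        counts = count_by_type(enumerate_motifs(rand_net))
        for mt in ("FF", "CFF"):
            null_counts[mt].append(counts[mt])

    results = []
    for mt in ("FF", "CFF"):
        nulls = np.array(null_counts[mt], dtype=float)
        mean = float(nulls.mean())
        sd = float(nulls.std(ddof=1)) if len(nulls) > 1 else 0.0
        obs = observed[mt]
        z = (obs - mean) / sd if sd > 0 else float("inf") if obs > mean else 0.0
        p = (1 + int((nulls >= obs).sum())) / (1 + n_random)
        results.append(
            MotifSignificance(
                motif_type=mt,
                observed_count=obs,
                null_mean=mean,
                null_sd=sd,
                z_score=float(z),
                empirical_p=float(p),
                n_randomizations=n_random,
            )
        )
    return results


# ---------------------------------------------------------------------------
# module embedding and regulator roles


def ff_pair_summary(
    instances: Sequence[MotifInstance], partition: ModulePartition
) -> list[FFPairSummary]:
    """One row per (master, local) regulator pair with its distinct-target
    count and module labels; regulators outside the partition are labelled
    ``"unassigned"``."""
    pairs: dict[tuple[str, str], set[str]] = {}
    for inst in instances:
        pairs.setdefault((inst.master, inst.local), set()).add(inst.target)

    def label(node: str) -> int | str:
        m = partition.module_of(node)
        return m if m is not None else "unassigned"

    rows = [
        FFPairSummary(
            master=master,
            master_module=label(master),
            local=local,
            local_module=label(local),
            n_targets=len(targets),
        )
        for (master, local), targets in pairs.items()
    ]
    rows.sort(key=lambda r: (-r.n_targets, r.master, r.local))
    return rows


@dataclass
class EmbeddingReport:
    """Fraction of motif instances whose two regulators share a module."""

    fractions: dict[MotifType, float]          # per motif type; NaN if none
    embedded: dict[MotifType, int]
    totals: dict[MotifType, int]
    cross_talk: list[MotifInstance]            # inter-module instances
    unassigned: list[MotifInstance]            # a regulator lacks a module


def embedding_fractions(
    instances: Sequence[MotifInstance], partition: ModulePartition
) -> EmbeddingReport:
    """Classify each instance as module-embedded or inter-module cross-talk.

    Embedding is decided on the regulator pair only (master and local in the
    same module); the target is typically a structural gene outside the
    regulator partition.  Instances with an unassigned regulator are listed
    separately and excluded from the fractions.
    """
    embedded = {"FF": 0, "CFF": 0}
    totals = {"FF": 0, "CFF": 0}
    cross: list[MotifInstance] = []
    unassigned: list[MotifInstance] = []
    for inst in instances:
        ma = partition.module_of(inst.master)
        mb = partition.module_of(inst.local)
        if ma is None or mb is None:
            unassigned.append(inst)
            continue
        totals[inst.motif_type] += 1
        if ma == mb:
            embedded[inst.motif_type] += 1
        else:
            cross.append(inst)
    fractions = {
        mt: (embedded[mt] / totals[mt]) if totals[mt] else float("nan")
        for mt in ("FF", "CFF")
    }
    return EmbeddingReport(
        fractions=fractions,
        embedded=embedded,
        totals=totals,
        cross_talk=cross,
        unassigned=unassigned,
    )


@dataclass
class RegulatorRole:
    regulator: str
    n_master: int
    n_local: int

    @property
    def dominant_role(self) -> str:
        if self.n_master > self.n_local:
            return "master"
        if self.n_local > self.n_master:
            return "local"
        return "mixed"


def regulator_role_profile(
    instances: Sequence[MotifInstance],
) -> dict[str, RegulatorRole]:
    """Count, per regulator, its appearances in the master and local roles.

    In a hierarchical TRN the same factor can be master in one FF and local
    in another; the dominant role over all instances classifies it, with
    exact ties reported as "mixed".
    """
    counts: dict[str, list[int]] = {}
    for inst in instances:
        counts.setdefault(inst.master, [0, 0])[0] += 1
        counts.setdefault(inst.local, [0, 0])[1] += 1
    return {
        reg: RegulatorRole(reg, n_master=c[0], n_local=c[1])
        for reg, c in sorted(counts.items())
    }
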