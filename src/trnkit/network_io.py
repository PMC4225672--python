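"""Reading, validating, filtering and writing regulatory-interaction networks.

A transcriptional regulatory network (TRN) is stored as a directed graph whose
edges point from a regulator (a DNA-binding transcription factor, TF, or a
sigma factor) to a regulated gene.  The on-disk dialect is a tab-separated
edge list with columns ``regulator``, ``target``, ``regulator_class``,
``mode``, ``evidence``; ``#`` starts a comment and a header row is detected by
its reserved column names.

Gene identifiers are case-preserved but compared case-insensitively after
whitespace trimming; sigma-factor spellings such as ``SigA``/``sigA`` are
canonicalized to ``sigA``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from .errors import (
    ClassConflictError,
    EmptyNetworkError,
    ParseError,
    WriteError,
)

logger = logging.getLogger(__name__)

# regulator classes
TF = "TF"
SIGMA = "sigma"
UNKNOWN = "unknown"
TARGET_ONLY = "target"

REGULATOR_CLASSES = {TF, SIGMA, UNKNOWN}

# regulatory modes
ACTIVATION = "activation"
REPRESSION = "repression"
DUAL = "dual"

MODES = {ACTIVATION, REPRESSION, DUAL, UNKNOWN}

# evidence levels
STRONG = "strong"
WEAK = "weak"

EVIDENCE_LEVELS = {STRONG, WEAK, UNKNOWN}

_HEADER_NAMES = {"regulator", "target", "regulator_class", "mode", "evidence"}

_CLASS_ALIASES = {
    "tf": TF,
    "transcription_factor": TF,
    "sigma": SIGMA,
    "sig": SIGMA,
    "σ": SIGMA,
    "sigma_factor": SIGMA,
    "unknown": UNKNOWN,
    "": UNKNOWN,
}

_MODE_ALIASES = {
    "activation": ACTIVATION,
    "activator": ACTIVATION,
    "+": ACTIVATION,
    "repression": REPRESSION,
    "repressor": REPRESSION,
    "-": REPRESSION,
    "dual": DUAL,
    "+/-": DUAL,
    "unknown": UNKNOWN,
    "": UNKNOWN,
}

_EVIDENCE_ALIASES = {
    "strong": STRONG,
    "weak": WEAK,
    "unknown": UNKNOWN,
    "": UNKNOWN,
}

_SIGMA_RE = re.compile(r"^sig([a-z])$", re.IGNORECASE)


def canonical_id(raw: str) -> str:
    """Trim an identifier and canonicalize sigma-factor spellings.

    ``SigA``, ``sigA``, ``SIGA`` all become ``sigA``.  Other identifiers keep
    their original case (comparison happens on the lower-cased key).
    """
    gid = raw.strip()
    m = _SIGMA_RE.match(gid)
    if m:
        return "sig" + m.group(1).upper()
    return gid


def _merge_modes(a: str, b: str) -> str:
    """Reconcile duplicated-edge modes: activation + repression -> dual."""
    if a == b:
        return a
    pair = {a, b}
    if UNKNOWN in pair:
        (other,) = pair - {UNKNOWN}
        return other
    # activation+repression, or anything involving dual
    return DUAL


@dataclass(frozen=True)
class Interaction:
    """One curated regulatory interaction (a row of the edge list)."""

    regulator: str
    target: str
    regulator_class: str = UNKNOWN
    mode: str = UNKNOWN
    evidence: str = UNKNOWN

    def __post_init__(self):
        if not self.regulator or not self.target:
            raise ValueError("regulator and target must be non-empty")
        if self.regulator_class not in REGULATOR_CLASSES:
            raise ValueError(f"bad regulator_class {self.regulator_class!r}")
        if self.mode not in MODES:
            raise ValueError(f"bad mode {self.mode!r}")
        if self.evidence not in EVIDENCE_LEVELS:
            raise ValueError(f"bad evidence {self.evidence!r}")


class RegulatoryNetwork:
    """A directed regulatory network with class-annotated nodes.

    Thin wrapper around a :class:`networkx.DiGraph`; node attribute ``cls``
    is one of ``TF``/``sigma``/``unknown``/``target``, edge attributes are
    ``mode`` and ``evidence``.  At most one edge exists per ordered
    (regulator, target) pair; duplicate rows are collapsed with mode
    reconciliation at construction.  Self-loops (autoregulation) are legal
    and preserved.
    """

    def __init__(self, provenance: str = ""):
        self.graph = nx.DiGraph()
        self.provenance = provenance
        # lower-cased key -> display id, for case-insensitive identity
        self._display: dict[str, str] = {}

    # -- construction ---------------------------------------------------

    def _intern(self, raw: str) -> str:
        gid = canonical_id(raw)
        key = gid.lower()
        if key not in self._display:
            self._display[key] = gid
        return self._display[key]

    def add_interaction(self, it: Interaction) -> None:
        reg = self._intern(it.regulator)
        tgt = self._intern(it.target)

        prev = self.graph.nodes[reg]["cls"] if reg in self.graph else None
        if prev in (None, TARGET_ONLY, UNKNOWN):
            self.graph.add_node(reg, cls=it.regulator_class if it.regulator_class != UNKNOWN else (prev or UNKNOWN))
            if it.regulator_class != UNKNOWN:
                self.graph.nodes[reg]["cls"] = it.regulator_class
            elif prev is None:
                self.graph.nodes[reg]["cls"] = UNKNOWN
        elif it.regulator_class != UNKNOWN and prev != it.regulator_class:
            raise ClassConflictError(
                f"regulator {reg!r} declared both {prev!r} and {it.regulator_class!r}"
            )

        if tgt not in self.graph:
            self.graph.add_node(tgt, cls=TARGET_ONLY)

        if self.graph.has_edge(reg, tgt):
            data = self.graph.edges[reg, tgt]
            data["mode"] = _merge_modes(data["mode"], it.mode)
            # keep the strongest evidence seen for the pair
            order = {STRONG: 2, WEAK: 1, UNKNOWN: 0}
            if order[it.evidence] > order[data["evidence"]]:
                data["evidence"] = it.evidence
        else:
            self.graph.add_edge(reg, tgt, mode=it.mode, evidence=it.evidence)

    # -- queries ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_class(self, node: str) -> str:
        return self.graph.nodes[node]["cls"]

    def regulators(self) -> list[str]:
        """TF and sigma-factor nodes, sorted."""
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d["cls"] in (TF, SIGMA)
        )

    def resolve(self, raw: str) -> str | None:
        """Case-insensitive lookup of an identifier; None if absent."""
        return self._display.get(canonical_id(raw).lower())

    def interactions(self) -> Iterator[Interaction]:
        for u, v, d in sorted(self.graph.edges(data=True)):
            yield Interaction(
                regulator=u,
                target=v,
                regulator_class=self.graph.nodes[u]["cls"]
                if self.graph.nodes[u]["cls"] in REGULATOR_CLASSES
                else UNKNOWN,
                mode=d["mode"],
                evidence=d["evidence"],
            )

    def copy(self) -> "RegulatoryNetwork":
        out = RegulatoryNetwork(provenance=self.provenance)
        out.graph = self.graph.copy()
        out._display = dict(self._display)
        return out

    def undirected_projection(self, drop_self_loops: bool = True) -> nx.Graph:
        """Undirected simple projection: reciprocal edges merged, loops dropped."""
        und = nx.Graph()
        und.add_nodes_from(self.graph.nodes)
        for u, v in self.graph.edges:
            if drop_self_loops and u == v:
                continue
            und.add_edge(u, v)
        return und

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        if set(self.graph.edges) != set(other.graph.edges):
            return False
        for n in self.graph.nodes:
            if self.graph.nodes[n]["cls"] != other.graph.nodes[n]["cls"]:
                return False
        for u, v in self.graph.edges:
            a, b = self.graph.edges[u, v], other.graph.edges[u, v]
            if (a["mode"], a["evidence"]) != (b["mode"], b["evidence"]):
                return False
        return True

    def __repr__(self) -> str:
        return f"<RegulatoryNetwork {self.n_nodes} nodes, {self.n_edges} edges>"


# ---------------------------------------------------------------------------
# parsing


def _parse_enum(value: str, aliases: dict[str, str], what: str, lineno: int) -> str:
    key = value.strip().lower()
    if key not in aliases:
        raise ParseError(f"unrecognized {what} {value!r}", lineno)
    return aliases[key]


def parse_network(path: str | Path, dialect: str = "tsv_edgelist") -> RegulatoryNetwork:
    """Parse a TSV edge list into a validated :class:`RegulatoryNetwork`.

    Each non-comment line needs at least two columns (regulator, target);
    columns three to five are regulator class, regulatory mode and evidence
    strength, all optional.  A header row is auto-detected.  Raw node/edge
    counts are logged after loading.

    Raises
    ------
    EmptyNetworkError
        if the file contains no interactions.
    ParseError
        on a malformed line (carries the line number).
    ClassConflictError
        if one regulator id is declared both TF and sigma.
    """
    if dialect != "tsv_edgelist":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    net = RegulatoryNetwork(provenance=str(path))
    n_rows = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            cols = [c.strip() for c in line.split("\t")]
            if n_rows == 0 and cols[0].lower() in _HEADER_NAMES:
                continue  # header row
            if len(cols) < 2 or not cols[0] or not cols[1]:
                raise ParseError("need at least regulator and target columns", lineno)
            cls = _parse_enum(cols[2], _CLASS_ALIASES, "regulator_class", lineno) if len(cols) > 2 else UNKNOWN
            mode = _parse_enum(cols[3], _MODE_ALIASES, "mode", lineno) if len(cols) > 3 else UNKNOWN
            ev = _parse_enum(cols[4], _EVIDENCE_ALIASES, "evidence", lineno) if len(cols) > 4 else UNKNOWN
            net.add_interaction(
                Interaction(cols[0], cols[1], regulator_class=cls, mode=mode, evidence=ev)
            )
            n_rows += 1
    if n_rows == 0:
        raise EmptyNetworkError(f"{path} contains no interactions")
    logger.info(
        "loaded %s: %d rows -> %d nodes, %d edges",
        path, n_rows, net.n_nodes, net.n_edges,
    )
    return net


# ---------------------------------------------------------------------------
# filtering and projection


def filter_by_evidence(
    net: RegulatoryNetwork, keep: Iterable[str]
) -> RegulatoryNetwork:
    """Restrict to edges whose evidence level is in ``keep``.

    Nodes left with zero degree are dropped.  The input network is not
    modified.  An empty result is legal (logged as a warning).
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep must be a non-empty set of evidence levels")
    bad = keep - EVIDENCE_LEVELS
    if bad:
        raise ValueError(f"unknown evidence levels: {sorted(bad)}")

    out = RegulatoryNetwork(provenance=net.provenance)
    for it in net.interactions():
        if it.evidence in keep:
            out.add_interaction(it)
    if out.n_edges == 0:
        logger.warning("evidence filter %s removed every edge", sorted(keep))
    logger.info(
        "evidence filter %s: %d -> %d edges", sorted(keep), net.n_edges, out.n_edges
    )
    return out


def extract_regulator_subnetwork(
    net: RegulatoryNetwork,
    exclude: Iterable[str] = (),
    keep_isolated: bool = True,
) -> RegulatoryNetwork:
    """Project onto the regulator-only (TF / sigma factor) subnetwork.

    The node set is every TF and sigma factor of ``net`` minus ``exclude``
    (typically the housekeeping factor sigA, whose near-global connectivity
    would fuse everything into one mega-module); the edge set is every edge
    whose source AND target both survive.  Regulators left without edges are
    kept as isolated nodes by default, mirroring the disconnected regulator
    groups seen in curated TRNs.
    """
    excl_keys = set()
    for raw in exclude:
        resolved = net.resolve(raw)
        if resolved is None:
            logger.warning("exclusion id %r not present in network", raw)
        else:
            excl_keys.add(resolved)

    regs = [r for r in net.regulators() if r not in excl_keys]
    reg_set = set(regs)

    out = RegulatoryNetwork(provenance=f"{net.provenance}|regulator-subnetwork")
    for it in net.interactions():
        if it.regulator in reg_set and it.target in reg_set:
            # the target is itself a regulator here; keep its class annotation
            out.add_interaction(it)
            out.graph.nodes[it.target]["cls"] = net.node_class(it.target)
    if keep_isolated:
        for r in regs:
            if r not in out.graph:
                out._intern(r)
                out.graph.add_node(r, cls=net.node_class(r))
    logger.info(
        "regulator subnetwork (excluding %s): %d nodes, %d edges",
        sorted(excl_keys), out.n_nodes, out.n_edges,
    )
    return out


# ---------------------------------------------------------------------------
# writing


def write_network(
    net: RegulatoryNetwork, path: str | Path, format: str = "tsv_edgelist"
) -> None:
    """Serialize a network as the TSV dialect or GraphML.

    Round-trip guarantee (TSV): ``parse_network`` on the written file
    reproduces node set, edge set and annotations exactly.  Isolated nodes
    are written as ``# node:`` comment records so they survive the trip.
    """
    path = Path(path)
    try:
        if format == "tsv_edgelist":
            with open(path, "wt", encoding="utf-8") as fh:
                fh.write("regulator\ttarget\tregulator_class\tmode\tevidence\n")
                for it in net.interactions():
                    fh.write(
                        f"{it.regulator}\t{it.target}\t{it.regulator_class}"
                        f"\t{it.mode}\t{it.evidence}\n"
                    )
                isolated = sorted(
                    n for n in net.graph.nodes if net.graph.degree(n) == 0
                )
                for n in isolated:
                    fh.write(f"# node: {n}\t{net.node_class(n)}\n")
        elif format == "graphml":
            nx.write_graphml(net.graph, path)
        else:
            raise ValueError(f"unknown format {format!r}")
    except OSError as exc:
        raise WriteError(f"cannot write {path}: {exc}") from exc


_NODE_RECORD = re.compile(r"^#\s*node:\s*(\S+)\t?(\S+)?\s*$")


def read_network(path: str | Path) -> RegulatoryNetwork:
    """parse_network plus recovery of isolated-node records written by
    :func:`write_network`."""
    try:
        net = parse_network(path)
    except EmptyNetworkError:
        # a file may legitimately hold node records only (edge-free network)
        net = RegulatoryNetwork(provenance=str(path))
        with open(path, "rt", encoding="utf-8") as fh:
            if not any(_NODE_RECORD.match(ln.strip()) for ln in fh):
                raise
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            m = _NODE_RECORD.match(line.strip())
            if m:
                node = net._intern(m.group(1))
                if node not in net.graph:
                    net.graph.add_node(node, cls=m.group(2) or UNKNOWN)
    return net
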