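"""Degree distributions, clustering coefficients, CCDFs and tail fits.

A scale-free regulatory network has an out-degree distribution P(k) ~ k^-gamma.
Rather than fitting P(k) directly (noisy at large k), the complementary
cumulative distribution CCDF(k) = Pr[K >= k] is fitted by least squares in
log-log space; for a power law its slope is -(gamma - 1), so the implied P(k)
exponent reported alongside the raw slope is ``slope - 1``.  The competing
exponential model is fitted as log10(CCDF) against k, and the model with the
higher coefficient of determination R^2 wins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateDistributionError,
    EmptyNetworkError,
    FitRangeError,
    InsufficientDataError,
)
from .network_io import RegulatoryNetwork

logger = logging.getLogger(__name__)

Direction = Literal["in", "out", "total"]


@dataclass
class DegreeStats:
    """Degree histogram, frequencies, CCDF and clustering-by-degree."""

    direction: Direction
    counts: dict[int, int]            # degree k -> number of nodes
    frequencies: dict[int, float]     # degree k -> fraction of all nodes, P(k)
    ccdf_points: list[tuple[int, float]]   # (k, Pr[K >= k | K >= 1]), k >= 1
    clustering_by_degree: dict[int, float]  # k -> mean local clustering C(k)
    mean_clustering: float
    n_nodes: int


@dataclass
class TailFit:
    """Least-squares straight-line fit to a degree-distribution tail."""

    model: Literal["power_law", "exponential"]
    slope: float
    intercept: float
    r_squared: float
    fit_range: tuple[int, int]
    n_points: int
    reliable: bool = True

    @property
    def implied_pk_exponent(self) -> float | None:
        """P(k) exponent implied by a power-law CCDF slope (slope - 1)."""
        if self.model != "power_law":
            return None
        return self.slope - 1.0


def _degrees(net: RegulatoryNetwork, direction: Direction) -> dict[str, int]:
    g = net.graph
    if direction == "in":
        return dict(g.in_degree())
    if direction == "out":
        return dict(g.out_degree())
    if direction == "total":
        return dict(g.degree())
    raise ValueError(f"unknown direction {direction!r}")


def degree_stats(net: RegulatoryNetwork, direction: Direction = "out") -> DegreeStats:
    """Degree histogram and CCDF in the given direction.

    All nodes enter the histogram denominator, including zero-degree nodes;
    a self-loop contributes one to both the in- and out-degree of its node.
    The CCDF conditions on k >= 1 (log k is undefined at zero).
    """
    if net.n_nodes == 0:
        raise EmptyNetworkError("cannot compute degree stats of an empty network")
    degs = _degrees(net, direction)
    n = len(degs)
    counts: dict[int, int] = {}
    for d in degs.values():
        counts[d] = counts.get(d, 0) + 1
    counts = dict(sorted(counts.items()))
    freqs = {k: c / n for k, c in counts.items()}

    ccdf_points = _ccdf_from_counts(counts) if any(k >= 1 for k in counts) else []

    und = net.undirected_projection()
    local = nx.clustering(und)
    by_deg: dict[int, list[float]] = {}
    for node, c in local.items():
        by_deg.setdefault(degs[node], []).append(c)
    clustering_by_degree = {
        k: float(np.mean(v)) for k, v in sorted(by_deg.items())
    }
    mean_c = float(np.mean(list(local.values()))) if local else 0.0

    return DegreeStats(
        direction=direction,
        counts=counts,
        frequencies=freqs,
        ccdf_points=ccdf_points,
        clustering_by_degree=clustering_by_degree,
        mean_clustering=mean_c,
        n_nodes=n,
    )


def top_regulators(
    net: RegulatoryNetwork, n_top: int = 5
) -> list[dict[str, float | str | int]]:
    """Highest out-degree regulators with their one-step coverage fractions.

    Coverage is reported against two denominators (all nodes, and all nodes
    except the hub itself) because curated-network papers rarely state which
    one they used.
    """
    out = dict(net.graph.out_degree())
    ranked = sorted(out.items(), key=lambda kv: (-kv[1], kv[0]))[:n_top]
    n = net.n_nodes
    return [
        {
            "node": node,
            "out_degree": k,
            "coverage_of_all_nodes": k / n if n else 0.0,
            "coverage_of_other_nodes": k / (n - 1) if n > 1 else 0.0,
        }
        for node, k in ranked
    ]


def mean_clustering(net: RegulatoryNetwork) -> float:
    """Unweighted mean local clustering coefficient.

    Computed on the undirected simple projection (self-loops removed,
    reciprocal edge pairs merged); nodes with projected degree < 2
    contribute 0.
    """
    if net.n_nodes == 0:
        raise EmptyNetworkError("mean clustering of an empty network")
    und = net.undirected_projection()
    return float(nx.average_clustering(und))


def _ccdf_from_counts(counts: dict[int, int]) -> list[tuple[int, float]]:
    ks = sorted(k for k in counts if k >= 1)
    denom = sum(counts[k] for k in ks)
    points = []
    tail = denom
    for k in ks:
        points.append((k, tail / denom))
        tail -= counts[k]
    return points


def ccdf(stats: DegreeStats) -> list[tuple[int, float]]:
    """CCDF pairs (k, fraction of positive-degree nodes with degree >= k)."""
    if not any(k >= 1 for k in stats.counts):
        raise DegenerateDistributionError(
            "all degrees are zero; CCDF undefined"
        )
    return _ccdf_from_counts(stats.counts)


def fit_tail(
    ccdf_points: Sequence[tuple[int, float]],
    model: Literal["power_law", "exponential"] = "power_law",
    k_min: int = 1,
) -> TailFit:
    """Ordinary least-squares fit of the CCDF tail.

    power_law:    log10(CCDF) on log10(k)   (slope = -(gamma - 1))
    exponential:  log10(CCDF) on k

    Points with k < k_min or CCDF == 0 are excluded.  Fewer than three
    distinct k values raises :class:`InsufficientDataError`; exactly three
    is accepted but flagged unreliable only when degenerate.
    """
    pts = [(k, f) for k, f in ccdf_points if k >= k_min and f > 0]
    if len(pts) < 3:
        raise InsufficientDataError(
            f"need >= 3 CCDF points with k >= {k_min}, got {len(pts)}"
        )
    ks = np.array([k for k, _ in pts], dtype=float)
    fs = np.array([f for _, f in pts], dtype=float)
    x = np.log10(ks) if model == "power_law" else ks
    y = np.log10(fs)
    if np.ptp(x) == 0:
        raise InsufficientDataError("all fit abscissae identical")
    res = sps.linregress(x, y)
    r2 = float(res.rvalue**2)
    return TailFit(
        model=model,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        fit_range=(int(ks.min()), int(ks.max())),
        n_points=len(pts),
        reliable=len(pts) >= 3,
    )


def compare_models(pl: TailFit, ex: TailFit) -> str:
    """Pick the better-supported tail model by R^2; ties go to power_law."""
    if pl.model != "power_law" or ex.model != "exponential":
        raise FitRangeError("expected one power_law and one exponential fit")
    if pl.fit_range != ex.fit_range or pl.n_points != ex.n_points:
        raise FitRangeError(
            f"fits cover different point sets: {pl.fit_range}/{pl.n_points} vs "
            f"{ex.fit_range}/{ex.n_points}"
        )
    if math.isclose(pl.r_squared, ex.r_squared, rel_tol=0, abs_tol=1e-12):
        logger.warning("power-law and exponential fits tie on R^2; choosing power_law")
        return "power_law"
    return "power_law" if pl.r_squared > ex.r_squared else "exponential"
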