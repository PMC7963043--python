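"""Shortest-path trees and cost-weighted betweenness chokepoint profiles.

Communication between two protein regions is read off the coupling graph by
reconstructing, for every ordered residue pair (s ∈ X, t ∈ Y), the cheapest
path in the pruned adjacency A. Each interior residue of that path accrues a
weight (by default 1/G_st, so strongly coupled pairs — cheap paths — count
more). Residues accumulating a large share of this traffic are chokepoints:
perturbing them is expected to disrupt much of the X↔Y communication.

Ties between equal-cost paths are broken deterministically: walking back from
the target, the predecessor with the smallest residue index is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .coupling_graph import CouplingGraph
from .structure_io import RegionSet

__all__ = [
    "PathTree",
    "BetweennessProfile",
    "shortest_path_tree",
    "betweenness",
    "threshold_counts",
    "WEIGHT_FUNCTIONS",
]

_REL_TOL = 1e-12


@dataclass
class PathTree:
    """Single-source tree of tie-broken cheapest paths."""

    source: int
    predecessors: np.ndarray  # -1 marks source/unreachable
    costs: np.ndarray  # +inf marks unreachable

    def path_to(self, target: int) -> list[int]:
        """Node sequence source→target; empty list if unreachable."""
        if not np.isfinite(self.costs[target]):
            return []
        path = [target]
        while path[-1] != self.source:
            path.append(int(self.predecessors[path[-1]]))
        return path[::-1]


@dataclass
class BetweennessProfile:
    """Per-residue χ between a source and a target region."""

    chi: np.ndarray
    source_region: str
    target_region: str
    normalization: float = 0.0  # max χ mapped to 100 %
    labels: list[str] = field(default_factory=list)

    @property
    def percent(self) -> np.ndarray:
        if self.normalization == 0:
            return np.zeros_like(self.chi)
        return 100.0 * self.chi / self.normalization


def _tie_broken_tree(adjacency: np.ndarray, costs: np.ndarray, source: int) -> np.ndarray:
    """Predecessor array realizing the documented smallest-index tie-break.

    A node's predecessor is the smallest-index neighbour u with
    cost[u] + A[u, v] == cost[v] (to relative tolerance). Because every
    such u lies on some cheapest path, the recursion yields, among all
    cheapest s→t paths, the one whose predecessors (read backwards from t)
    are minimal.
    """
    n = adjacency.shape[0]
    pred = np.full(n, -1, dtype=int)
    has_edge = adjacency > 0
    for v in range(n):
        if v == source or not np.isfinite(costs[v]):
            continue
        through = costs + adjacency[:, v]
        tol = _REL_TOL * max(1.0, abs(costs[v]))
        candidates = np.flatnonzero(has_edge[:, v] & (np.abs(through - costs[v]) <= tol))
        if candidates.size == 0:  # numerical guard; cannot occur for exact dijkstra
            raise RuntimeError(f"no optimal predecessor found for node {v}")
        pred[v] = int(candidates[0])
    return pred


def shortest_path_tree(graph: CouplingGraph, source: int) -> PathTree:
    """Tie-broken cheapest-path tree from ``source`` over the pruned adjacency."""
    n = graph.n
    if not 0 <= source < n:
        raise ValueError(f"source {source} out of range 0..{n - 1}")
    costs = dijkstra(csr_matrix(graph.A), directed=False, indices=source)
    pred = _tie_broken_tree(graph.A, costs, source)
    return PathTree(source=source, predecessors=pred, costs=costs)


def _inv_geodesic(cost: float, graph: CouplingGraph, s: int, t: int) -> float:
    return 1.0 / cost


def _coupling_weight(cost: float, graph: CouplingGraph, s: int, t: int) -> float:
    return graph.params.a_thresh * graph.absC_clipped[s, t] / cost


def _unit_weight(cost: float, graph: CouplingGraph, s: int, t: int) -> float:
    return 1.0


#: pluggable per-pair weights: strongly coupled pairs dominate under the default
WEIGHT_FUNCTIONS: dict[str, Callable] = {
    "inv_geodesic": _inv_geodesic,
    "coupling": _coupling_weight,
    "unit": _unit_weight,
}


def betweenness(
    graph: CouplingGraph,
    x: RegionSet,
    y: RegionSet | str = "all",
    weight: str | Callable = "inv_geodesic",
) -> BetweennessProfile:
    """Cost-weighted betweenness χ between regions x and y.

    For each ordered pair (s ∈ x, t ∈ y, s ≠ t) the unique tie-broken
    cheapest path is reconstructed; every interior node accrues the pair
    weight (default 1/G_st). Endpoints accrue nothing. Raises if no (s, t)
    pair is reachable.
    """
    n = graph.n
    xi = _indices(x, n)
    if isinstance(y, str) and y == "all":
        yi = np.arange(n)
        y_name = "all"
    else:
        yi = _indices(y, n)
        y_name = y.name
    weight_fn = WEIGHT_FUNCTIONS[weight] if isinstance(weight, str) else weight

    chi = np.zeros(n)
    reachable_pairs = 0
    for s in xi:
        tree = shortest_path_tree(graph, int(s))
        for t in yi:
            t = int(t)
            if t == s or not np.isfinite(tree.costs[t]) or tree.costs[t] == 0:
                continue
            reachable_pairs += 1
            w = weight_fn(float(tree.costs[t]), graph, int(s), t)
            node = int(tree.predecessors[t])
            while node != s:
                chi[node] += w
                node = int(tree.predecessors[node])
    if reachable_pairs == 0:
        raise ValueError(f"no reachable pair between regions {x.name!r} and {y_name!r}")
    return BetweennessProfile(
        chi=chi, source_region=x.name, target_region=y_name,
        normalization=float(chi.max()), labels=list(graph.labels),
    )


def threshold_counts(profile: BetweennessProfile, windows=(25.0, 50.0, 75.0)) -> dict[float, int]:
    """How many residues fall within p % of the maximum χ, per window p.

    "Within p %" means χ ≥ (100 − p) % of the maximum, so counts are
    non-decreasing in p.
    """
    if profile.chi.size == 0:
        raise ValueError("empty profile")
    for w in windows:
        if not 0.0 < w <= 100.0:
            raise ValueError(f"window {w} outside (0, 100]")
    top = profile.chi.max()
    return {float(w): int(np.sum(profile.chi >= (100.0 - w) / 100.0 * top)) for w in windows}


def _indices(region: RegionSet, n: int) -> np.ndarray:
    if region.resolved_indices is None or region.resolved_indices.size == 0:
        raise ValueError(f"region {region.name!r} empty or unresolved")
    idx = region.resolved_indices
    if idx.min() < 0 or idx.max() >= n:
        raise ValueError(f"region {region.name!r} indices outside graph of size {n}")
    return idx
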