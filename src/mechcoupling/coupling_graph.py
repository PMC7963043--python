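"""Pruned correlation graph, geodesics, and the mechanical-coupling matrix.

The normalized covariance C is turned into an undirected weighted graph whose
edge lengths are A_ij = 1 − |C_ij| (short edge = strong coupling). Edges are
kept only when the correlation is above the noise floor μ_|C| + σ_|C| AND the
two Cα atoms are within D_cut of each other, so every edge is a physically
plausible direct contact with non-trivial correlation. The geodesic matrix G
accumulates edge lengths along cheapest paths; the mechanical coupling

    M_ij = A_thresh · |C_ij| / G_ij

is large only when residues i and j both move together (|C| large) and are
joined by an efficient pathway (G small).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import pdist, squareform

from .enm import CovarianceMatrix
from .structure_io import RegionSet, ResidueMap, Structure

__all__ = [
    "PruningParams",
    "PruningStats",
    "CouplingGraph",
    "build_coupling_graph",
    "geodesic_matrix",
    "mechanical_coupling",
    "region_max_coupling",
    "matrix_difference",
    "min_connecting_cutoff",
]


@dataclass(frozen=True)
class PruningParams:
    """Edge-pruning constants: contact cutoff and correlation clipping."""

    d_cut: float = 11.0
    c_thresh: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.c_thresh < 1.0:
            raise ValueError("c_thresh must lie in (0, 1)")
        if self.d_cut <= 0:
            raise ValueError("d_cut must be positive")

    @property
    def a_thresh(self) -> float:
        """Shortest admissible edge length, 1 − c_thresh."""
        return 1.0 - self.c_thresh


@dataclass
class PruningStats:
    """Mean/s.d. of |C| off-diagonal entries, recomputed per covariance."""

    mu_absC: float
    sigma_absC: float


@dataclass
class CouplingGraph:
    """Adjacency A, Cα distances D, geodesics G, mechanical coupling M."""

    A: np.ndarray
    D: np.ndarray
    absC_clipped: np.ndarray
    params: PruningParams
    stats: PruningStats
    labels: list[str] = field(default_factory=list)
    G: np.ndarray | None = None
    M: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.A.shape[0]


def build_coupling_graph(
    cov: CovarianceMatrix, structure: Structure, params: PruningParams | None = None
) -> CouplingGraph:
    """Construct the pruned adjacency matrix from covariance plus geometry.

    |C_ij| above c_thresh is clipped to c_thresh (numerical stability: avoids
    near-zero edge lengths inside secondary-structure elements). An edge
    survives only if |C_ij| ≥ μ_|C| + σ_|C| (statistics over off-diagonal
    |C|, unclipped) and D_ij ≤ d_cut. Diagonal carries no edge.
    """
    params = params or PruningParams()
    c = np.asarray(cov.normalized, dtype=float)
    n = c.shape[0]
    if len(structure) != n:
        raise ValueError(f"covariance is {n}×{n} but structure has {len(structure)} residues")
    dist = squareform(pdist(structure.coords))

    abs_c = np.abs(c)
    off = ~np.eye(n, dtype=bool)
    mu = float(abs_c[off].mean())
    sigma = float(abs_c[off].std())
    clipped = np.minimum(abs_c, params.c_thresh)

    keep = off & (abs_c >= mu + sigma) & (dist <= params.d_cut)
    adjacency = np.where(keep, 1.0 - clipped, 0.0)
    return CouplingGraph(
        A=adjacency, D=dist, absC_clipped=clipped, params=params,
        stats=PruningStats(mu_absC=mu, sigma_absC=sigma), labels=structure.labels,
    )


def geodesic_matrix(graph: CouplingGraph) -> CouplingGraph:
    """Fill G with all-pairs cheapest-path costs over the pruned adjacency.

    Unreachable pairs are +inf; G_ii = 0. Distances come from Dijkstra on
    the sparse edge set; path reconstruction uses the deterministic trees of
    :mod:`mechcoupling.pathways`.
    """
    sparse = csr_matrix(graph.A)
    graph.G = dijkstra(sparse, directed=False)
    return graph


def mechanical_coupling(graph: CouplingGraph) -> CouplingGraph:
    """Fill M = A_thresh·|C|/G (clipped |C|); 0 on diagonal and across gaps."""
    if graph.G is None:
        raise ValueError("geodesic matrix G not computed; call geodesic_matrix first")
    with np.errstate(divide="ignore", invalid="ignore"):
        m = graph.params.a_thresh * graph.absC_clipped / graph.G
    m[~np.isfinite(m)] = 0.0
    np.fill_diagonal(m, 0.0)
    graph.M = m
    return graph


def region_max_coupling(graph: CouplingGraph, x: RegionSet, y: RegionSet) -> np.ndarray:
    """For each residue in x, its maximum M to any residue of y.

    The diagonal is excluded, so a residue shared by both regions does not
    couple to itself.
    """
    if graph.M is None:
        raise ValueError("M not computed")
    xi = _resolved(x)
    yi = _resolved(y)
    sub = graph.M[np.ix_(xi, yi)].copy()
    return sub.max(axis=1)


def matrix_difference(
    g1: CouplingGraph,
    g2: CouplingGraph,
    residue_map: ResidueMap | None = None,
    region_pairs: list[tuple[RegionSet, RegionSet]] | None = None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Signed coupling difference M(g1) − M(g2) on common residues.

    ``residue_map`` pairs g1's residues (A side) with g2's (B side); omit it
    when both graphs share one structure. Returns the difference matrix and
    per-region-pair block means (regions indexed into the common set).
    """
    if g1.M is None or g2.M is None:
        raise ValueError("both graphs need M computed")
    if residue_map is None:
        if g1.n != g2.n:
            raise ValueError("graphs differ in size; provide a residue map")
        m1, m2 = g1.M, g2.M
    else:
        ai, bi = residue_map.a_indices, residue_map.b_indices
        if ai.size == 0:
            raise ValueError("empty residue overlap")
        m1 = g1.M[np.ix_(ai, ai)]
        m2 = g2.M[np.ix_(bi, bi)]
    diff = m1 - m2
    summaries: dict[str, float] = {}
    for rx, ry in region_pairs or []:
        block = diff[np.ix_(_resolved(rx), _resolved(ry))]
        summaries[f"{rx.name}|{ry.name}"] = float(block.mean())
    return diff, summaries


def min_connecting_cutoff(structure: Structure, resolution: float = 0.1) -> float:
    """Smallest contact cutoff (Å) at which the Cα distance graph is connected.

    Diagnostic for choosing d_cut: the minimax edge over a minimum spanning
    tree of the Euclidean distance matrix, rounded up to ``resolution``.
    """
    from scipy.sparse.csgraph import minimum_spanning_tree

    dist = squareform(pdist(structure.coords))
    mst = minimum_spanning_tree(csr_matrix(dist)).toarray()
    longest = float(mst.max())
    return float(np.ceil(longest / resolution) * resolution)


def _resolved(region: RegionSet) -> np.ndarray:
    if region.resolved_indices is None or region.resolved_indices.size == 0:
        raise ValueError(f"region {region.name!r} is empty or unresolved")
    return region.resolved_indices
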