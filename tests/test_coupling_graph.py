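"""Pruned adjacency, geodesics and mechanical coupling against brute-force oracles."""

import networkx as nx
import numpy as np
import pytest

from mechcoupling.coupling_graph import (
    PruningParams,
    build_coupling_graph,
    geodesic_matrix,
    matrix_difference,
    mechanical_coupling,
    min_connecting_cutoff,
    region_max_coupling,
)
from mechcoupling.structure_io import RegionSet

from conftest import graph_from_adjacency, random_cloud, random_normalized_covariance


def brute_force_adjacency(c, dist, params):
    """Loop-by-loop re-application of the clipping and pruning rules."""
    n = c.shape[0]
    abs_c = np.abs(c)
    off = [abs_c[i, j] for i in range(n) for j in range(n) if i != j]
    mu, sigma = np.mean(off), np.std(off)
    a = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if abs_c[i, j] < mu + sigma or dist[i, j] > params.d_cut:
                continue
            a[i, j] = 1.0 - min(abs_c[i, j], params.c_thresh)
    return a


class TestBuildCouplingGraph:
    def test_clipping_arithmetic(self):
        c = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        from mechcoupling.enm import CovarianceMatrix

        cov = CovarianceMatrix(raw=c, normalized=c, msf=np.ones(3))
        s = random_cloud(3, seed=0, box=5.0)
        g = build_coupling_graph(cov, s, PruningParams())
        # perfectly correlated adjacent pair: |C| clipped to 0.95, edge 0.05
        assert g.A[0, 1] == pytest.approx(0.05)

    def test_distance_cutoff_kills_edge(self):
        from conftest import structure_from_coords
        from mechcoupling.enm import CovarianceMatrix

        coords = np.array([[0.0, 0, 0], [12.0, 0, 0], [3.0, 0, 0], [6.0, 3, 0]])
        c = np.full((4, 4), 0.2)
        c[0, 1] = c[1, 0] = 0.99  # strong but 12 Å apart
        c[0, 2] = c[2, 0] = 0.99  # strong and 3 Å apart
        np.fill_diagonal(c, 1.0)
        cov = CovarianceMatrix(raw=c, normalized=c, msf=np.ones(4))
        g = build_coupling_graph(cov, structure_from_coords(coords), PruningParams(d_cut=11.0))
        assert g.A[0, 1] == 0.0  # beyond the 11 Å contact cutoff
        assert g.A[0, 2] > 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_filter(self, seed):
        cov = random_normalized_covariance(10, seed)
        s = random_cloud(10, seed=seed + 100, box=9.0)
        params = PruningParams()
        g = build_coupling_graph(cov, s, params)
        oracle = brute_force_adjacency(cov.normalized, g.D, params)
        np.testing.assert_allclose(g.A, oracle, atol=1e-12)

    def test_edge_lengths_within_declared_band(self):
        cov = random_normalized_covariance(15, seed=3)
        g = build_coupling_graph(cov, random_cloud(15, seed=4, box=8.0))
        edges = g.A[g.A > 0]
        assert edges.size > 0
        assert np.all(edges >= g.params.a_thresh - 1e-12)
        assert np.all(edges < 1.0)

    def test_size_mismatch_rejected(self):
        cov = random_normalized_covariance(6, seed=5)
        with pytest.raises(ValueError, match="residues"):
            build_coupling_graph(cov, random_cloud(7, seed=6))


class TestGeodesics:
    def test_direct_cheapest_edge(self):
        a = np.array([[0.0, 0.1, 0.0], [0.1, 0.0, 0.1], [0.0, 0.1, 0.0]])
        g = geodesic_matrix(graph_from_adjacency(a))
        assert g.G[0, 1] == pytest.approx(0.1)
        assert g.G[0, 2] == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_floyd_warshall_oracle(self, seed):
        cov = random_normalized_covariance(12, seed)
        graph = geodesic_matrix(
            build_coupling_graph(cov, random_cloud(12, seed=seed + 50, box=8.0))
        )
        nxg = nx.from_numpy_array(graph.A)
        oracle = nx.floyd_warshall_numpy(nxg, weight="weight")
        np.testing.assert_allclose(graph.G, oracle, atol=1e-10)

    def test_disconnected_pairs_infinite(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 0.2
        a[2, 3] = a[3, 2] = 0.3
        g = geodesic_matrix(graph_from_adjacency(a))
        assert np.isinf(g.G[0, 2])
        assert g.G[0, 1] == pytest.approx(0.2)

    def test_triangle_inequality(self):
        cov = random_normalized_covariance(12, seed=9)
        g = geodesic_matrix(build_coupling_graph(cov, random_cloud(12, seed=59, box=8.0)))
        finite = np.isfinite(g.G)
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    if finite[i, j] and finite[j, k] and finite[i, k]:
                        assert g.G[i, k] <= g.G[i, j] + g.G[j, k] + 1e-9


class TestMechanicalCoupling:
    def test_formula_arithmetic_at_clip(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.05
        a[1, 2] = a[2, 1] = 0.05
        g = mechanical_coupling(geodesic_matrix(graph_from_adjacency(a)))
        # clipped |C| = 0.95 over geodesic 0.05: M = 0.05·0.95/0.05 = 0.95
        assert g.M[0, 1] == pytest.approx(0.95)

    def test_symmetric_zero_diagonal_disconnected_zero(self):
        cov = random_normalized_covariance(10, seed=11)
        g = mechanical_coupling(
            geodesic_matrix(build_coupling_graph(cov, random_cloud(10, seed=61, box=8.0)))
        )
        np.testing.assert_allclose(g.M, g.M.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(g.M), 0.0)
        assert np.all(g.M[np.isinf(g.G)] == 0.0)

    def test_requires_geodesics(self):
        cov = random_normalized_covariance(5, seed=12)
        g = build_coupling_graph(cov, random_cloud(5, seed=62, box=8.0))
        with pytest.raises(ValueError, match="geodesic"):
            mechanical_coupling(g)


class TestRegionMaxCoupling:
    def test_matches_brute_force_submatrix_max(self):
        rng = np.random.default_rng(13)
        m = rng.uniform(0, 1, (8, 8))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        g = graph_from_adjacency(np.zeros((8, 8)))
        g.G = np.ones((8, 8))
        g.M = m
        x = RegionSet.from_indices("x", [0, 2, 4])
        y = RegionSet.from_indices("y", [1, 3, 5, 7])
        profile = region_max_coupling(g, x, y)
        oracle = [max(m[i, j] for j in [1, 3, 5, 7]) for i in [0, 2, 4]]
        np.testing.assert_allclose(profile, oracle)

    def test_single_residue_self_pair_is_zero(self):
        g = graph_from_adjacency(np.zeros((4, 4)))
        g.G = np.ones((4, 4))
        g.M = np.ones((4, 4)) - np.eye(4)
        r = RegionSet.from_indices("i", [2])
        assert region_max_coupling(g, r, r)[0] == 0.0

    def test_empty_region_rejected(self):
        g = graph_from_adjacency(np.zeros((4, 4)))
        g.M = np.zeros((4, 4))
        with pytest.raises(ValueError, match="empty"):
            region_max_coupling(g, RegionSet(name="void"), RegionSet.from_indices("y", [0]))


class TestMatrixDifference:
    def test_identity_gives_zero(self):
        cov = random_normalized_covariance(8, seed=14)
        g = mechanical_coupling(
            geodesic_matrix(build_coupling_graph(cov, random_cloud(8, seed=64, box=8.0)))
        )
        diff, _ = matrix_difference(g, g)
        np.testing.assert_allclose(diff, 0.0)

    def test_block_means_match_hand_computation(self):
        g1 = graph_from_adjacency(np.zeros((4, 4)))
        g2 = graph_from_adjacency(np.zeros((4, 4)))
        g1.M = np.arange(16, dtype=float).reshape(4, 4)
        g2.M = np.ones((4, 4))
        x = RegionSet.from_indices("x", [0, 1])
        y = RegionSet.from_indices("y", [2, 3])
        diff, sums = matrix_difference(g1, g2, region_pairs=[(x, y)])
        # block rows 0-1 × cols 2-3 of (g1.M − 1): (1,2,5,6) → mean 3.5
        assert sums["x|y"] == pytest.approx(3.5)


def test_min_connecting_cutoff_bounds_connectivity():
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial.distance import pdist, squareform

    s = random_cloud(20, seed=15, box=20.0)
    c = min_connecting_cutoff(s)
    dist = squareform(pdist(s.coords))

    def n_components(cut):
        contact = (dist <= cut) & ~np.eye(20, dtype=bool)
        return connected_components(csr_matrix(contact), directed=False)[0]

    assert n_components(c) == 1
    assert n_components(c - 0.2) > 1
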