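"""Shared fixtures: small bead structures and random coupling graphs."""

from __future__ import annotations

import numpy as np
import pytest

from mechcoupling.coupling_graph import CouplingGraph, PruningParams, PruningStats
from mechcoupling.enm import CovarianceMatrix
from mechcoupling.structure_io import Residue, Structure


def structure_from_coords(coords, chain: str = "A", source_id: str = "toy") -> Structure:
    """Wrap an N×3 coordinate array as a single-chain Cα structure."""
    return Structure(
        residues=[
            Residue(chain, i + 1, " ", "GLY", tuple(float(c) for c in xyz))
            for i, xyz in enumerate(np.asarray(coords, dtype=float))
        ],
        source_id=source_id,
    )


def random_cloud(n: int, seed: int, box: float = 12.0) -> Structure:
    """Random bead cloud inside a box small enough to be fully connected."""
    rng = np.random.default_rng(seed)
    return structure_from_coords(rng.uniform(0.0, box, (n, 3)), source_id=f"cloud{seed}")


def random_normalized_covariance(n: int, seed: int) -> CovarianceMatrix:
    """Symmetric unit-diagonal matrix with entries in (−1, 1), plus a raw part."""
    rng = np.random.default_rng(seed)
    c = rng.uniform(-1.0, 1.0, (n, n))
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    msf = rng.uniform(0.5, 2.0, n)
    raw = c * np.sqrt(np.outer(msf, msf))
    return CovarianceMatrix(raw=raw, normalized=c, msf=msf)


def graph_from_adjacency(adjacency, coords=None, params: PruningParams | None = None) -> CouplingGraph:
    """CouplingGraph wrapper for handcrafted edge-length matrices."""
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    params = params or PruningParams()
    clipped = np.where(a > 0, 1.0 - a, 0.0)
    d = np.zeros((n, n)) if coords is None else None
    if coords is not None:
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(np.asarray(coords, dtype=float)))
    return CouplingGraph(
        A=a, D=d, absC_clipped=clipped, params=params,
        stats=PruningStats(mu_absC=0.0, sigma_absC=0.0),
        labels=[f"A:{i + 1}" for i in range(n)],
    )


@pytest.fixture(scope="session")
def hinge():
    """Default two-domain hinge fixture with its ANM, shared across tests."""
    from mechcoupling import HingeModelSpec, build_anm, make_hinge_structure

    structure, linker_idx, regions = make_hinge_structure(HingeModelSpec(seed=11))
    model = build_anm(structure)
    return structure, linker_idx, regions, model


THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.000  10.500  10.000  1.00  0.00           C
ATOM      3  CA  GLY A   2      14.500  11.000  10.200  1.00  0.00           C
ATOM      4  O   GLY A   2      15.000  11.500  10.000  1.00  0.00           O
ATOM      5  CA ASER A   3      18.000  12.000  10.500  0.60  0.00           C
ATOM      6  CA BSER A   3      18.200  12.100  10.600  0.40  0.00           C
HETATM    7 FE    FE A 900      20.000  20.000  20.000  1.00  0.00          FE
END
"""
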