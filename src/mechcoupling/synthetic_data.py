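"""Synthetic fixtures with known ground truth for the coupling pipeline.

Three generators cover the pipeline's inputs:

* a two-domain "hinge" bead structure — two jittered cubic lattices joined by
  a single-strand linker, so every inter-domain communication path must
  traverse known linker residues (planted chokepoints);
* rigid-body perturbed copies of a structure, so the displacement vector and
  recovered superposition transform are known exactly;
* peptide uptake tables with planted correlation blocks plus Gaussian noise,
  so cluster recovery can be scored against truth.

Every generator is a pure function of its spec (including the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .hdx_analysis import REFERENCE_HOURS, UptakeTable
from .structure_io import RegionSet, Residue, Structure

__all__ = [
    "HingeModelSpec",
    "PlantedHDXSpec",
    "make_hinge_structure",
    "perturb_rigid",
    "make_planted_hdx",
]


@dataclass(frozen=True)
class HingeModelSpec:
    """Geometry of the two-domain hinge fixture.

    ``domain_separation`` is the face-to-face gap (Å) bridged by the linker;
    the default spaces linker beads exactly ``bead_spacing`` apart. Bead
    spacing defaults to the Cα virtual-bond length, 3.8 Å. Keep the linker
    short enough that its beads still contact the domain faces at the ENM
    cutoff: a long single-strand linker has only collinear springs at its
    middle, which makes transverse motion free and breaks the network's
    six-rigid-body-mode spectrum.
    """

    n_per_domain: int = 64
    linker_length: int = 4
    bead_spacing: float = 3.8
    domain_separation: float | None = None
    jitter: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_domain < 2 or self.linker_length < 2:
            raise ValueError("domain and linker sizes must be ≥ 2")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")

    @property
    def gap(self) -> float:
        if self.domain_separation is not None:
            return self.domain_separation
        return (self.linker_length + 1) * self.bead_spacing


def _lattice(n: int, spacing: float) -> np.ndarray:
    """First n points of a cubic lattice, centred at the origin."""
    side = math.ceil(n ** (1.0 / 3.0))
    pts = np.array(
        [(x, y, z) for x in range(side) for y in range(side) for z in range(side)][:n],
        dtype=float,
    )
    return (pts - pts.mean(axis=0)) * spacing


def make_hinge_structure(
    spec: HingeModelSpec, connectivity_cutoff: float = 15.0
) -> tuple[Structure, np.ndarray, dict[str, RegionSet]]:
    """Two compact domains joined by a single-strand linker.

    Returns (structure, linker residue indices, regions) with regions
    "domain_a", "domain_b", "linker". Chains A/L/B carry the three parts.
    Fails fast if the geometry disconnects the contact graph at
    ``connectivity_cutoff`` or lets the domains touch within it (which would
    bypass the planted bottleneck), suggesting a workable spacing.
    """
    rng = np.random.default_rng(spec.seed)
    dom = _lattice(spec.n_per_domain, spec.bead_spacing)
    half_width = dom[:, 0].max() - dom[:, 0].min()

    a = dom + rng.normal(0.0, spec.jitter, dom.shape)
    b = dom + rng.normal(0.0, spec.jitter, dom.shape)
    # faces of A and B sit at ±gap/2 around the origin
    a = a - [a[:, 0].max() + spec.gap / 2.0, 0.0, 0.0]
    b = b - [b[:, 0].min() - spec.gap / 2.0, 0.0, 0.0]
    xs = np.linspace(-spec.gap / 2.0, spec.gap / 2.0, spec.linker_length + 2)[1:-1]
    # helical strand: a straight linker leaves domain torsion about its axis
    # nearly free, splitting off a spurious 7th soft mode; winding the beads
    # off-axis gives the torsion a lever arm
    theta = np.arange(spec.linker_length) * np.deg2rad(120.0)
    radius = 0.8 * spec.bead_spacing
    linker = np.column_stack([xs, radius * np.cos(theta), radius * np.sin(theta)])
    linker = linker + rng.normal(0.0, spec.jitter, linker.shape)

    coords = np.vstack([a, linker, b])
    residues = []
    for i, xyz in enumerate(coords):
        if i < spec.n_per_domain:
            chain, num = "A", i + 1
        elif i < spec.n_per_domain + spec.linker_length:
            chain, num = "L", i - spec.n_per_domain + 1
        else:
            chain, num = "B", i - spec.n_per_domain - spec.linker_length + 1
        residues.append(Residue(chain, num, " ", "GLY", tuple(float(c) for c in xyz)))
    structure = Structure(residues=residues, source_id=f"hinge-seed{spec.seed}")

    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    dist = squareform(pdist(coords))
    contact = (dist <= connectivity_cutoff) & ~np.eye(len(coords), dtype=bool)
    n_comp, _ = connected_components(csr_matrix(contact), directed=False)
    if n_comp > 1:
        gap_step = spec.gap / (spec.linker_length + 1)
        raise ValueError(
            f"contact graph disconnected at {connectivity_cutoff} Å ({n_comp} components); "
            f"linker beads are {gap_step:.1f} Å apart — shorten bead_spacing or lengthen the linker"
        )
    na, nl = spec.n_per_domain, spec.linker_length
    cross = dist[:na, na + nl :]
    if cross.min() <= connectivity_cutoff:
        raise ValueError(
            f"domains touch at {cross.min():.1f} Å, within the {connectivity_cutoff} Å cutoff; "
            f"increase domain_separation beyond {connectivity_cutoff + 2 * spec.jitter:.1f} Å"
        )

    linker_idx = np.arange(na, na + nl)
    regions = {
        "domain_a": RegionSet.from_indices("domain_a", range(na)),
        "domain_b": RegionSet.from_indices("domain_b", range(na + nl, na + nl + spec.n_per_domain)),
        "linker": RegionSet.from_indices("linker", linker_idx),
    }
    return structure, linker_idx, regions


def perturb_rigid(
    structure: Structure,
    region: RegionSet,
    rotation_deg: float = 0.0,
    translation=(0.0, 0.0, 0.0),
    axis=(0.0, 0.0, 1.0),
) -> Structure:
    """Rigidly move one region of a structure; the remainder is untouched.

    The region is rotated by ``rotation_deg`` about ``axis`` through its own
    centroid, then shifted by ``translation`` (Å). Internal distances within
    the region are preserved exactly (up to floating point).
    """
    if region.resolved_indices is None or region.resolved_indices.size == 0:
        raise ValueError(f"region {region.name!r} empty or unresolved")
    idx = set(int(i) for i in region.resolved_indices)
    coords = structure.coords
    sub = coords[sorted(idx)]
    centroid = sub.mean(axis=0)
    rot = Rotation.from_rotvec(np.deg2rad(rotation_deg) * np.asarray(axis, float) / np.linalg.norm(axis))
    moved = (sub - centroid) @ rot.as_matrix().T + centroid + np.asarray(translation, float)

    new_residues = []
    moved_iter = iter(moved)
    for i, r in enumerate(structure.residues):
        if i in idx:
            xyz = next(moved_iter)
            new_residues.append(Residue(r.chain_id, r.resnum, r.icode, r.resname, tuple(float(c) for c in xyz)))
        else:
            new_residues.append(r)
    return Structure(residues=new_residues, source_id=structure.source_id + "-perturbed")


@dataclass(frozen=True)
class PlantedHDXSpec:
    """Planted-block uptake table: block structure, means, noise, seed.

    ``block_means`` are the 1-hour %D levels of each block; blocks named in
    ``anti_block_pairs`` (index pairs) get mirrored temporal profiles, i.e.
    their uptake differences anti-correlate across peptide pairs.
    """

    block_sizes: tuple = (8, 8)
    block_means: tuple = (30.0, 70.0)
    anti_block_pairs: tuple = ()
    noise_sd: float = 0.0
    timepoints: tuple = (0.25, 1.0, 4.0, REFERENCE_HOURS)
    d_max: float = 10.0
    condition: str = "planted"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_sizes) != len(self.block_means):
            raise ValueError("one mean per block required")
        if any(not 0.0 <= m <= 100.0 for m in self.block_means):
            raise ValueError("block means must lie in [0, 100] %D")
        if REFERENCE_HOURS not in self.timepoints:
            raise ValueError(f"timepoints must include the {REFERENCE_HOURS} h reference")

    @property
    def n_peptides(self) -> int:
        return int(sum(self.block_sizes))


def make_planted_hdx(spec: PlantedHDXSpec) -> tuple[UptakeTable, np.ndarray]:
    """Uptake table with planted correlation blocks; returns (table, labels).

    Peptides within a block share one exchange profile (plus i.i.d. Gaussian
    noise of sd ``noise_sd`` %D); anti-paired blocks get mirrored profiles
    (100 − %D) at sub-reference timepoints. %D is clipped to [0, 100] and
    converted to fractional deuterium counts against ``d_max``.
    """
    rng = np.random.default_rng(spec.seed)
    tps = np.asarray(spec.timepoints, dtype=float)
    sub = tps < REFERENCE_HOURS

    # single-exponential exchange, rate fixed so %D(1 h) equals the block mean
    def curve(mean: float) -> np.ndarray:
        if mean >= 100.0:
            return np.full_like(tps, 100.0)
        rate = -np.log1p(-mean / 100.0)  # per hour
        return 100.0 * (1.0 - np.exp(-rate * tps))

    profiles = np.stack([curve(m) for m in spec.block_means])
    profiles[:, ~sub] = 100.0  # full exchange at the reference point
    mirrored = set()
    for i, j in spec.anti_block_pairs:
        profiles[j, sub] = 100.0 - profiles[i, sub]
        mirrored.add(int(j))

    labels = np.repeat(np.arange(len(spec.block_sizes)), spec.block_sizes)
    pct = profiles[labels]
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, pct.shape)
        noise[:, ~sub] = 0.0  # reference stays exact by definition
        pct = pct + noise
    lo, hi = pct.min(), pct.max()
    pct = np.clip(pct, 0.0, 100.0)
    if lo < 0.0 or hi > 100.0:
        import warnings

        warnings.warn("planted %D clipped to [0, 100]; means near the bounds distort", stacklevel=2)

    counts = pct / 100.0 * spec.d_max
    ids = [f"pep{i + 1:03d}" for i in range(spec.n_peptides)]
    columns = pd.MultiIndex.from_product(
        [[spec.condition], tps.tolist()], names=["condition", "timepoint"]
    )
    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="peptide_id"), columns=columns)
    span = 10
    peptides = pd.DataFrame(
        {
            "chain": ["A"] * spec.n_peptides,
            "start": [1 + span * i for i in range(spec.n_peptides)],
            "end": [span * (i + 1) for i in range(spec.n_peptides)],
        },
        index=pd.Index(ids, name="peptide_id"),
    )
    return UptakeTable(counts=counts_df, peptides=peptides), labels
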