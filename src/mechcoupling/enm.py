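"""Anisotropic network model: Hessian, normal modes, covariance, displacements.

The protein is modelled as Cα beads joined by identical harmonic springs
(force constant ``gamma``) whenever two beads lie within ``cutoff`` Å. The
3N×3N Hessian of this energy has exactly six zero modes (rigid translations
and rotations) for a connected contact network; the remaining modes, weighted
by inverse eigenvalue, build the residue-residue covariance matrix that the
coupling-graph stage consumes.

Residue-level covariance entries are the traces of the 3×3 Cartesian blocks
(the standard 3N→N contraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

from .structure_io import ResidueMap, Structure, superpose_rmsd, apply_transform

__all__ = [
    "ANMModel",
    "CovarianceMatrix",
    "DisplacementVector",
    "RMSFProfile",
    "anm_hessian",
    "build_anm",
    "covariance_from_modes",
    "subtract_mode_covariance",
    "rmsf_profile",
    "rmsf_percent_change",
    "displacement_unit_vector",
    "pseudo_covariance",
    "mode_displacement_overlap",
]

#: relative eigenvalue threshold below which a mode counts as rigid-body
TRIVIAL_TOL = 1e-8


@dataclass
class ANMModel:
    """Eigen-decomposed elastic network for one structure.

    ``eigenvalues`` ascend; ``eigenvectors[:, k]`` is the orthonormal 3N-mode
    paired with ``eigenvalues[k]``. The six rigid-body modes are flagged by
    ``n_trivial`` (they are kept, not deleted). Non-trivial modes are indexed
    1-based by ascending eigenvalue: mode 1 is the slowest internal motion.
    """

    structure: Structure
    cutoff: float
    gamma: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_trivial: int = 6

    @property
    def n_residues(self) -> int:
        return len(self.structure)

    @property
    def n_modes(self) -> int:
        """Number of non-trivial (internal) modes."""
        return self.eigenvalues.size - self.n_trivial

    def mode(self, k: int) -> tuple[float, np.ndarray]:
        """Eigenpair of non-trivial mode ``k`` (1-based, slowest first)."""
        if not 1 <= k <= self.n_modes:
            raise ValueError(f"mode index {k} outside 1..{self.n_modes}")
        col = self.n_trivial + k - 1
        return float(self.eigenvalues[col]), self.eigenvectors[:, col]


@dataclass
class CovarianceMatrix:
    """Residue-level covariance: raw values, unit-diagonal normalization, MSF.

    ``msf`` holds the per-residue mean-square fluctuation used to normalize;
    for mode-subtracted matrices it is the FULL matrix's MSF, so the
    normalized entries stay on the full-covariance scale.
    """

    raw: np.ndarray
    normalized: np.ndarray
    msf: np.ndarray
    mask: np.ndarray | None = None  # residues excluded from normalization

    @property
    def n(self) -> int:
        return self.raw.shape[0]


@dataclass
class RMSFProfile:
    values: np.ndarray
    reference: str = ""


@dataclass
class DisplacementVector:
    """Unit-norm per-residue displacement between two superposed structures."""

    vectors: np.ndarray  # n_common × 3, flattened norm 1
    residue_map: ResidueMap

    @property
    def flat(self) -> np.ndarray:
        return self.vectors.ravel()


def anm_hessian(coords: np.ndarray, cutoff: float, gamma: float) -> np.ndarray:
    """3N×3N ANM Hessian: −γ d̂d̂ᵀ off-diagonal blocks for each contact pair.

    Pure assembly; no connectivity or size checks, so it can be compared
    against finite differences of the network energy on arbitrary bead sets.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    dist = squareform(pdist(coords))
    contact = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    hessian = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(np.triu(contact, k=1))
    for i, j in zip(ii, jj):
        d = coords[j] - coords[i]
        block = -gamma * np.outer(d, d) / (d @ d)
        hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return hessian


def build_anm(structure: Structure, cutoff: float = 15.0, gamma: float = 1.0) -> ANMModel:
    """Assemble and diagonalize the ANM Hessian for a Cα structure.

    Raises if fewer than 3 residues, or if the contact network is
    disconnected at ``cutoff`` (reporting the number of components), or if
    the spectrum does not show exactly six rigid-body modes.
    """
    n = len(structure)
    if n < 3:
        raise ValueError(f"need at least 3 residues, got {n}")
    coords = structure.coords
    dist = squareform(pdist(coords))
    contact = (dist <= cutoff) & ~np.eye(n, dtype=bool)

    n_comp, comp = connected_components(csr_matrix(contact), directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp)
        raise ValueError(
            f"contact network disconnected at cutoff {cutoff} Å: "
            f"{n_comp} components with sizes {sorted(sizes.tolist(), reverse=True)}"
        )

    eigenvalues, eigenvectors = eigh(anm_hessian(coords, cutoff, gamma))
    eigenvalues = np.where(np.abs(eigenvalues) < TRIVIAL_TOL * max(eigenvalues.max(), 1.0), 0.0, eigenvalues)
    n_trivial = int(np.sum(eigenvalues < TRIVIAL_TOL * max(eigenvalues.max(), 1.0)))
    if n_trivial != 6:
        raise ValueError(
            f"expected 6 rigid-body modes, found {n_trivial}; "
            "the contact network is likely ill-conditioned"
        )
    return ANMModel(
        structure=structure, cutoff=cutoff, gamma=gamma,
        eigenvalues=eigenvalues, eigenvectors=eigenvectors, n_trivial=n_trivial,
    )


def _block_trace(matrix_3n: np.ndarray) -> np.ndarray:
    """Contract a 3N×3N matrix to N×N by tracing each 3×3 residue block."""
    n = matrix_3n.shape[0] // 3
    return np.einsum("iaja->ij", matrix_3n.reshape(n, 3, n, 3))


def covariance_from_modes(model: ANMModel, n_modes: int | None = None) -> CovarianceMatrix:
    """Residue covariance from the inverse-eigenvalue-weighted mode sum.

    All non-trivial modes are used by default (``n_modes`` restricts to the
    slowest ``n_modes`` for experiments). Equals the block-traced pseudo-
    inverse of the Hessian when all modes are kept.
    """
    lam = model.eigenvalues[model.n_trivial :]
    vec = model.eigenvectors[:, model.n_trivial :]
    if n_modes is not None:
        lam, vec = lam[:n_modes], vec[:, :n_modes]
    if np.any(lam <= TRIVIAL_TOL * max(model.eigenvalues.max(), 1.0)):
        raise ValueError("non-trivial eigenvalue at or below tolerance: ill-conditioned model")
    raw3n = (vec / lam) @ vec.T
    raw = _block_trace(raw3n)
    msf = np.diag(raw).copy()
    normalized = raw / np.sqrt(np.outer(msf, msf))
    return CovarianceMatrix(raw=raw, normalized=normalized, msf=msf)


def subtract_mode_covariance(cov: CovarianceMatrix, model: ANMModel, k: int) -> CovarianceMatrix:
    """Covariance with non-trivial mode ``k`` removed.

    Removes (1/λ_k) ν_k ν_kᵀ (block-traced) from the raw matrix, then
    normalizes by the FULL matrix's mean-square fluctuations so the
    mode-subtracted couplings stay comparable to the full ones.
    """
    lam_k, nu_k = model.mode(k)  # raises for k out of 1..n_modes
    raw = cov.raw - _block_trace(np.outer(nu_k, nu_k)) / lam_k
    normalized = raw / np.sqrt(np.outer(cov.msf, cov.msf))
    return CovarianceMatrix(raw=raw, normalized=normalized, msf=cov.msf.copy())


def rmsf_profile(cov: CovarianceMatrix, reference: str = "") -> RMSFProfile:
    """Per-residue RMSF √(raw C_ii), in model units (Å²·γ⁻¹ square-rooted)."""
    diag = np.diag(cov.raw)
    if np.any(diag < 0):
        raise ValueError("negative covariance diagonal; raw matrix required")
    return RMSFProfile(values=np.sqrt(diag), reference=reference)


def rmsf_percent_change(ref: RMSFProfile, alt: RMSFProfile, residue_map: ResidueMap) -> np.ndarray:
    """100·(alt − ref)/ref on the common residues of the map."""
    r = ref.values[residue_map.a_indices]
    a = alt.values[residue_map.b_indices]
    if np.any(r == 0):
        raise ValueError("reference RMSF of zero on a common residue")
    return 100.0 * (a - r) / r


def displacement_unit_vector(
    a: Structure,
    b: Structure,
    residue_map: ResidueMap,
    fit_subset=None,
    tol: float = 1e-10,
) -> DisplacementVector:
    """Unit vector of the conformational change from ``a`` to ``b``.

    ``b`` is rigid-body superposed onto ``a`` over ``fit_subset`` (indices
    into the common-residue list; default all common residues), then the
    per-residue coordinate differences on common residues are flattened and
    normalized to unit Euclidean length.
    """
    ai, bi = residue_map.a_indices, residue_map.b_indices
    if ai.size < 3:
        raise ValueError("need at least 3 common residues")
    a_common = a.coords[ai]
    b_common = b.coords[bi]
    rot, trans, _ = superpose_rmsd(a_common, b_common, fit_subset=fit_subset)
    delta = apply_transform(b_common, rot, trans) - a_common
    norm = float(np.linalg.norm(delta))
    if norm < tol:
        raise ValueError("degenerate displacement: structures identical after superposition")
    return DisplacementVector(vectors=delta / norm, residue_map=residue_map)


def pseudo_covariance(d: DisplacementVector, mask_tol: float = 1e-8) -> CovarianceMatrix:
    """Rank-deficient surrogate covariance C'_ij = ΔR_i · ΔR_j.

    Treats the single displacement between two crystal forms as if it were
    the only motion, to ask what coupling that motion alone would create.
    Normalized by its own diagonal; residues whose displacement magnitude is
    near zero are masked (their normalized entries set to 0).
    """
    v = d.vectors
    if not np.any(v):
        raise ValueError("all-zero displacement vector")
    raw = v @ v.T
    diag = np.diag(raw).copy()
    mask = diag < mask_tol * diag.max()
    safe = np.where(mask, 1.0, diag)
    normalized = raw / np.sqrt(np.outer(safe, safe))
    normalized[mask, :] = 0.0
    normalized[:, mask] = 0.0
    return CovarianceMatrix(raw=raw, normalized=normalized, msf=diag, mask=mask)


def mode_displacement_overlap(model: ANMModel, d: DisplacementVector) -> np.ndarray:
    """|ν_k · ΔR| per non-trivial mode, slowest first.

    ΔR is defined on the common residues of its map; it is zero-padded onto
    the model's full residue set (map indices must refer to the model's
    structure on the A side) and renormalized before projection.
    """
    n = model.n_residues
    padded = np.zeros((n, 3))
    ai = d.residue_map.a_indices
    if ai.max(initial=-1) >= n:
        raise ValueError("residue map does not fit the model's structure")
    padded[ai] = d.vectors
    flat = padded.ravel()
    nrm = np.linalg.norm(flat)
    if nrm == 0:
        raise ValueError("displacement vanishes after padding")
    flat = flat / nrm
    vec = model.eigenvectors[:, model.n_trivial :]
    if vec.shape[0] != flat.size:
        raise ValueError("dimension mismatch after padding")
    return np.abs(vec.T @ flat)
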