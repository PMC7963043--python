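"""Per-normal-mode influence on coupling pathways, and pathway overlaps.

A mode's importance for the communication between regions X and Y is measured
by rebuilding the whole coupling-graph/betweenness pipeline from the
covariance with that mode subtracted and comparing the resulting chokepoint
profile χ₋ₖ with the full-covariance profile χ₀:

    O_k = (χ₋ₖ · χ₀) / (χ₀ · χ₀),    I_k = 1 − O_k.

I_k near 1 means the communication collapses without mode k; I_k < 0 means
removing the mode concentrates even more traffic on the reference
chokepoints. The same overlap compares χ profiles from any two motions, e.g.
an ANM covariance vs. the crystallographic displacement's pseudo-covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coupling_graph import PruningParams, build_coupling_graph, geodesic_matrix, mechanical_coupling
from .enm import ANMModel, CovarianceMatrix, covariance_from_modes, subtract_mode_covariance
from .pathways import BetweennessProfile, betweenness
from .structure_io import RegionSet, Structure

__all__ = ["ModeInfluenceRecord", "influence_of_mode", "influence_table", "pathway_overlap", "chi_profile"]


@dataclass
class ModeInfluenceRecord:
    mode: int
    overlap: float  # O_k ≥ 0
    influence: float  # I_k = 1 − O_k, may be negative
    source_region: str
    target_region: str
    structure_id: str = ""


def chi_profile(
    cov: CovarianceMatrix,
    structure: Structure,
    params: PruningParams,
    x: RegionSet,
    y: RegionSet | str = "all",
    weight: str = "inv_geodesic",
) -> BetweennessProfile:
    """Covariance → pruned graph → geodesics → M → betweenness, in one call.

    Pruning statistics μ_|C|, σ_|C| are recomputed on the given covariance
    (same d_cut/c_thresh constants, full procedure applied afresh).
    """
    graph = build_coupling_graph(cov, structure, params)
    mechanical_coupling(geodesic_matrix(graph))
    return betweenness(graph, x, y, weight=weight)


def pathway_overlap(chi_a: BetweennessProfile, chi_ref: BetweennessProfile) -> float:
    """O = (χ_a · χ_ref)/(χ_ref · χ_ref); asymmetric, may exceed 1."""
    a, r = chi_a.chi, chi_ref.chi
    if a.shape != r.shape:
        raise ValueError("profiles live on different residue sets")
    denom = float(r @ r)
    if denom == 0:
        raise ValueError("reference χ profile is all-zero")
    return float(a @ r) / denom


def influence_of_mode(
    model: ANMModel,
    structure: Structure,
    params: PruningParams,
    x: RegionSet,
    y: RegionSet | str,
    k: int,
    cov: CovarianceMatrix | None = None,
    chi0: BetweennessProfile | None = None,
    weight: str = "inv_geodesic",
) -> ModeInfluenceRecord:
    """Influence I_k of non-trivial mode k on the X–Y coupling pathways.

    ``cov`` and ``chi0`` (the full-covariance matrix and profile) can be
    passed in to avoid recomputation across a mode scan.
    """
    if cov is None:
        cov = covariance_from_modes(model)
    if chi0 is None:
        chi0 = chi_profile(cov, structure, params, x, y, weight=weight)
    if not np.any(chi0.chi):
        raise ValueError("reference χ profile is all-zero")
    cov_minus = subtract_mode_covariance(cov, model, k)
    try:
        chi_minus = chi_profile(cov_minus, structure, params, x, y, weight=weight)
        overlap = pathway_overlap(chi_minus, chi0)
    except ValueError:
        # removing the mode severed every X–Y pathway: the χ_−k = 0 limit,
        # i.e. this single mode carried all motions needed for the coupling
        overlap = 0.0
    return ModeInfluenceRecord(
        mode=k, overlap=overlap, influence=1.0 - overlap,
        source_region=chi0.source_region, target_region=chi0.target_region,
        structure_id=structure.source_id,
    )


def influence_table(
    model: ANMModel,
    structure: Structure,
    params: PruningParams,
    x: RegionSet,
    y: RegionSet | str,
    modes,
    weight: str = "inv_geodesic",
) -> list[ModeInfluenceRecord]:
    """I_k for each mode in ``modes``, sharing one reference profile."""
    cov = covariance_from_modes(model)
    chi0 = chi_profile(cov, structure, params, x, y, weight=weight)
    return [
        influence_of_mode(model, structure, params, x, y, k, cov=cov, chi0=chi0, weight=weight)
        for k in modes
    ]
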