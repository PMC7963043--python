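"""Elastic-network model: Hessian, modes, covariance, displacement quantities."""

import numpy as np
import pytest
from scipy.linalg import eigh

from mechcoupling.enm import (
    anm_hessian,
    build_anm,
    covariance_from_modes,
    displacement_unit_vector,
    mode_displacement_overlap,
    pseudo_covariance,
    rmsf_percent_change,
    rmsf_profile,
    subtract_mode_covariance,
    _block_trace,
)
from mechcoupling.structure_io import common_residue_map

from conftest import random_cloud, structure_from_coords


def pinv_covariance_oracle(model):
    """Block-traced pseudo-inverse of the Hessian rebuilt from eigenpairs."""
    hessian = (model.eigenvectors * model.eigenvalues) @ model.eigenvectors.T
    return _block_trace(np.linalg.pinv(hessian, rcond=1e-10, hermitian=True))


class TestBuildANM:
    def test_connected_cloud_has_exactly_six_zero_modes(self):
        model = build_anm(random_cloud(20, seed=0))
        assert model.n_trivial == 6
        assert np.all(model.eigenvalues[:6] == 0.0)
        assert model.eigenvalues[6] > 0

    def test_diatomic_hessian_single_mode_along_bond(self):
        # closed-form oracle: two beads, one spring — eigenvalues {0×5, 2γ},
        # the stiff mode moving the beads oppositely along the bond axis
        gamma = 1.7
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        w, v = eigh(anm_hessian(coords, cutoff=5.0, gamma=gamma))
        np.testing.assert_allclose(w[:5], 0.0, atol=1e-12)
        assert w[5] == pytest.approx(2.0 * gamma)
        mode = v[:, 5].reshape(2, 3)
        np.testing.assert_allclose(np.abs(mode[:, 0]), 1.0 / np.sqrt(2.0), atol=1e-12)
        assert mode[0, 0] == pytest.approx(-mode[1, 0])

    def test_hessian_matches_finite_difference_of_network_energy(self):
        coords = random_cloud(5, seed=1, box=8.0).coords
        cutoff, gamma = 15.0, 1.3
        dist0 = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        contact = (dist0 <= cutoff) & ~np.eye(5, dtype=bool)

        def energy(flat):
            c = flat.reshape(5, 3)
            e = 0.0
            for i in range(5):
                for j in range(i + 1, 5):
                    if contact[i, j]:
                        d = np.linalg.norm(c[i] - c[j]) - dist0[i, j]
                        e += 0.5 * gamma * d * d
            return e

        x0 = coords.ravel()
        h = 1e-5
        num = np.zeros((15, 15))
        for p in range(15):
            for q in range(15):
                xpp = x0.copy(); xpp[p] += h; xpp[q] += h
                xpm = x0.copy(); xpm[p] += h; xpm[q] -= h
                xmp = x0.copy(); xmp[p] -= h; xmp[q] += h
                xmm = x0.copy(); xmm[p] -= h; xmm[q] -= h
                num[p, q] = (energy(xpp) - energy(xpm) - energy(xmp) + energy(xmm)) / (4 * h * h)
        np.testing.assert_allclose(anm_hessian(coords, cutoff, gamma), num, atol=5e-5)

    def test_hessian_translation_invariance(self):
        coords = random_cloud(7, seed=2).coords
        hessian = anm_hessian(coords, 15.0, 1.0)
        # each 3×3 super-row sums to zero: uniform translation costs nothing
        row_blocks = hessian.reshape(7, 3, 7, 3).sum(axis=2)
        np.testing.assert_allclose(row_blocks, 0.0, atol=1e-12)

    def test_disconnected_network_rejected_naming_components(self):
        coords = np.vstack([random_cloud(5, seed=3, box=5.0).coords,
                            random_cloud(5, seed=4, box=5.0).coords + 100.0])
        with pytest.raises(ValueError, match="2 components"):
            build_anm(structure_from_coords(coords), cutoff=15.0)

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            build_anm(structure_from_coords(np.zeros((2, 3))))


class TestCovariance:
    def test_unit_diagonal(self):
        cov = covariance_from_modes(build_anm(random_cloud(10, seed=5)))
        np.testing.assert_allclose(np.diag(cov.normalized), 1.0, atol=1e-12)

    @pytest.mark.parametrize("n", [6, 15, 30])
    def test_equals_hessian_pseudo_inverse(self, n):
        model = build_anm(random_cloud(n, seed=n))
        cov = covariance_from_modes(model)
        oracle = pinv_covariance_oracle(model)
        scale = np.abs(oracle).max()
        assert np.max(np.abs(cov.raw - oracle)) / scale < 1e-8

    def test_normalized_invariant_under_gamma_rescaling(self):
        s = random_cloud(9, seed=6)
        c1 = covariance_from_modes(build_anm(s, gamma=1.0))
        c2 = covariance_from_modes(build_anm(s, gamma=7.5))
        np.testing.assert_allclose(c1.normalized, c2.normalized, atol=1e-9)


class TestModeSubtraction:
    def test_reconstruction_identity(self):
        model = build_anm(random_cloud(8, seed=7))
        cov = covariance_from_modes(model)
        lam, nu = model.mode(3)
        back = subtract_mode_covariance(cov, model, 3).raw + _block_trace(np.outer(nu, nu)) / lam
        np.testing.assert_allclose(back, cov.raw, atol=1e-12)

    def test_subtracting_every_mode_leaves_zero(self):
        model = build_anm(random_cloud(6, seed=8))
        cov = covariance_from_modes(model)
        residual = cov.raw.copy()
        for k in range(1, model.n_modes + 1):
            lam, nu = model.mode(k)
            residual = residual - _block_trace(np.outer(nu, nu)) / lam
        np.testing.assert_allclose(residual, 0.0, atol=1e-10)

    def test_subtracted_matrix_equals_mode_sum_without_k(self):
        model = build_anm(random_cloud(6, seed=9))
        cov = covariance_from_modes(model)
        minus_first = subtract_mode_covariance(cov, model, 1)
        lam = model.eigenvalues[7:]
        vec = model.eigenvectors[:, 7:]
        oracle = _block_trace((vec / lam) @ vec.T)
        np.testing.assert_allclose(minus_first.raw, oracle, atol=1e-10)
        # normalization uses the FULL covariance diagonal, not its own
        np.testing.assert_allclose(
            minus_first.normalized, oracle / np.sqrt(np.outer(cov.msf, cov.msf)), atol=1e-12
        )

    def test_trivial_or_out_of_range_mode_rejected(self):
        model = build_anm(random_cloud(6, seed=10))
        cov = covariance_from_modes(model)
        for bad in (0, -1, model.n_modes + 1):
            with pytest.raises(ValueError, match="mode index"):
                subtract_mode_covariance(cov, model, bad)


class TestRMSF:
    def test_matches_mode_sum_oracle(self):
        model = build_anm(random_cloud(6, seed=11))
        cov = covariance_from_modes(model)
        lam = model.eigenvalues[6:]
        vec = model.eigenvectors[:, 6:].reshape(6, 3, -1)
        oracle = np.sqrt(np.einsum("iak,k->i", vec**2, 1.0 / lam))
        np.testing.assert_allclose(rmsf_profile(cov).values, oracle, atol=1e-10)

    def test_percent_change_identity_and_arithmetic(self):
        s = random_cloud(5, seed=12)
        cov = covariance_from_modes(build_anm(s))
        prof = rmsf_profile(cov)
        rmap = common_residue_map(s, s)
        np.testing.assert_allclose(rmsf_percent_change(prof, prof, rmap), 0.0)
        from mechcoupling.enm import RMSFProfile

        ref = RMSFProfile(values=np.array([2.0] * 5))
        alt = RMSFProfile(values=np.array([2.5] * 5))
        np.testing.assert_allclose(rmsf_percent_change(ref, alt, rmap), 25.0)


class TestDisplacement:
    def test_unit_norm_and_fixed_domain_near_zero(self, hinge):
        from mechcoupling.synthetic_data import perturb_rigid

        structure, _, regions, _ = hinge
        moved = perturb_rigid(structure, regions["domain_b"], rotation_deg=12.0, translation=(2.0, 0.5, 0.0))
        rmap = common_residue_map(structure, moved)
        fit = [int(i) for i in regions["domain_a"].resolved_indices]
        d = displacement_unit_vector(structure, moved, rmap, fit_subset=fit)
        assert np.linalg.norm(d.flat) == pytest.approx(1.0)
        fixed = np.linalg.norm(d.vectors[regions["domain_a"].resolved_indices], axis=1)
        movedmag = np.linalg.norm(d.vectors[regions["domain_b"].resolved_indices], axis=1)
        assert fixed.max() < 1e-8
        assert movedmag.min() > 1e-4

    def test_pure_rigid_motion_degenerate(self):
        from mechcoupling.synthetic_data import perturb_rigid
        from mechcoupling.structure_io import RegionSet

        s = random_cloud(10, seed=13)
        whole = RegionSet.from_indices("all", range(10))
        moved = perturb_rigid(s, whole, rotation_deg=30.0, translation=(5.0, 1.0, 2.0))
        rmap = common_residue_map(s, moved)
        with pytest.raises(ValueError, match="degenerate"):
            displacement_unit_vector(s, moved, rmap)


class TestPseudoCovariance:
    def test_hand_computed_dot_products(self):
        from mechcoupling.enm import DisplacementVector
        from mechcoupling.structure_io import ResidueMap

        vecs = np.array([[1.0, 0, 0], [0, 1.0, 0], [1.0, 1.0, 0], [0, 0, 2.0]])
        vecs = vecs / np.linalg.norm(vecs)
        d = DisplacementVector(vectors=vecs, residue_map=ResidueMap(pairs=[(i, i) for i in range(4)]))
        cov = pseudo_covariance(d)
        np.testing.assert_allclose(cov.raw, vecs @ vecs.T, atol=1e-15)
        # Gram matrix of 3-vectors: rank ≤ 3
        assert np.linalg.matrix_rank(cov.raw, tol=1e-10) <= 3
        np.testing.assert_allclose(np.diag(cov.normalized), 1.0, atol=1e-12)

    def test_parallel_displacements_make_rank_one(self):
        from mechcoupling.enm import DisplacementVector
        from mechcoupling.structure_io import ResidueMap

        vecs = np.outer([1.0, 2.0, -1.0, 0.5], [1.0, 0.0, 0.0])
        vecs = vecs / np.linalg.norm(vecs)
        d = DisplacementVector(vectors=vecs, residue_map=ResidueMap(pairs=[(i, i) for i in range(4)]))
        assert np.linalg.matrix_rank(pseudo_covariance(d).raw, tol=1e-10) == 1


class TestModeDisplacementOverlap:
    def test_eigenvector_recovers_itself(self):
        from mechcoupling.enm import DisplacementVector
        from mechcoupling.structure_io import ResidueMap

        model = build_anm(random_cloud(6, seed=14))
        _, nu = model.mode(2)
        d = DisplacementVector(
            vectors=nu.reshape(6, 3),
            residue_map=ResidueMap(pairs=[(i, i) for i in range(6)]),
        )
        overlaps = mode_displacement_overlap(model, d)
        assert overlaps[1] == pytest.approx(1.0)
        others = np.delete(overlaps, 1)
        np.testing.assert_allclose(others, 0.0, atol=1e-10)

    def test_parseval_in_internal_subspace(self):
        from mechcoupling.enm import DisplacementVector
        from mechcoupling.structure_io import ResidueMap

        model = build_anm(random_cloud(6, seed=15))
        rng = np.random.default_rng(0)
        coeffs = rng.normal(size=model.n_modes)
        flat = model.eigenvectors[:, 6:] @ coeffs
        d = DisplacementVector(
            vectors=(flat / np.linalg.norm(flat)).reshape(6, 3),
            residue_map=ResidueMap(pairs=[(i, i) for i in range(6)]),
        )
        overlaps = mode_displacement_overlap(model, d)
        assert np.sum(overlaps**2) == pytest.approx(1.0)
        # projection oracle
        np.testing.assert_allclose(
            overlaps, np.abs(coeffs) / np.linalg.norm(coeffs), atol=1e-10
        )
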