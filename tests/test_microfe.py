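"""Element stiffness, solver oracles and strain-field extraction."""

import numpy as np
import pytest

from rtfe import (
    BCSpec,
    FEProblem,
    assemble_and_solve,
    build_material_volume,
    effective_strain_field,
    element_stiffness,
    make_homogeneous_block,
    solve_material_volume,
)
from rtfe.errors import EmptyDistributionError, InvalidInputError, InvalidSpecError
from rtfe.microfe import _unit_stiffness

H = 0.0105


class TestElementStiffness:
    def test_six_rigid_body_modes(self):
        K = element_stiffness(12000.0, 0.3, H)
        w = np.linalg.eigvalsh(K)
        assert np.all(np.abs(w[:6]) < 1e-6 * w[-1])
        assert w[6] > 1e-6 * w[-1]

    def test_linear_in_modulus_and_edge_length(self):
        K1 = element_stiffness(1000.0, 0.3, H)
        np.testing.assert_allclose(element_stiffness(2000.0, 0.3, H), 2 * K1)
        np.testing.assert_allclose(element_stiffness(1000.0, 0.3, 2 * H), 2 * K1)

    def test_symmetry_and_translation_nullspace(self):
        K = element_stiffness(5000.0, 0.25, H)
        np.testing.assert_allclose(K, K.T)
        for comp in range(3):
            t = np.zeros(24)
            t[comp::3] = 1.0  # rigid translation
            np.testing.assert_allclose(K @ t, 0.0, atol=1e-8)

    def test_patch_test_uniform_strain_energy(self):
        # a linear displacement field u_z = eps * z must yield the exact
        # uniaxial-strain energy density 0.5 * C33 * eps^2
        E, nu, eps = 10000.0, 0.3, 1e-3
        K = element_stiffness(E, nu, H)
        from rtfe.microfe import _CORNERS

        u = np.zeros(24)
        u[2::3] = eps * _CORNERS[:, 2] * H
        energy = 0.5 * u @ K @ u
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        expected = 0.5 * (lam + 2 * mu) * eps**2 * H**3
        assert energy == pytest.approx(expected, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidInputError):
            element_stiffness(-1.0, 0.3, H)
        with pytest.raises(InvalidInputError):
            element_stiffness(1.0, 0.6, H)


def _homogeneous_problem(shape, e_mpa=10000.0, **kw):
    return FEProblem(np.full(shape, e_mpa), 0.3, H, **kw)


class TestHomogeneousOracle:
    @pytest.mark.parametrize("shape", [(4, 4, 4), (6, 5, 9), (12, 10, 16)])
    def test_roller_block_uniform_10000_microstrain(self, shape):
        p = _homogeneous_problem(shape, bc=BCSpec(bottom_mode="roller"), tol=1e-9)
        s = assemble_and_solve(p)
        np.testing.assert_allclose(s.effective_strain, 10_000.0, rtol=1e-6)
        area = shape[0] * shape[1] * H**2
        assert s.f_resultant == pytest.approx(10000.0 * 0.01 * area, rel=1e-6)

    def test_zero_displacement_gives_zero_everything(self):
        p = _homogeneous_problem((4, 4, 4), bc=BCSpec(delta_fraction=0.0))
        s = assemble_and_solve(p)
        assert s.f_resultant == 0.0
        np.testing.assert_array_equal(s.effective_strain, 0.0)

    def test_linearity_in_prescribed_displacement(self):
        s1 = assemble_and_solve(
            _homogeneous_problem((4, 4, 6), bc=BCSpec(delta_fraction=0.01), tol=1e-10)
        )
        s2 = assemble_and_solve(
            _homogeneous_problem((4, 4, 6), bc=BCSpec(delta_fraction=0.02), tol=1e-10)
        )
        np.testing.assert_allclose(
            s2.effective_strain, 2 * s1.effective_strain, rtol=1e-5
        )
        assert s2.f_resultant == pytest.approx(2 * s1.f_resultant, rel=1e-5)


class TestSolverEquivalence:
    def test_cg_matches_dense_direct_solve_on_small_grid(self, rng):
        moduli = rng.uniform(3.0, 12000.0, (6, 6, 6))
        direct = assemble_and_solve(FEProblem(moduli, 0.3, H), method="direct")
        iterative = assemble_and_solve(FEProblem(moduli, 0.3, H, tol=1e-12))
        scale = np.abs(direct.displacement).max()
        assert (
            np.abs(iterative.displacement - direct.displacement).max() / scale < 1e-8
        )
        assert iterative.f_resultant == pytest.approx(direct.f_resultant, rel=1e-8)

    def test_equilibrium_of_reaction_sums(self, rng):
        moduli = rng.uniform(100.0, 12000.0, (5, 5, 7))
        s = assemble_and_solve(FEProblem(moduli, 0.3, H, tol=1e-10))
        assert s.equilibrium_error < 1e-6


class TestSerialStack:
    def test_two_material_series_springs(self):
        # soft-on-stiff stack under roller BC: axial stress is continuous,
        # centroid strains partition inversely to the moduli (1-D series
        # springs); with equal Poisson ratios the interface mismatch is a
        # small edge effect, so compare at moderate tolerance
        e_soft, e_stiff = 5000.0, 10000.0
        moduli = np.full((6, 6, 8), e_stiff)
        moduli[:, :, 4:] = e_soft
        s = assemble_and_solve(
            FEProblem(moduli, 0.3, H, bc=BCSpec(bottom_mode="roller"), tol=1e-10)
        )
        assert s.equilibrium_error < 1e-6
        # closed form: eps_i = delta / (L * E_i * (0.5/E1 + 0.5/E2))
        delta_over_l = 0.01
        eps_stiff = delta_over_l / (e_stiff * (0.5 / e_stiff + 0.5 / e_soft))
        eps_soft = delta_over_l / (e_soft * (0.5 / e_stiff + 0.5 / e_soft))
        got_stiff = np.median(s.effective_strain[:, :, 1]) / 1e6
        got_soft = np.median(s.effective_strain[:, :, 6]) / 1e6
        assert got_stiff == pytest.approx(eps_stiff, rel=0.03)
        assert got_soft == pytest.approx(eps_soft, rel=0.03)
        # resultant force equals the series-spring stiffness prediction
        area = 36 * H**2
        e_series = 1.0 / (0.5 / e_stiff + 0.5 / e_soft)
        assert s.f_resultant == pytest.approx(
            e_series * delta_over_l * area, rel=0.03
        )


class TestLoadPathCheck:
    def test_disconnected_mesh_is_warned_but_solved(self):
        vol = make_homogeneous_block((6, 6, 8), 500.0, H)
        vol.values[:, :, 3:5] = 0.0  # sever the column with a soft band
        matvol = build_material_volume(vol)
        s = solve_material_volume(matvol)
        assert any("disconnected" in w for w in s.warnings)
        assert s.f_resultant > 0  # soft tissue still carries (little) load

    def test_connected_mesh_has_no_warning(self):
        vol = make_homogeneous_block((4, 4, 4), 500.0, H)
        s = solve_material_volume(build_material_volume(vol))
        assert s.warnings == []


class TestEffectiveStrainField:
    def test_full_mask_on_homogeneous_block_is_constant(self):
        p = _homogeneous_problem((4, 4, 4), bc=BCSpec(bottom_mode="roller"))
        s = assemble_and_solve(p)
        dist = effective_strain_field(s, np.ones((4, 4, 4), bool))
        assert len(dist) == 64
        np.testing.assert_allclose(dist.strains_ue, 10_000.0, rtol=1e-5)
        assert dist.f_applied == dist.f_resultant

    def test_mask_selects_exactly_the_masked_elements(self, rng):
        moduli = rng.uniform(100.0, 12000.0, (4, 4, 4))
        s = assemble_and_solve(FEProblem(moduli, 0.3, H))
        mask = rng.uniform(size=(4, 4, 4)) < 0.5
        dist = effective_strain_field(s, mask)
        assert len(dist) == int(mask.sum())
        np.testing.assert_array_equal(
            np.sort(dist.strains_ue), np.sort(s.effective_strain[mask])
        )

    def test_empty_mask_rejected(self):
        s = assemble_and_solve(_homogeneous_problem((4, 4, 4)))
        with pytest.raises(EmptyDistributionError):
            effective_strain_field(s, np.zeros((4, 4, 4), bool))
        with pytest.raises(InvalidInputError):
            effective_strain_field(s, np.ones((5, 4, 4), bool))


def test_bcspec_validation():
    with pytest.raises(InvalidSpecError):
        BCSpec(delta_fraction=0.5)
    with pytest.raises(InvalidSpecError):
        BCSpec(bottom_mode="floating")


def test_unit_stiffness_row_sums_vanish():
    # translation invariance at the assembled-stencil level
    k = _unit_stiffness(0.3)
    for comp in range(3):
        t = np.zeros(24)
        t[comp::3] = 1.0
        np.testing.assert_allclose(k @ t, 0.0, atol=1e-12)
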