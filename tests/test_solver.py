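"""FE solver: patch test, couplings, contact, equilibrium, scaling."""

import numpy as np
import pytest

from fusegap import (
    AssembledModel,
    ContactParams,
    LoadCase,
    ModelParams,
    apply_load_case,
    build_arthrodesis_model,
    build_verification_fixture,
    solve,
)
from tests.conftest import mean_set_materials, timoshenko_tip_deflection


class TestLoadCase:
    def test_neutral_force_is_vertical(self):
        lc = LoadCase(phi=0.0)
        assert np.allclose(lc.force_vector, [0.0, -650.0, 0.0])

    def test_tilted_force_keeps_magnitude_and_rotates(self):
        lc = LoadCase(phi=-20.0)
        F = lc.force_vector
        assert np.linalg.norm(F) == pytest.approx(650.0)
        assert abs(F[2]) == pytest.approx(650.0 * np.sin(np.radians(20.0)))
        assert F[0] == 0.0  # rotation about the anterior axis

    def test_angle_and_force_limits(self):
        with pytest.raises(ValueError):
            LoadCase(phi=-25.0)
        with pytest.raises(ValueError):
            LoadCase(phi=0.0, force_magnitude=-10.0)

    def test_missing_surface_set_reported(self):
        mesh = build_verification_fixture("patch_block")
        with pytest.raises(ValueError, match="support"):
            apply_load_case(mesh, LoadCase(load_ref=None, pivot_ref=None))


class TestPatchAndBeam:
    def test_patch_test_uniform_uniaxial_stress(self):
        """Constant traction on a uniform cube reproduces sigma_xx exactly."""
        mesh = build_verification_fixture("patch_block")
        t = 2.5
        lc = LoadCase(
            load_ref=None, pivot_ref=None, fixed_surfaces=(),
            rollers=(("face_xmin", 0), ("face_ymin", 1), ("face_zmin", 2)),
            tractions={"face_xmax": (t, 0.0, 0.0)},
        )
        sol = solve(mesh, {"block": (17000.0, 0.3)}, lc)
        assert sol.converged
        assert np.allclose(sol.stress[:, 0], t, rtol=1e-9)
        assert np.abs(sol.stress[:, 1:]).max() < 1e-9 * t
        assert sol.residual < 1e-9

    def test_cantilever_tip_deflection_beam_theory(self, cantilever_force):
        mesh, _, sol, F = cantilever_force
        tip = np.unique(mesh.surface_sets["tip"])
        ref = timoshenko_tip_deflection(F)
        assert sol.u[tip, 1].mean() == pytest.approx(ref, rel=0.05)


class TestContact:
    def test_closing_blocks_transmit_full_pressure(self):
        """Penalty contact transmits the applied pressure across the gap."""
        mesh = build_verification_fixture("contact_blocks")
        p = 2.0
        model = AssembledModel(
            mesh,
            {"block_lower": (1000.0, 0.3), "block_upper": (1000.0, 0.3)},
            ContactParams(friction_mu=0.0),
            contact_pairs=(("contact_upper", "contact_lower"),),
        )
        sol = model.solve(
            LoadCase(
                load_ref=None, pivot_ref=None, fixed_surfaces=("bottom",),
                tractions={"top": (0.0, -p, 0.0)},
            )
        )
        assert sol.converged
        assert any(v.any() for v in sol.contact_active.values())
        transmitted = sol.reaction_force[1]  # reaction under the lower block
        assert transmitted == pytest.approx(p * 100.0, rel=0.02)

    def test_open_gap_stays_inactive(self, arthro_coarse, arthro_solution):
        # ~1 mm gap versus ~0.01 mm motion: articular contact never engages
        assert arthro_solution.converged
        assert not any(v.any() for v in arthro_solution.contact_active.values())

    def test_friction_cap_limits_tangential_force(self):
        """Coulomb friction: tangential reaction never exceeds mu * normal."""
        mesh = build_verification_fixture("contact_blocks")
        mu = 0.3
        model = AssembledModel(
            mesh,
            {"block_lower": (1000.0, 0.3), "block_upper": (1000.0, 0.3)},
            ContactParams(friction_mu=mu),
            contact_pairs=(("contact_upper", "contact_lower"),),
        )
        p, q = 2.0, 1.5  # tangential load above the friction cone
        sol = model.solve(
            LoadCase(
                load_ref=None, pivot_ref=None, fixed_surfaces=("bottom",),
                tractions={"top": (q, -p, 0.0)},
            )
        )
        Rx, Ry = sol.reaction_force[0], sol.reaction_force[1]
        assert abs(Rx) <= mu * abs(Ry) * 1.05 + 1e-6


class TestGlobalProperties:
    def test_equilibrium_of_converged_solution(self, arthro_solution):
        assert arthro_solution.equilibrium_residual < 1e-6
        assert arthro_solution.residual < 1e-6

    def test_uniform_stiffness_scaling(self):
        """Doubling every modulus halves u and leaves stresses unchanged."""
        mesh = build_arthrodesis_model(ModelParams(elem_size=7.0))
        base = mean_set_materials()
        scaled = {k: (2.0 * E, nu) for k, (E, nu) in base.items()}
        lc = LoadCase(phi=-10.0)
        pairs = (("articular_lower", "articular_upper"),)
        s1 = AssembledModel(mesh, base, contact_pairs=pairs).solve(lc)
        s2 = AssembledModel(mesh, scaled, contact_pairs=pairs).solve(lc)
        ref = np.abs(s1.u).max()
        assert np.abs(s2.u - 0.5 * s1.u).max() < 1e-6 * ref
        sref = np.abs(s1.stress).max()
        assert np.abs(s2.stress - s1.stress).max() < 1e-6 * sref

    def test_incomplete_materials_rejected(self):
        mesh = build_verification_fixture("contact_blocks")
        with pytest.raises(ValueError, match="cover"):
            AssembledModel(mesh, {"block_lower": (1000.0, 0.3)})
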