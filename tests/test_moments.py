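"""Implant frame and section-moment extraction against free-body statics."""

import numpy as np
import pytest

from fusegap import (
    AssembledModel,
    LoadCase,
    SectionCutter,
    build_verification_fixture,
    equilibrium_check,
    implant_frame,
)
from fusegap.mesh import Mesh

STATIONS = np.arange(5.0, 71.0, 5.0)


class TestImplantFrame:
    def test_axis_of_ideal_cylinder(self, cantilever):
        mesh, _ = cantilever
        frame = implant_frame(mesh)
        assert np.allclose(frame.x_axis, [1.0, 0.0, 0.0], atol=1e-9)
        assert frame.span == pytest.approx(75.0)
        R = frame.rotation()
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_sign_points_away_from_entry(self, cantilever):
        # convention: distal (entry) -> proximal, so origin is at the entry
        mesh, _ = cantilever
        frame = implant_frame(mesh)
        assert np.allclose(frame.origin, [0.0, 0.0, 0.0], atol=1e-9)

    def test_frame_rotates_with_the_geometry(self, cantilever):
        mesh, _ = cantilever
        ang = np.radians(30.0)
        R = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0.0],
                [np.sin(ang), np.cos(ang), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        rotated = Mesh(
            nodes=mesh.nodes @ R.T,
            elements=mesh.elements,
            element_sets=mesh.element_sets,
            reference_points={
                k: R @ v for k, v in mesh.reference_points.items()
            },
        )
        frame = implant_frame(rotated)
        assert np.allclose(frame.x_axis, R @ [1.0, 0.0, 0.0], atol=1e-9)

    def test_missing_set_rejected(self, cantilever):
        with pytest.raises(ValueError):
            implant_frame(cantilever[0], elem_set="stem")


class TestSectionMoments:
    def test_zero_field_gives_zero_moments(self, cantilever):
        mesh, model = cantilever
        frame = implant_frame(mesh)
        cutter = SectionCutter(mesh, frame, STATIONS, include_sets=("nail",))
        cur = cutter.evaluate(
            np.zeros((mesh.n_nodes, 3)), model.E_elem, model.nu_elem
        )
        assert np.allclose([cur.Mx, cur.My, cur.Mz], 0.0)

    def test_tip_force_matches_free_body_statics(self, cantilever_force):
        """Bending moment = F x lever arm at every station, within 5%."""
        mesh, model, sol, F = cantilever_force
        frame = implant_frame(mesh)
        cutter = SectionCutter(mesh, frame, STATIONS, include_sets=("nail",))
        cur = cutter.evaluate(sol.u, model.E_elem, model.nu_elem)
        res = equilibrium_check(cur, frame, [((75.0, 0.0, 0.0), (0.0, F, 0.0))])
        assert res.max() < 0.05
        # spot value: |Mz| = F * d at the station nearest the clamp
        assert abs(cur.Mz[0]) == pytest.approx(F * 70.0, rel=0.05)

    def test_tip_torque_is_constant_torsion(self, cantilever_torque):
        mesh, model, sol, T = cantilever_torque
        frame = implant_frame(mesh)
        cutter = SectionCutter(mesh, frame, STATIONS, include_sets=("nail",))
        cur = cutter.evaluate(sol.u, model.E_elem, model.nu_elem)
        assert np.allclose(cur.Mx, T, rtol=0.05)
        assert np.abs(cur.My).max() < 0.05 * T
        assert np.abs(cur.Mz).max() < 0.05 * T

    def test_element_stress_route_consistent(self, cantilever_force):
        """Per-element stress integration (foreign-field mode) tracks the
        displacement-based integration within the averaging error."""
        mesh, model, sol, F = cantilever_force
        frame = implant_frame(mesh)
        cutter = SectionCutter(mesh, frame, STATIONS, ("nail",))
        cur_u = cutter.evaluate(sol.u, model.E_elem, model.nu_elem)
        cur_s = cutter.evaluate_from_element_stress(sol.stress)
        scale = np.abs(cur_u.Mz).max()
        assert np.abs(cur_s.Mz - cur_u.Mz).max() < 0.1 * scale
        assert np.abs(cur_s.Mx - cur_u.Mx).max() < 0.1 * scale

    def test_station_outside_span_rejected(self, cantilever):
        mesh, _ = cantilever
        frame = implant_frame(mesh)
        with pytest.raises(ValueError):
            SectionCutter(mesh, frame, np.array([80.0]))

    def test_unloaded_equilibrium_residual_zero(self, cantilever):
        mesh, model = cantilever
        frame = implant_frame(mesh)
        cutter = SectionCutter(mesh, frame, STATIONS, include_sets=("nail",))
        cur = cutter.evaluate(
            np.zeros((mesh.n_nodes, 3)), model.E_elem, model.nu_elem
        )
        res = equilibrium_check(cur, frame, [])
        assert np.allclose(res, 0.0)

    def test_magnitudes_invariant_under_model_rotation(self, cantilever_force):
        """Rotating mesh+load rotates the frame; |Mx| and |M_bend| persist."""
        mesh, model, sol, F = cantilever_force
        ang = np.radians(25.0)
        R = np.array(
            [
                [np.cos(ang), 0.0, np.sin(ang)],
                [0.0, 1.0, 0.0],
                [-np.sin(ang), 0.0, np.cos(ang)],
            ]
        )
        rotated = Mesh(
            nodes=mesh.nodes @ R.T,
            elements=mesh.elements,
            element_sets=mesh.element_sets,
            surface_sets=mesh.surface_sets,
            reference_points={k: R @ v for k, v in mesh.reference_points.items()},
        )
        frame0 = implant_frame(mesh)
        frame1 = implant_frame(rotated)
        cur0 = SectionCutter(mesh, frame0, STATIONS, ("nail",)).evaluate(
            sol.u, model.E_elem, model.nu_elem
        )
        cur1 = SectionCutter(rotated, frame1, STATIONS, ("nail",)).evaluate(
            sol.u @ R.T, model.E_elem, model.nu_elem
        )
        bend0 = np.hypot(cur0.My, cur0.Mz)
        bend1 = np.hypot(cur1.My, cur1.Mz)
        scale = bend0.max()
        assert np.abs(np.abs(cur0.Mx) - np.abs(cur1.Mx)).max() < 1e-6 * scale
        assert np.abs(bend0 - bend1).max() < 1e-6 * scale
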