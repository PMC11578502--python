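"""Synthetic geometry: mesh validity, gap control, parameter handling."""

import numpy as np
import pytest

from fusegap import (
    ModelParams,
    build_arthrodesis_model,
    build_verification_fixture,
    pair_surfaces,
)
from fusegap.mesh import box_grid, signed_volumes
from fusegap.model import MATERIAL_SETS

REQUIRED_SURFACES = (
    "articular_lower", "articular_upper", "support",
    "load_coupling", "pivot_coupling",
)


class TestArthrodesisModel:
    def test_default_model_is_valid(self):
        mesh = build_arthrodesis_model(ModelParams(elem_size=5.0))
        mesh.check_valid(MATERIAL_SETS)  # jacobians + set partition
        for name in REQUIRED_SURFACES:
            assert len(mesh.surface_sets[name]) > 0
        assert {"load", "pivot"} <= set(mesh.reference_points)
        # pivot sits soft_tissue_offset below the lower body
        assert mesh.reference_points["pivot"][1] == pytest.approx(-17.0)
        # labeled articular subregions cover the whole lower facet
        total = sum(
            len(mesh.surface_sets[f"articular_lower_{r}"])
            for r in ("posterior", "central", "anterior")
        )
        assert total == len(mesh.surface_sets["articular_lower"])

    @pytest.mark.parametrize("gap", [0.5, 1.0, 2.0])
    def test_measured_gap_matches_parameter(self, gap):
        # taller talar block keeps the 75 mm nail inside at the 0.5 mm gap
        p = ModelParams(
            elem_size=3.0, gap_width=gap, upper_block_size=(40.0, 31.0, 30.0)
        )
        mesh = build_arthrodesis_model(p)
        pairing = pair_surfaces(mesh)
        # concentric cylindrical surfaces: gap equal to the parameter up to
        # the chordal sagitta of the faceted surfaces
        sagitta = p.elem_size**2 / (8 * p.gap_curvature_radius)
        tol = max(0.05 * p.elem_size, 2 * sagitta)
        assert pairing.distance.min() == pytest.approx(gap, abs=tol)
        assert np.median(pairing.distance) == pytest.approx(gap, abs=tol + 0.05)

    def test_element_count_scales_with_resolution(self):
        def block_elems(h):
            m = build_arthrodesis_model(ModelParams(elem_size=h))
            return sum(
                len(m.element_sets[s])
                for s in ("cortical_lower", "cancellous_lower",
                          "cortical_upper", "cancellous_upper", "pmma")
            )

        # halving h scales the structured block grids ~O(h^-3)
        assert block_elems(2.5) >= 4 * block_elems(5.0)

    def test_nail_crosses_the_gap(self):
        p = ModelParams(elem_size=5.0)
        mesh = build_arthrodesis_model(p)
        ys = mesh.nodes[np.unique(mesh.elements[mesh.element_sets["nail"]]), 1]
        gap_y = mesh.reference_points["gap_center"][1]
        assert ys.min() < gap_y < ys.max()

    @pytest.mark.parametrize(
        "bad",
        [
            dict(gap_width=-1.0),
            dict(nail_wall=7.0),
            dict(nail_length=200.0),          # longer than the assembly
            dict(screw_positions=(12.0, 30.0, 46.5)),  # crosses the gap
            dict(screw_positions=(12.0, 30.0, 90.0)),  # outside the nail
            dict(nail_offset_x=-30.0),        # outside the blocks
        ],
    )
    def test_infeasible_parameters_raise(self, bad):
        with pytest.raises(ValueError):
            build_arthrodesis_model(ModelParams(elem_size=5.0, **bad))


class TestVerificationFixtures:
    @pytest.mark.parametrize(
        "kind,kw",
        [
            ("patch_block", {}),
            ("cantilever_tube", {"elem_size": 3.0}),
            ("contact_blocks", {}),
        ],
    )
    def test_fixture_meshes_are_valid(self, kind, kw):
        mesh = build_verification_fixture(kind, **kw)
        assert mesh.n_elements > 0
        assert np.all(mesh.volumes() > 0)

    def test_cantilever_matches_nail_dimensions(self):
        mesh = build_verification_fixture("cantilever_tube", elem_size=3.0)
        x = mesh.nodes
        assert x[:, 0].max() - x[:, 0].min() == pytest.approx(75.0)
        # corner nodes sit exactly on the wall radii (midsides on chords)
        corners = np.unique(mesh.elements[:, :4])
        r = np.hypot(x[corners, 1], x[corners, 2])
        assert r.max() == pytest.approx(6.0, abs=1e-9)
        assert r.min() == pytest.approx(4.0, abs=1e-9)

    def test_patch_block_is_single_set_cube(self):
        mesh = build_verification_fixture("patch_block")
        assert list(mesh.element_sets) == ["block"]
        span = mesh.nodes.max(axis=0) - mesh.nodes.min(axis=0)
        assert np.allclose(span, 10.0)

    def test_analytic_planes_have_unit_gap(self):
        mesh = build_verification_fixture(
            "analytic_surface_pair", variant="planes", distance=1.0
        )
        pr = pair_surfaces(mesh, "lower", "upper")
        assert np.allclose(pr.distance, 1.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_verification_fixture("moebius_strip")


class TestMeshPrimitives:
    def test_box_grid_volume_is_exact(self):
        nodes, tets, _ = box_grid((0, 0, 0), (4.0, 6.0, 2.0), 1.0)
        assert signed_volumes(nodes[tets]).sum() == pytest.approx(48.0)
        assert np.all(signed_volumes(nodes[tets]) > 0)

    def test_locate_points_finds_containing_elements(self):
        mesh = build_verification_fixture("patch_block")
        rng = np.random.default_rng(0)
        pts = rng.uniform(0.5, 9.5, size=(20, 3))
        elems, lam = mesh.locate_points(pts)
        assert np.all(elems >= 0)
        # barycentric interpolation of coordinates reproduces the points
        corners = mesh.corner_coords(elems)
        recon = np.einsum("kj,kjc->kc", lam, corners)
        assert np.allclose(recon, pts, atol=1e-9)
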