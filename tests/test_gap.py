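"""Surface pairing, displacement decomposition and monitor-point selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusegap import (
    build_verification_fixture,
    decompose,
    pair_surfaces,
    select_monitor_point,
)
from fusegap.gap import project_on_triangles


def brute_force_pairing(mesh, lower, upper):
    """Exhaustive all-triangle nearest-point scan (independent of the KD path)."""
    tris = mesh.surface_sets[upper][:, :3]
    tv = mesh.nodes[tris]
    ids = np.unique(mesh.surface_sets[lower])
    best_tri = np.empty(len(ids), dtype=int)
    best_d = np.empty(len(ids))
    for i, p in enumerate(mesh.nodes[ids]):
        pp = np.broadcast_to(p, (len(tris), 3))
        _, dist, _ = project_on_triangles(pp, tv[:, 0], tv[:, 1], tv[:, 2])
        j = int(np.argmin(dist))  # ties -> lowest triangle id
        best_tri[i], best_d[i] = j, dist[j]
    return best_tri, best_d


class TestPairing:
    def test_parallel_planes(self):
        mesh = build_verification_fixture(
            "analytic_surface_pair", variant="planes", distance=1.0
        )
        pr = pair_surfaces(mesh, "lower", "upper")
        assert np.allclose(pr.distance, 1.0)
        # normals oriented from the upper body toward the lower one
        assert np.allclose(pr.normal, [0.0, -1.0, 0.0])
        assert np.allclose(np.linalg.norm(pr.normal, axis=1), 1.0)

    def test_concentric_spherical_caps_pair_radially(self):
        d, R = 0.5, 30.0
        mesh = build_verification_fixture(
            "analytic_surface_pair", variant="spheres", distance=d, radius=R,
            elem_size=0.8,
        )
        pr = pair_surfaces(mesh, "lower", "upper")
        # faceting bias either way, bounded by the diagonal-chord sagitta
        # (plus boundary effects at the patch rim)
        sagitta = (0.8 * np.sqrt(2)) ** 2 / (8 * R)
        assert np.all(np.abs(pr.distance - d) <= 3 * sagitta)
        # nearest points lie radially outward from the sample points
        unit_p = pr.points / np.linalg.norm(pr.points, axis=1, keepdims=True)
        radial = (pr.nearest * unit_p).sum(axis=1)
        offset = np.linalg.norm(pr.nearest - radial[:, None] * unit_p, axis=1)
        assert offset.max() < 0.5  # within one facet of the radial direction

    def test_matches_brute_force_scan(self, arthro_coarse):
        mesh, _ = arthro_coarse
        assert len(mesh.surface_sets["articular_upper"]) <= 5000
        pr = pair_surfaces(mesh)
        bt, bd = brute_force_pairing(mesh, "articular_lower", "articular_upper")
        assert np.array_equal(pr.tri_ids, bt)
        assert np.allclose(pr.distance, bd)

    def test_empty_surface_rejected(self):
        mesh = build_verification_fixture(
            "analytic_surface_pair", variant="planes"
        )
        mesh.surface_sets["void"] = np.empty((0, 6), dtype=int)
        with pytest.raises(ValueError):
            pair_surfaces(mesh, "void", "upper")


@pytest.fixture(scope="module")
def plane_pairing():
    mesh = build_verification_fixture(
        "analytic_surface_pair", variant="planes", distance=1.0
    )
    return mesh, pair_surfaces(mesh, "lower", "upper")


class TestDecomposition:
    def test_rigid_normal_translation(self, plane_pairing):
        mesh, pr = plane_pairing
        u = np.zeros((mesh.n_nodes, 3))
        u[np.unique(mesh.surface_sets["lower"]), 1] = 0.1  # lower moves up
        g = decompose(pr, u)
        assert np.allclose(g.du_n, -0.1)  # closing is negative
        assert np.allclose(g.du_t_mag, 0.0, atol=1e-14)

    def test_rigid_inplane_slide(self, plane_pairing):
        mesh, pr = plane_pairing
        u = np.zeros((mesh.n_nodes, 3))
        u[np.unique(mesh.surface_sets["lower"]), 0] = 0.05
        g = decompose(pr, u)
        assert np.allclose(g.du_n, 0.0, atol=1e-14)
        assert np.allclose(g.du_t_mag, 0.05)
        assert np.allclose(g.du_t_signed, 0.05)  # anterior reference direction

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=10, derandomize=True)
    def test_pythagoras_and_reconstruction(self, seed):
        mesh = build_verification_fixture(
            "analytic_surface_pair", variant="spheres", distance=0.5
        )
        pr = pair_surfaces(mesh, "lower", "upper")
        rng = np.random.default_rng(seed)
        u = rng.normal(scale=0.05, size=(mesh.n_nodes, 3))
        g = decompose(pr, u)
        assert np.allclose(
            g.du_n**2 + g.du_t_mag**2, (g.du**2).sum(axis=1), atol=1e-14
        )
        recon = g.du_n[:, None] * pr.normal + g.du_t_vec
        assert np.abs(recon - g.du).max() < 1e-10
        assert np.abs((g.du_t_vec * pr.normal).sum(axis=1)).max() < 1e-10

    def test_rotation_about_local_normal_has_zero_normal_component(
        self, plane_pairing
    ):
        """Rigid rotation of the lower surface about a point's normal leaves
        the normal component at that point zero (exact for a flat pairing)."""
        mesh, pr = plane_pairing
        theta = 1e-3
        pivot = pr.points[0]
        n = pr.normal[0]
        u = np.zeros((mesh.n_nodes, 3))
        ids = np.unique(mesh.surface_sets["lower"])
        u[ids] = theta * np.cross(n, mesh.nodes[ids] - pivot)
        g = decompose(pr, u)
        assert abs(g.du_n[0]) < 1e-12
        assert np.abs(g.du_n).max() < 1e-12  # flat surface: exact everywhere

    def test_mismatched_fields_rejected(self, plane_pairing):
        _, pr = plane_pairing
        with pytest.raises(ValueError):
            decompose(pr, np.zeros((3, 3)), np.zeros((4, 3)))


class TestMonitorPoint:
    def test_identical_fields_return_lowest_id(self):
        f = np.ones(10)
        assert select_monitor_point(f, f) == 0

    def test_single_discrepant_point_selected(self):
        a, b = np.zeros(10), np.zeros(10)
        b[7] = 1.0
        assert select_monitor_point(a, b) == 7

    def test_matches_exhaustive_scan_with_subset(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=50), rng.normal(size=50)
        sub = np.arange(10, 30)
        brute = sub[int(np.argmax(np.abs(a[sub] - b[sub])))]
        assert select_monitor_point(a, b, sub) == brute

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            select_monitor_point(np.ones(3), np.ones(3), np.empty(0, dtype=int))
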