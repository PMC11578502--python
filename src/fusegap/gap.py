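"""Articular-gap kinematics: surface pairing and displacement decomposition.

For every sample point on the lower (calcaneal-analog) articular surface the
closest point on the upper (talar-analog) surface is found by exact
point-to-triangle projection (KD-tree accelerated, but guaranteed identical
to an exhaustive all-triangle search).  The relative displacement between the
paired points is split into a signed normal component along the local upper-
surface normal (negative = gap closing) and an in-plane tangential vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import Mesh


@dataclass
class SurfacePairing:
    """Nearest-point map from lower-surface nodes to the upper surface."""

    point_ids: np.ndarray      #: (k,) lower-surface node ids (sample points)
    points: np.ndarray         #: (k, 3) sample coordinates
    tri_ids: np.ndarray        #: (k,) paired upper corner-triangle ids
    nearest: np.ndarray        #: (k, 3) closest points on the upper surface
    distance: np.ndarray       #: (k,) gap distances (>= 0)
    normal: np.ndarray         #: (k, 3) unit normals, oriented upper -> lower
    facet_nodes: np.ndarray    #: (k, 6) quadratic facet connectivity
    facet_weights: np.ndarray  #: (k, 6) interpolation weights at the nearest point
    n_nodes: int               #: node count of the parent mesh

    def interpolate_upper(self, u: np.ndarray) -> np.ndarray:
        """Interpolate a nodal field at the paired upper-surface points."""
        return np.einsum("kj,kjc->kc", self.facet_weights, u[self.facet_nodes])


@dataclass
class GapDisplacementField:
    """Normal/tangential split of relative gap displacements (mm)."""

    du: np.ndarray         #: (k, 3) relative displacement lower - upper
    du_n: np.ndarray       #: (k,) signed normal component (negative = closing)
    du_t_vec: np.ndarray   #: (k, 3) tangential (in-plane) vector
    du_t_mag: np.ndarray   #: (k,) tangential magnitude
    du_t_signed: np.ndarray  #: (k,) projection on the in-plane reference direction


# ---------------------------------------------------------------------------
# exact point-triangle projection (vectorized Ericson algorithm)


def project_on_triangles(p, a, b, c):
    """Closest points of ``p`` on triangles ``(a, b, c)`` (all (q, 3)).

    Returns ``(closest, dist, bary)`` with barycentric coordinates of the
    projection in the triangle.
    """
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = (ab * ap).sum(1), (ac * ap).sum(1)
    bp, cp = p - b, p - c
    d3, d4 = (ab * bp).sum(1), (ac * bp).sum(1)
    d5, d6 = (ab * cp).sum(1), (ac * cp).sum(1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    q = len(p)
    u = np.empty(q)
    v = np.empty(q)
    # region masks, evaluated in the standard order
    m_a = (d1 <= 0) & (d2 <= 0)
    m_b = (~m_a) & (d3 >= 0) & (d4 <= d3)
    m_c = (~m_a) & (~m_b) & (d6 >= 0) & (d5 <= d6)
    m_ab = (~m_a) & (~m_b) & (~m_c) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    m_ac = (~m_a) & (~m_b) & (~m_c) & (~m_ab) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    m_bc = (
        (~m_a) & (~m_b) & (~m_c) & (~m_ab) & (~m_ac)
        & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    )
    m_in = ~(m_a | m_b | m_c | m_ab | m_ac | m_bc)

    u[m_a], v[m_a] = 0.0, 0.0
    u[m_b], v[m_b] = 1.0, 0.0
    u[m_c], v[m_c] = 0.0, 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(m_ab, d1 / (d1 - d3), 0.0)
        u[m_ab], v[m_ab] = t[m_ab], 0.0
        t = np.where(m_ac, d2 / (d2 - d6), 0.0)
        u[m_ac], v[m_ac] = 0.0, t[m_ac]
        t = np.where(m_bc, (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
        u[m_bc], v[m_bc] = 1.0 - t[m_bc], t[m_bc]
        denom = va + vb + vc
        u[m_in] = (vb / denom)[m_in]
        v[m_in] = (vc / denom)[m_in]

    closest = a + u[:, None] * ab + v[:, None] * ac
    dist = np.linalg.norm(p - closest, axis=1)
    bary = np.column_stack([1.0 - u - v, u, v])
    return closest, dist, bary


# ---------------------------------------------------------------------------
# pairing


def pair_surfaces(
    mesh: Mesh, lower_surface: str = "articular_lower",
    upper_surface: str = "articular_upper", k_candidates: int = 24,
) -> SurfacePairing:
    """Pair every lower-surface node with its closest upper-surface point.

    Candidate triangles come from a KD-tree over triangle centroids; the
    candidate set is then widened to every triangle whose centroid lies
    within (best distance + largest centroid-to-vertex radius), which makes
    the result identical to a brute-force all-triangle scan.  Equidistant
    triangles are resolved toward the lowest triangle id.
    """
    facets = mesh.surface_sets[upper_surface]
    if len(facets) == 0 or len(mesh.surface_sets[lower_surface]) == 0:
        raise ValueError("empty articular surface")
    tris = facets[:, :3]
    tv = mesh.nodes[tris]
    cent = tv.mean(axis=1)
    rmax = float(np.linalg.norm(tv - cent[:, None], axis=2).max())
    tree = cKDTree(cent)

    ids = np.unique(mesh.surface_sets[lower_surface])
    pts = mesh.nodes[ids]
    kq = min(k_candidates, len(tris))
    _, cand = tree.query(pts, k=kq)
    cand = np.atleast_2d(cand)

    best_tri = np.empty(len(pts), dtype=int)
    best_near = np.empty((len(pts), 3))
    best_dist = np.empty(len(pts))
    best_bary = np.empty((len(pts), 3))
    for i, p in enumerate(pts):
        cl = np.sort(cand[i])
        near, dist, bary = _best_on(p, cl, tv)
        j0 = np.argmin(dist)
        # widen to the guaranteed-complete candidate set
        full = np.sort(tree.query_ball_point(p, dist[j0] + rmax + 1e-12))
        if len(full) > len(cl):
            cl = np.asarray(full)
            near, dist, bary = _best_on(p, cl, tv)
            j0 = np.argmin(dist)
        best_tri[i] = cl[j0]
        best_near[i] = near[j0]
        best_dist[i] = dist[j0]
        best_bary[i] = bary[j0]

    normal = _normals_at(mesh, upper_surface, best_tri, best_bary)

    w6 = _t6_weights(best_bary)
    return SurfacePairing(
        point_ids=ids, points=pts, tri_ids=best_tri, nearest=best_near,
        distance=best_dist, normal=normal, facet_nodes=facets[best_tri],
        facet_weights=w6, n_nodes=mesh.n_nodes,
    )


def _best_on(p, tri_ids, tv):
    t = tv[tri_ids]
    pp = np.broadcast_to(p, (len(tri_ids), 3))
    return project_on_triangles(pp, t[:, 0], t[:, 1], t[:, 2])


def _t6_weights(bary: np.ndarray) -> np.ndarray:
    """Quadratic (T6) interpolation weights from corner barycentric coords."""
    l0, l1, l2 = bary[:, 0], bary[:, 1], bary[:, 2]
    return np.column_stack(
        [
            l0 * (2 * l0 - 1), l1 * (2 * l1 - 1), l2 * (2 * l2 - 1),
            4 * l0 * l1, 4 * l1 * l2, 4 * l2 * l0,
        ]
    )


def _normals_at(mesh, surface, tri_ids, bary, tol=1e-9):
    """Surface normal at projection points.

    Interior projections use the face normal; projections on an edge average
    the two adjacent face normals; vertex projections use the angle-weighted
    vertex normal.  All normals inherit the facet orientation (outward from
    the upper body, i.e. pointing toward the lower body).
    """
    tris = mesh.surface_sets[surface][:, :3]
    tv = mesh.nodes[tris]
    fn = np.cross(tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0])
    fn /= np.linalg.norm(fn, axis=1, keepdims=True)

    # angle-weighted vertex normals
    vn = np.zeros((mesh.n_nodes, 3))
    for c in range(3):
        e1 = tv[:, (c + 1) % 3] - tv[:, c]
        e2 = tv[:, (c + 2) % 3] - tv[:, c]
        cosang = (e1 * e2).sum(1) / (
            np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
        )
        ang = np.arccos(np.clip(cosang, -1, 1))
        np.add.at(vn, tris[:, c], ang[:, None] * fn)

    # edge -> adjacent-face map
    edges = {}
    for t, tri in enumerate(tris):
        for a, b in ((0, 1), (1, 2), (2, 0)):
            key = (min(tri[a], tri[b]), max(tri[a], tri[b]))
            edges.setdefault(key, []).append(t)

    out = np.empty((len(tri_ids), 3))
    for i, (t, lam) in enumerate(zip(tri_ids, bary)):
        zero = lam < tol
        if zero.sum() == 0:
            n = fn[t]
        elif zero.sum() == 2:
            n = vn[tris[t][np.argmax(lam)]]
        else:
            a, b = tris[t][~zero]
            key = (min(a, b), max(a, b))
            n = fn[edges[key]].sum(axis=0)
        out[i] = n / np.linalg.norm(n)
    return out


# ---------------------------------------------------------------------------
# decomposition


def decompose(
    pairing: SurfacePairing,
    u_lower: np.ndarray,
    u_upper: np.ndarray | None = None,
    reference_direction=(1.0, 0.0, 0.0),
) -> GapDisplacementField:
    """Split relative gap displacements into normal and tangential parts.

    ``u_lower`` may be the full nodal field (n_nodes, 3) -- then ``u_upper``
    defaults to the same field and both sides are sampled/interpolated from
    it -- or a (k, 3) array already evaluated at the paired points (with
    ``u_upper`` given likewise).  The signed tangential scalar is the
    projection of the tangential vector on ``reference_direction`` projected
    into the local tangent plane (anterior-posterior by default).
    """
    if len(u_lower) == pairing.n_nodes and u_lower.ndim == 2:
        ul = u_lower[pairing.point_ids]
        uu = pairing.interpolate_upper(u_upper if u_upper is not None else u_lower)
    else:
        if u_upper is None or len(u_upper) != len(u_lower):
            raise ValueError("per-point fields require matching u_lower/u_upper")
        ul, uu = np.asarray(u_lower), np.asarray(u_upper)

    du = ul - uu
    n = pairing.normal
    du_n = (du * n).sum(axis=1)
    du_t = du - du_n[:, None] * n
    ref = np.asarray(reference_direction, dtype=float)
    ref_t = ref[None, :] - (n @ ref)[:, None] * n
    norm = np.linalg.norm(ref_t, axis=1)
    ref_t = np.divide(
        ref_t, norm[:, None], out=np.zeros_like(ref_t), where=norm[:, None] > 1e-12
    )
    return GapDisplacementField(
        du=du, du_n=du_n, du_t_vec=du_t,
        du_t_mag=np.linalg.norm(du_t, axis=1),
        du_t_signed=(du_t * ref_t).sum(axis=1),
    )


def select_monitor_point(
    field_eversion: np.ndarray,
    field_inversion: np.ndarray,
    subset: np.ndarray | None = None,
) -> int:
    """Index of the point with the largest eversion/inversion discrepancy.

    ``field_*`` are per-point scalars of one component (normal or signed
    tangential) at the extreme load configurations; ``subset`` restricts the
    search to a facet subregion (indices into the pairing's point list).
    Ties resolve to the lowest index.
    """
    f_ev, f_inv = np.asarray(field_eversion), np.asarray(field_inversion)
    if f_ev.shape != f_inv.shape:
        raise ValueError("fields must share the pairing")
    disc = np.abs(f_ev - f_inv)
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("empty monitor subregion")
        sub = np.asarray(subset)
        return int(sub[np.argmax(disc[sub])])
    return int(np.argmax(disc))
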