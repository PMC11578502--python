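"""Quadratic tetrahedral mesh container and structured mesh generation.

All meshes are 10-node tetrahedra (corner nodes 0-3 followed by midside
nodes on edges 01, 12, 20, 03, 13, 23 -- the VTK/Abaqus C3D10 convention).
Elements are straight-sided: midside nodes sit at edge midpoints, so the
Jacobian is constant per element and corner-node geometry defines volumes,
faces and point location.

Coordinates are millimetres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

#: local corner pairs of the six element edges, in connectivity order
EDGE_CORNERS = np.array([(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)])

#: corner triples of the four faces of a positively oriented tet, wound outward
FACE_CORNERS = np.array([(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)])


# ---------------------------------------------------------------------------
# container


@dataclass
class Mesh:
    """An assembly mesh with named element sets, surface sets and reference points.

    Attributes
    ----------
    nodes : (n, 3) float array of coordinates in mm.
    elements : (m, 10) int array, C3D10 connectivity.
    element_sets : name -> int array of element ids.  Material sets partition
        the elements: every element belongs to exactly one material set.
    surface_sets : name -> (k, 6) int array of oriented quadratic triangle
        facets (3 corners + 3 midsides), wound outward from the owning body.
    reference_points : name -> (3,) coordinate, for kinematic couplings.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)
    surface_sets: dict[str, np.ndarray] = field(default_factory=dict)
    reference_points: dict[str, np.ndarray] = field(default_factory=dict)
    #: optional (k, 6) tie records (slave_node, host_elem, lam0..lam3)
    #: coupling a node rigidly to the displacement field of a host element
    ties: np.ndarray | None = None

    # -- basic derived quantities ------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def corner_coords(self, elem_ids: np.ndarray | None = None) -> np.ndarray:
        """(m, 4, 3) corner coordinates."""
        el = self.elements if elem_ids is None else self.elements[elem_ids]
        return self.nodes[el[:, :4]]

    def volumes(self, elem_ids: np.ndarray | None = None) -> np.ndarray:
        """Signed element volumes (positive for valid elements)."""
        x = self.corner_coords(elem_ids)
        return signed_volumes(x)

    def centroids(self, elem_ids: np.ndarray | None = None) -> np.ndarray:
        return self.corner_coords(elem_ids).mean(axis=1)

    # -- surface helpers ---------------------------------------------------

    def corner_triangles(self, surface: str) -> np.ndarray:
        """(k, 3) corner-node triangles of a surface set."""
        return self.surface_sets[surface][:, :3]

    def facet_areas_normals(self, surface: str) -> tuple[np.ndarray, np.ndarray]:
        """Areas and outward unit normals of the (straight) facets."""
        tri = self.nodes[self.corner_triangles(surface)]
        cr = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        area = 0.5 * np.linalg.norm(cr, axis=1)
        normal = cr / np.linalg.norm(cr, axis=1, keepdims=True)
        return area, normal

    # -- validity ----------------------------------------------------------

    def check_valid(self, material_sets: list[str] | None = None) -> None:
        """Raise ValueError on negative Jacobians or non-partitioning sets."""
        vol = self.volumes()
        if not np.all(vol > 0):
            bad = int(np.sum(vol <= 0))
            raise ValueError(f"{bad} elements with non-positive Jacobian")
        if material_sets is not None:
            count = np.zeros(self.n_elements, dtype=int)
            for name in material_sets:
                count[self.element_sets[name]] += 1
            if not np.all(count == 1):
                raise ValueError("material element sets do not partition the mesh")

    # -- point location ----------------------------------------------------

    def locate_points(
        self, points: np.ndarray, elem_ids: np.ndarray | None = None,
        tol: float = 1e-8, k: int = 40,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Find containing elements and barycentric coordinates of points.

        Searches the given element subset (default: all).  Returns
        ``(elems, lam)`` with ``elems[i] = -1`` when a point lies outside
        every candidate element by more than ``tol`` (in barycentric units);
        in that case the best (least-outside) candidate's coordinates are
        still returned so callers may clamp if they choose.
        """
        sub = np.arange(self.n_elements) if elem_ids is None else np.asarray(elem_ids)
        x = self.corner_coords(sub)
        tree = cKDTree(x.mean(axis=1))
        k = min(k, len(sub))
        _, cand = tree.query(points, k=k)
        cand = np.atleast_2d(cand)
        elems = np.full(len(points), -1, dtype=int)
        lams = np.zeros((len(points), 4))
        for i, p in enumerate(np.asarray(points, dtype=float)):
            cs = sub[cand[i]]
            lam = barycentric(self.corner_coords(cs), p)
            worst = lam.min(axis=1)
            j = int(np.argmax(worst))
            lams[i] = lam[j]
            elems[i] = cs[j] if worst[j] >= -tol else -1
        return elems, lams


# ---------------------------------------------------------------------------
# low-level geometry


def signed_volumes(x: np.ndarray) -> np.ndarray:
    """Signed volumes of straight tets from (m, 4, 3) corner coords."""
    d = x[:, 1:] - x[:, :1]
    return np.linalg.det(d) / 6.0


def orient_positive(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Swap two corners of negatively oriented tets so all volumes > 0."""
    tets = tets.copy()
    vol = signed_volumes(nodes[tets])
    flip = vol < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()
    return tets


def barycentric(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of point p in each tet of (m, 4, 3) corners."""
    a = np.swapaxes(x[:, 1:] - x[:, :1], 1, 2)  # columns are edge vectors
    rhs = p[None, :] - x[:, 0]
    lam123 = np.linalg.solve(a, rhs[..., None])[..., 0]
    lam0 = 1.0 - lam123.sum(axis=1, keepdims=True)
    return np.hstack([lam0, lam123])


def _edge_keys(pairs: np.ndarray, n_nodes: int) -> np.ndarray:
    lo = np.minimum(pairs[..., 0], pairs[..., 1]).astype(np.int64)
    hi = np.maximum(pairs[..., 0], pairs[..., 1]).astype(np.int64)
    return lo * np.int64(n_nodes) + hi


def quadratic_from_linear(
    nodes: np.ndarray, tets: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Insert midside nodes on a linear tet mesh.

    Returns ``(nodes10, elems10, edge_keys_sorted)`` where the third array
    holds the sorted int64 edge keys so facet midsides can be looked up with
    :func:`edge_midside_lookup` (midside node id = n_linear + rank of key).
    """
    n = len(nodes)
    pairs = tets[:, EDGE_CORNERS]  # (m, 6, 2)
    keys = _edge_keys(pairs, n).ravel()
    uniq, inv = np.unique(keys, return_inverse=True)
    lo, hi = uniq // n, uniq % n
    mids = 0.5 * (nodes[lo] + nodes[hi])
    nodes10 = np.vstack([nodes, mids])
    elems10 = np.hstack([tets, (n + inv.reshape(len(tets), 6))])
    return nodes10, elems10, uniq


def edge_midside_lookup(
    edge_keys_sorted: np.ndarray, pairs: np.ndarray, n_linear: int
) -> np.ndarray:
    """Midside node ids for corner-node pairs, given the sorted edge keys."""
    keys = _edge_keys(np.asarray(pairs), n_linear)
    idx = np.searchsorted(edge_keys_sorted, keys)
    if not np.all(edge_keys_sorted[idx] == keys):
        raise KeyError("queried edge does not exist in the mesh")
    return n_linear + idx


def boundary_faces(tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Outward-wound boundary corner triangles of a linear tet mesh.

    Returns ``(faces, owners)``: (k, 3) corner triples (outward winding for
    positively oriented tets) and the owning element id of each face.
    """
    m = len(tets)
    faces = tets[:, FACE_CORNERS]  # (m, 4, 3)
    flat = faces.reshape(-1, 3)
    key = np.sort(flat, axis=1)
    _, first, counts = np.unique(
        key, axis=0, return_index=True, return_counts=True
    )
    sel = first[counts == 1]
    return flat[sel], sel // 4


def facets_quadratic(
    faces: np.ndarray, edge_keys_sorted: np.ndarray, n_linear: int
) -> np.ndarray:
    """Promote (k, 3) corner triangles to (k, 6) quadratic facets."""
    pairs = np.stack(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=1
    )
    mids = edge_midside_lookup(edge_keys_sorted, pairs, n_linear)
    return np.hstack([faces, mids])


# ---------------------------------------------------------------------------
# structured generators (linear tets; callers promote to quadratic)

#: the six path-simplices of the unit cube (Kuhn split); translation-invariant
#: in index space, hence conforming across cells and periodic seams
_CUBE_TETS = []
for _perm in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
    _c = [np.zeros(3, dtype=int)]
    for _ax in _perm:
        _step = _c[-1].copy()
        _step[_ax] += 1
        _c.append(_step)
    _CUBE_TETS.append(np.array(_c))
_CUBE_TETS = np.array(_CUBE_TETS)  # (6, 4, 3) corner offsets


def box_grid(
    origin: np.ndarray,
    spans: tuple[float, float, float],
    h: float,
    cell_mask=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Structured tet grid over a box, optionally masked per cell.

    ``cell_mask(centroids) -> bool array`` selects which grid cells are kept
    (used to attach support pads or carve simple features).  Unused nodes are
    dropped.  Returns ``(nodes, tets, cell_centroids_kept)``.
    """
    origin = np.asarray(origin, dtype=float)
    n = np.maximum(1, np.round(np.asarray(spans) / h).astype(int))
    axes = [np.linspace(0.0, spans[i], n[i] + 1) + origin[i] for i in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    nodes = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    ii, jj, kk = np.meshgrid(*(np.arange(c) for c in n), indexing="ij")
    cells = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    widths = np.array([spans[i] / n[i] for i in range(3)])
    cents = origin + (cells + 0.5) * widths
    if cell_mask is not None:
        keep = np.asarray(cell_mask(cents), dtype=bool)
        cells, cents = cells[keep], cents[keep]

    def nid(idx):
        return (idx[..., 0] * (n[1] + 1) + idx[..., 1]) * (n[2] + 1) + idx[..., 2]

    corner_idx = cells[:, None, None, :] + _CUBE_TETS[None]  # (c, 6, 4, 3)
    tets = nid(corner_idx).reshape(-1, 4)
    nodes, tets = _compress(nodes, tets)
    tets = orient_positive(nodes, tets)
    return nodes, tets, cents


def _compress(nodes: np.ndarray, tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    used, inv = np.unique(tets, return_inverse=True)
    return nodes[used], inv.reshape(tets.shape)


def tube_grid(
    inner_radius: float,
    outer_radius: float,
    length: float,
    h: float,
    axis_origin: np.ndarray = (0.0, 0.0, 0.0),
    axis: str = "y",
) -> tuple[np.ndarray, np.ndarray]:
    """Structured tet mesh of a hollow cylinder along a coordinate axis.

    Element size ``h`` controls the axial, circumferential and radial
    subdivisions (at least one element through the wall; quadratic elements
    carry the through-wall bending gradient).
    """
    wall = outer_radius - inner_radius
    nr = max(1, round(wall / h))
    mean_c = np.pi * (inner_radius + outer_radius)
    nt = max(8, round(mean_c / h))
    nx = max(2, round(length / h))

    r = np.linspace(inner_radius, outer_radius, nr + 1)
    t = np.arange(nt) * (2 * np.pi / nt)
    x = np.linspace(0.0, length, nx + 1)
    rr, tt, xx = np.meshgrid(r, t, x, indexing="ij")
    local = np.column_stack(
        [xx.ravel(), (rr * np.cos(tt)).ravel(), (rr * np.sin(tt)).ravel()]
    )
    nodes = _axis_frame(axis, axis_origin, local)

    ii, jj, kk = np.meshgrid(np.arange(nr), np.arange(nt), np.arange(nx), indexing="ij")
    cells = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])

    def nid(idx):
        return (idx[..., 0] * nt + (idx[..., 1] % nt)) * (nx + 1) + idx[..., 2]

    corner_idx = cells[:, None, None, :] + _CUBE_TETS[None]
    tets = nid(corner_idx).reshape(-1, 4)
    nodes, tets = _compress(nodes, tets)
    return nodes, orient_positive(nodes, tets)


def cylinder_grid(
    radius: float,
    length: float,
    h: float,
    n_rings: int = 2,
    axis_origin: np.ndarray = (0.0, 0.0, 0.0),
    axis: str = "z",
) -> tuple[np.ndarray, np.ndarray]:
    """Solid cylinder tet mesh (disk fan extruded along an axis).

    Used for the locking screws; the cross-section is a centre node plus
    ``n_rings`` concentric rings of 8 nodes.
    """
    nt = 8
    nx = max(2, round(length / h))
    # 2D disk triangulation
    pts2 = [np.zeros(2)]
    for ring in range(1, n_rings + 1):
        rad = radius * ring / n_rings
        ang = np.arange(nt) * (2 * np.pi / nt)
        pts2.extend(np.column_stack([rad * np.cos(ang), rad * np.sin(ang)]))
    pts2 = np.array(pts2)
    tris = []
    for j in range(nt):
        tris.append((0, 1 + j, 1 + (j + 1) % nt))
    for ring in range(1, n_rings):
        a0, b0 = 1 + (ring - 1) * nt, 1 + ring * nt
        for j in range(nt):
            j1 = (j + 1) % nt
            tris.append((a0 + j, b0 + j, b0 + j1))
            tris.append((a0 + j, b0 + j1, a0 + j1))
    tris = np.array(tris)

    xs = np.linspace(0.0, length, nx + 1)
    npts = len(pts2)
    local = np.column_stack(
        [
            np.repeat(xs, npts),
            np.tile(pts2[:, 0], nx + 1),
            np.tile(pts2[:, 1], nx + 1),
        ]
    )
    nodes = _axis_frame(axis, axis_origin, local)

    tets = []
    for layer in range(nx):
        lo, hi = layer * npts, (layer + 1) * npts
        for tri in tris:
            bot = lo + tri
            order = np.argsort(bot)
            i0, i1, i2 = bot[order]
            j0, j1, j2 = i0 + npts, i1 + npts, i2 + npts
            tets.extend([(i0, i1, i2, j0), (i1, i2, j0, j1), (i2, j0, j1, j2)])
    tets = np.array(tets)
    return nodes, orient_positive(nodes, tets)


def _axis_frame(axis: str, origin, local: np.ndarray) -> np.ndarray:
    """Map local (axial, u, v) coordinates onto a global coordinate axis."""
    maps = {
        "x": (0, 1, 2),
        "y": (1, 2, 0),
        "z": (2, 0, 1),
    }
    ia, iu, iv = maps[axis]
    out = np.empty_like(local)
    out[:, ia] = local[:, 0]
    out[:, iu] = local[:, 1]
    out[:, iv] = local[:, 2]
    return out + np.asarray(origin, dtype=float)


# ---------------------------------------------------------------------------
# assembly of multiple bodies


def merge_meshes(parts: list[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray, list[int], list[int]]:
    """Concatenate (nodes, tets) bodies without node sharing.

    Returns merged nodes, merged tets, per-part node offsets and element
    offsets.  Bodies interact only through ties and contact, so duplicate
    coordinates across bodies are intentional.
    """
    node_off, elem_off, nodes, tets = [], [], [], []
    nn = ne = 0
    for pn, pt in parts:
        node_off.append(nn)
        elem_off.append(ne)
        nodes.append(pn)
        tets.append(pt + nn)
        nn += len(pn)
        ne += len(pt)
    return np.vstack(nodes), np.vstack(tets), node_off, elem_off
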