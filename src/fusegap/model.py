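"""Parameterized synthetic arthrodesis geometry and verification fixtures.

The anatomy is deliberately simplified to a two-block "bone analog": a lower
(calcaneus-like) and an upper (talus-like) block, each with a cortical shell
around a cancellous core, separated by a curved articular gap of constant
normal width (two concentric cylindrical surfaces, so the gap normals vary
over the joint -- which is what makes the normal/tangential decomposition of
gap micromotion non-trivial).  A hollow titanium nail crosses the gap along
the vertical axis and is connected to both blocks by three transverse
locking screws; PMMA support pads on the anterior faces carry the fixed
boundary, and two reference points serve the kinematic couplings (vertical
load on the upper block, rocking pivot below the lower block).

Global axes: x = anterior, y = vertical (distal -> proximal), z = transverse
(medial-lateral); right-handed; units mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import (
    Mesh,
    boundary_faces,
    box_grid,
    cylinder_grid,
    facets_quadratic,
    merge_meshes,
    orient_positive,
    quadratic_from_linear,
    tube_grid,
)

#: material phase behind each element set of the arthrodesis model
PHASE_OF_SET = {
    "cortical_lower": "cortical",
    "cancellous_lower": "cancellous",
    "cortical_upper": "cortical",
    "cancellous_upper": "cancellous",
    "nail": "titanium",
    "screw_1": "titanium",
    "screw_2": "titanium",
    "screw_3": "titanium",
    "pmma": "pmma",
}

MATERIAL_SETS = list(PHASE_OF_SET)


@dataclass
class ModelParams:
    """Geometric parameters of the synthetic arthrodesis model (mm).

    Defaults follow the implant and surgical dimensions of the modelled
    construct: a 75 x Ø12 x 2 mm-wall interlocking nail with Ø3.7 mm
    locking screws, an ~1 mm debrided articular gap, a 2.5 +/- 0.4 mm
    cortical shell, and a pivot point 17 mm below the heel to account for
    soft tissue.  ``elem_size`` controls the structured mesh resolution
    (1.44 mm matches the reference discretization; coarser values are used
    for fast probabilistic sweeps).
    """

    lower_block_size: tuple[float, float, float] = (40.0, 48.0, 30.0)
    upper_block_size: tuple[float, float, float] = (40.0, 30.0, 30.0)
    cortical_thickness: float = 2.5
    cortical_thickness_sd: float = 0.4
    gap_width: float = 1.0
    gap_curvature_radius: float = 40.0
    nail_length: float = 75.0
    nail_outer_diameter: float = 12.0
    nail_wall: float = 2.0
    nail_offset_x: float = -8.0
    nail_entry_offset: float = 2.0
    screw_diameter: float = 3.7
    screw_positions: tuple[float, ...] = (12.0, 30.0, 55.0)
    screw_length: float = 26.0  # bicortical: ends anchor in the cortical shell
    pmma_pad_depth: float = 6.0
    pmma_pad_height: float = 22.0
    pmma_pad_width: float = 26.0
    soft_tissue_offset: float = 17.0
    load_center_x: float = 4.0
    load_patch_half: tuple[float, float] = (6.0, 12.0)
    elem_size: float = 1.44

    def validate(self) -> None:
        if self.gap_width <= 0:
            raise ValueError("gap_width must be positive")
        if self.cortical_thickness <= 0:
            raise ValueError("cortical_thickness must be positive")
        if self.nail_outer_diameter <= 2 * self.nail_wall:
            raise ValueError("nail_outer_diameter must exceed twice the wall")
        wx_l, h_l, wz_l = self.lower_block_size
        wx_u, h_u, wz_u = self.upper_block_size
        total = h_l + self.gap_width + h_u
        if self.nail_entry_offset + self.nail_length > total - 2.0:
            raise ValueError(
                f"nail ({self.nail_length} mm from entry offset "
                f"{self.nail_entry_offset} mm) is longer than the assembly "
                f"({total} mm) allows"
            )
        if abs(self.nail_offset_x) + self.nail_outer_diameter / 2 > wx_l / 2:
            raise ValueError("nail axis lies outside the bone blocks")
        r = self.gap_curvature_radius
        if r <= wx_l / 2:
            raise ValueError("gap_curvature_radius must exceed half the block width")
        sag = r - np.sqrt(r**2 - (wx_l / 2) ** 2)
        if sag > 0.2 * h_l:
            raise ValueError("articular curvature too strong for block height")
        gap_lo, gap_hi = h_l - sag, h_l + self.gap_width
        for i, s in enumerate(self.screw_positions):
            y = self.nail_entry_offset + s
            if not (0.0 < s < self.nail_length):
                raise ValueError(f"screw {i + 1} station {s} outside the nail span")
            rs = self.screw_diameter / 2
            if gap_lo - rs - 1.0 < y < gap_hi + rs + 1.0:
                raise ValueError(
                    f"screw {i + 1} at height {y:.1f} mm crosses the joint gap"
                )
            if not (1.0 < y < total - 1.0):
                raise ValueError(f"screw {i + 1} lies outside the bone stack")


# ---------------------------------------------------------------------------
# arthrodesis model


def build_arthrodesis_model(params: ModelParams | None = None) -> Mesh:
    """Build the meshed synthetic arthrodesis assembly.

    Returns a :class:`Mesh` with material element sets
    ``{cortical,cancellous}_{lower,upper}, nail, screw_1..3, pmma``,
    surface sets ``articular_{lower,upper}`` (plus posterior/central/anterior
    labeled subregions of the lower articular facet), ``support``,
    ``load_coupling``, ``pivot_coupling``, reference points ``load`` and
    ``pivot``, and tie records coupling the screws into nail and bone.
    """
    p = params or ModelParams()
    p.validate()
    h = p.elem_size
    wx_l, h_l, wz_l = p.lower_block_size
    wx_u, h_u, wz_u = p.upper_block_size
    r_art = p.gap_curvature_radius
    y_center = h_l - r_art  # articular cylinder axis height (axis along z)
    y_up0 = h_l + p.gap_width

    def y_top_lower(x):
        return y_center + np.sqrt(r_art**2 - np.minimum(x, wx_l / 2) ** 2)

    def y_bot_upper(x):
        return y_center + np.sqrt(
            (r_art + p.gap_width) ** 2 - np.minimum(x, wx_l / 2) ** 2
        )

    pad = dict(depth=p.pmma_pad_depth, height=p.pmma_pad_height, width=p.pmma_pad_width)
    # pads stay clear of the articular warp zones (top 25% / bottom 30%)
    pad_lo_y = (0.25 * h_l, min(0.25 * h_l + pad["height"], 0.72 * h_l))
    pad_up_y = (
        y_up0 + 0.32 * h_u,
        min(y_up0 + 0.32 * h_u + pad["height"], y_up0 + h_u - 1.0),
    )

    def pad_mask(c, x_face, ylim):
        return (
            (c[:, 0] >= x_face)
            & (c[:, 1] >= ylim[0])
            & (c[:, 1] <= ylim[1])
            & (np.abs(c[:, 2]) <= pad["width"] / 2)
        )

    # lower body: bone block + anterior PMMA pad on one structured grid
    def mask_lower(c):
        return (c[:, 0] < wx_l / 2) | pad_mask(c, wx_l / 2, pad_lo_y)

    n_lo, t_lo, c_lo = box_grid(
        (-wx_l / 2, 0.0, -wz_l / 2),
        (wx_l + pad["depth"], h_l, wz_l),
        h,
        mask_lower,
    )
    # warp the top 25% of the bone columns onto the articular cylinder
    yb = 0.75 * h_l
    sel = n_lo[:, 1] > yb + 1e-9
    xs = np.abs(n_lo[sel, 0])
    n_lo[sel, 1] = yb + (n_lo[sel, 1] - yb) * (y_top_lower(xs) - yb) / (h_l - yb)

    def mask_upper(c):
        return (c[:, 0] < wx_u / 2) | pad_mask(c, wx_u / 2, pad_up_y)

    n_up, t_up, c_up = box_grid(
        (-wx_u / 2, y_up0, -wz_u / 2),
        (wx_u + pad["depth"], h_u, wz_u),
        h,
        mask_upper,
    )
    yt = y_up0 + 0.30 * h_u
    sel = n_up[:, 1] < yt - 1e-9
    xs = np.abs(n_up[sel, 0])
    n_up[sel, 1] = yt - (yt - n_up[sel, 1]) * (yt - y_bot_upper(xs)) / (yt - y_up0)
    t_lo = orient_positive(n_lo, t_lo)
    t_up = orient_positive(n_up, t_up)

    ro, ri = p.nail_outer_diameter / 2, p.nail_outer_diameter / 2 - p.nail_wall
    n_nail, t_nail = tube_grid(
        ri, ro, p.nail_length, min(h, 1.75),
        axis_origin=(p.nail_offset_x, p.nail_entry_offset, 0.0), axis="y",
    )

    screws = []
    rs = p.screw_diameter / 2
    for s in p.screw_positions:
        # axial spacing <= 1 mm so node layers exist inside the nail wall
        ns, ts = cylinder_grid(
            rs, p.screw_length, min(h, 1.0),
            n_rings=1 if rs < h else 2,
            axis_origin=(p.nail_offset_x, p.nail_entry_offset + s, -p.screw_length / 2),
            axis="z",
        )
        screws.append((ns, ts))

    parts = [(n_lo, t_lo), (n_up, t_up), (n_nail, t_nail)] + screws
    nodes, tets, node_off, elem_off = merge_meshes(parts)
    nodes10, elems10, edge_keys = quadratic_from_linear(nodes, tets)
    n_lin = len(nodes)

    mesh = Mesh(nodes=nodes10, elements=elems10)

    # -- element sets ------------------------------------------------------
    def classify_block(cents, lower: bool):
        """cortical / cancellous / pmma labels from cell centroids."""
        wx = wx_l if lower else wx_u
        wz = wz_l if lower else wz_u
        # the shell is at least one element layer thick at any resolution
        # (a cortical shell that vanishes on coarse meshes would change the
        # load path qualitatively, not just in accuracy)
        t0 = max(p.cortical_thickness, 0.55 * h)
        t_art = t0 + p.cortical_thickness_sd   # thickened at articular facets
        t_sup = max(t0 - p.cortical_thickness_sd, 0.55 * h)  # thinned at support
        x, y, z = cents[:, 0], cents[:, 1], cents[:, 2]
        pmma = x > wx / 2
        rad = np.hypot(x, y - y_center)
        if lower:
            d_art = r_art - rad
            d_faces = np.minimum.reduce([x + wx / 2, y, wz / 2 - np.abs(z)])
        else:
            d_art = rad - (r_art + p.gap_width)
            d_faces = np.minimum.reduce(
                [x + wx / 2, (y_up0 + h_u) - y, wz / 2 - np.abs(z)]
            )
        d_sup = wx / 2 - x
        cort = (d_art < t_art) | (d_faces < t0) | (d_sup < t_sup)
        labels = np.where(pmma, 2, np.where(cort, 0, 1))
        return labels

    esets: dict[str, list] = {k: [] for k in MATERIAL_SETS}
    for body, (cents, lower) in enumerate([(c_lo, True), (c_up, False)]):
        labels = classify_block(cents, lower)
        eids = elem_off[body] + np.arange(6 * len(cents))
        lab_e = np.repeat(labels, 6)
        suffix = "lower" if lower else "upper"
        esets[f"cortical_{suffix}"].append(eids[lab_e == 0])
        esets[f"cancellous_{suffix}"].append(eids[lab_e == 1])
        esets["pmma"].append(eids[lab_e == 2])
    esets["nail"].append(elem_off[2] + np.arange(len(t_nail)))
    for i, (_, ts) in enumerate(screws):
        esets[f"screw_{i + 1}"].append(elem_off[3 + i] + np.arange(len(ts)))
    mesh.element_sets = {
        k: np.sort(np.concatenate(v)) if v else np.empty(0, dtype=int)
        for k, v in esets.items()
    }

    # -- surface sets ------------------------------------------------------
    def body_boundary(body):
        lo = elem_off[body]
        hi = elem_off[body + 1] if body + 1 < len(elem_off) else len(tets)
        faces, owners = boundary_faces(tets[lo:hi])
        return faces, owners + lo

    def face_data(faces):
        tri = nodes[faces]
        cen = tri.mean(axis=1)
        cr = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        nrm = cr / np.linalg.norm(cr, axis=1, keepdims=True)
        return cen, nrm

    ssets: dict[str, np.ndarray] = {}

    f_lo, _ = body_boundary(0)
    cen, nrm = face_data(f_lo)
    art_lo = (nrm[:, 1] > 0.6) & (cen[:, 1] > yb) & (cen[:, 0] < wx_l / 2)
    ssets["articular_lower"] = f_lo[art_lo]
    thirds = np.digitize(cen[art_lo, 0], [-wx_l / 6, wx_l / 6])
    for j, name in enumerate(["posterior", "central", "anterior"]):
        ssets[f"articular_lower_{name}"] = f_lo[art_lo][thirds == j]
    piv = (nrm[:, 1] < -0.9) & (cen[:, 0] < -wx_l / 2 + 0.3 * wx_l)
    ssets["pivot_coupling"] = f_lo[piv]
    sup_lo = nrm[:, 0] > 0.9
    sup_lo &= cen[:, 0] > wx_l / 2 + pad["depth"] - 0.6 * h

    f_up, _ = body_boundary(1)
    cen_u, nrm_u = face_data(f_up)
    art_up = (nrm_u[:, 1] < -0.6) & (cen_u[:, 1] < yt) & (cen_u[:, 0] < wx_u / 2)
    ssets["articular_upper"] = f_up[art_up]
    hx, hz = p.load_patch_half
    load = (
        (nrm_u[:, 1] > 0.9)
        & (np.abs(cen_u[:, 0] - p.load_center_x) <= hx)
        & (np.abs(cen_u[:, 2]) <= hz)
    )
    ssets["load_coupling"] = f_up[load]
    sup_up = nrm_u[:, 0] > 0.9
    sup_up &= cen_u[:, 0] > wx_u / 2 + pad["depth"] - 0.6 * h
    ssets["support"] = np.vstack([f_lo[sup_lo], f_up[sup_up]])

    for name, faces in ssets.items():
        if len(faces) == 0 and not name.startswith("articular_lower_"):
            raise ValueError(f"surface set '{name}' came out empty; refine elem_size")
    mesh.surface_sets = {
        k: facets_quadratic(v, edge_keys, n_lin) if len(v) else np.empty((0, 6), int)
        for k, v in ssets.items()
    }

    mesh.reference_points = {
        "load": np.array([p.load_center_x, y_up0 + h_u, 0.0]),
        "pivot": np.array(
            [-wx_l / 2 + 0.15 * wx_l, -p.soft_tissue_offset, 0.0]
        ),
        "nail_entry": np.array([p.nail_offset_x, p.nail_entry_offset, 0.0]),
        "gap_center": np.array(
            [p.nail_offset_x, h_l + p.gap_width / 2, 0.0]
        ),
    }

    # -- tie constraints: screws embedded in nail and bone -----------------
    mesh.ties = _screw_ties(mesh, elem_off, p)
    mesh.check_valid(MATERIAL_SETS)
    return mesh


def _screw_ties(mesh: Mesh, elem_off, p: ModelParams) -> np.ndarray:
    """(slave_node, host_elem, lam0..3) records embedding the screws.

    Every screw node (corner and midside) is coupled to the displacement
    field of the body that physically surrounds it: the nail where the node
    sits inside the nail wall annulus, the bone outside the nail, and
    nothing inside the hollow bore.  This is the only load path between the
    nail and the bones, which localizes load transfer at the locking screws
    the way interlocking actually works.
    """
    axis_pt = np.array([p.nail_offset_x, 0.0, 0.0])
    ro = p.nail_outer_diameter / 2
    ri = ro - p.nail_wall
    hosts_bone = {
        "lower": np.arange(elem_off[0], elem_off[1]),
        "upper": np.arange(elem_off[1], elem_off[2]),
    }
    nail_elems = np.arange(elem_off[2], elem_off[3])
    recs = []
    for i in range(len(p.screw_positions)):
        ids = np.unique(mesh.elements[mesh.element_sets[f"screw_{i + 1}"]])
        pts = mesh.nodes[ids]
        r_ax = np.hypot(pts[:, 0] - axis_pt[0], pts[:, 2] - axis_pt[2])
        in_wall = (r_ax >= ri - 0.25) & (r_ax <= ro + 0.25)
        in_bore = r_ax < ri - 0.25
        outside = ~(in_wall | in_bore)
        # wall-zone nodes -> nail (tolerant: the faceted annulus is thinner
        # than the true wall near its chord faces)
        el, lam = mesh.locate_points(pts[in_wall], nail_elems, tol=0.08)
        for nd, e, l4 in zip(ids[in_wall][el >= 0], el[el >= 0], lam[el >= 0]):
            recs.append((nd, e, *l4))
        # outside nodes -> containing bone block
        for side, helems in hosts_bone.items():
            el, lam = mesh.locate_points(pts[outside], helems, tol=1e-3)
            ok = el >= 0
            for nd, e, l4 in zip(ids[outside][ok], el[ok], lam[ok]):
                recs.append((nd, e, *l4))
    if not recs:
        raise ValueError("no tie constraints found for the screws")
    return np.array(recs)


# ---------------------------------------------------------------------------
# verification fixtures


def build_verification_fixture(kind: str, **kw) -> Mesh:
    """Closed-form verification geometries for solver and postprocessing tests.

    kinds: ``patch_block`` (single-material cube with named traction faces),
    ``cantilever_tube`` (hollow cylinder with the nail's dimensions, clamped
    end, along global x), ``contact_blocks`` (two stacked blocks with a plane
    gap), ``analytic_surface_pair`` (two surface meshes with a closed-form
    nearest-point map; ``variant='planes'|'spheres'``, ``distance=d``).
    """
    builders = {
        "patch_block": _patch_block,
        "cantilever_tube": _cantilever_tube,
        "contact_blocks": _contact_blocks,
        "analytic_surface_pair": _analytic_surface_pair,
    }
    if kind not in builders:
        raise ValueError(f"unknown fixture kind '{kind}'")
    return builders[kind](**kw)


def _finish_single_body(nodes, tets, set_name, face_rules):
    nodes10, elems10, edge_keys = quadratic_from_linear(nodes, tets)
    mesh = Mesh(nodes=nodes10, elements=elems10)
    mesh.element_sets = {set_name: np.arange(len(tets))}
    faces, _ = boundary_faces(tets)
    tri = nodes[faces]
    cen, cr = tri.mean(axis=1), np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    nrm = cr / np.linalg.norm(cr, axis=1, keepdims=True)
    for name, rule in face_rules.items():
        sel = rule(cen, nrm)
        mesh.surface_sets[name] = facets_quadratic(
            faces[sel], edge_keys, len(nodes)
        )
    return mesh


def _patch_block(size: float = 10.0, elem_size: float = 2.5):
    nodes, tets, _ = box_grid((0, 0, 0), (size, size, size), elem_size)
    rules = {}
    for ax, lab in zip(range(3), "xyz"):
        for sgn, word in [(-1, "min"), (1, "max")]:
            rules[f"face_{lab}{word}"] = (
                lambda c, n, ax=ax, sgn=sgn: n[:, ax] * sgn > 0.9
            )
    return _finish_single_body(nodes, tets, "block", rules)


def _cantilever_tube(elem_size: float = 1.75, length: float = 75.0,
                     outer_diameter: float = 12.0, wall: float = 2.0):
    ro, ri = outer_diameter / 2, outer_diameter / 2 - wall
    nodes, tets = tube_grid(ri, ro, length, elem_size, axis="x")
    rules = {
        "clamp": lambda c, n: n[:, 0] < -0.9,
        "tip": lambda c, n: n[:, 0] > 0.9,
    }
    mesh = _finish_single_body(nodes, tets, "nail", rules)
    mesh.reference_points["nail_entry"] = np.array([0.0, 0.0, 0.0])
    mesh.reference_points["tip_center"] = np.array([length, 0.0, 0.0])
    return mesh


def _contact_blocks(size=(10.0, 5.0, 10.0), gap: float = 0.05,
                    elem_size: float = 2.5):
    wx, hy, wz = size
    n1, t1, _ = box_grid((0, 0, 0), size, elem_size)
    n2, t2, _ = box_grid((0, hy + gap, 0), size, elem_size)
    nodes, tets, node_off, elem_off = merge_meshes([(n1, t1), (n2, t2)])
    nodes10, elems10, edge_keys = quadratic_from_linear(nodes, tets)
    mesh = Mesh(nodes=nodes10, elements=elems10)
    mesh.element_sets = {
        "block_lower": np.arange(elem_off[1]),
        "block_upper": np.arange(elem_off[1], len(tets)),
    }
    ssets = {}
    for body, (lo, hi) in enumerate([(0, elem_off[1]), (elem_off[1], len(tets))]):
        faces, _ = boundary_faces(tets[lo:hi])
        tri = nodes[faces]
        cr = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        nrm = cr / np.linalg.norm(cr, axis=1, keepdims=True)
        if body == 0:
            ssets["bottom"] = faces[nrm[:, 1] < -0.9]
            ssets["contact_lower"] = faces[nrm[:, 1] > 0.9]
        else:
            ssets["top"] = faces[nrm[:, 1] > 0.9]
            ssets["contact_upper"] = faces[nrm[:, 1] < -0.9]
    mesh.surface_sets = {
        k: facets_quadratic(v, edge_keys, len(nodes)) for k, v in ssets.items()
    }
    return mesh


def _surface_only_mesh(parts):
    """Mesh with no volume elements, only named quadratic surface facets."""
    all_nodes, ssets = [], {}
    off = 0
    for name, (nodes, tris) in parts.items():
        edges = np.vstack(
            [tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]
        )
        keys = np.sort(edges, axis=1)
        uniq, inv = np.unique(keys, axis=0, return_inverse=True)
        mids = 0.5 * (nodes[uniq[:, 0]] + nodes[uniq[:, 1]])
        mid_ids = len(nodes) + inv.reshape(3, len(tris)).T
        facets = np.hstack([tris, mid_ids]) + off
        all_nodes.append(np.vstack([nodes, mids]))
        ssets[name] = facets
        off += len(nodes) + len(mids)
    mesh = Mesh(
        nodes=np.vstack(all_nodes), elements=np.empty((0, 10), dtype=int)
    )
    mesh.surface_sets = ssets
    return mesh


def _analytic_surface_pair(variant: str = "planes", distance: float = 1.0,
                           elem_size: float = 1.0, extent: float = 10.0,
                           radius: float = 30.0):
    if variant == "planes":
        def plane(y, flip):
            n = max(2, round(extent / elem_size))
            g = np.linspace(-extent / 2, extent / 2, n + 1)
            xx, zz = np.meshgrid(g, g, indexing="ij")
            nodes = np.column_stack([xx.ravel(), np.full(xx.size, y), zz.ravel()])
            tris = []
            for i in range(n):
                for j in range(n):
                    a = i * (n + 1) + j
                    b, c, d = a + 1, a + n + 1, a + n + 2
                    tris += [(a, b, d), (a, d, c)]
            tris = np.array(tris)
            if flip:  # wind so the normal points from the upper body downward
                tris = tris[:, ::-1]
            return nodes, tris

        return _surface_only_mesh(
            {"lower": plane(0.0, False), "upper": plane(distance, True)}
        )
    if variant == "spheres":
        def cap(r, flip):
            n = max(2, round(extent / elem_size))
            g = np.linspace(-extent / 2, extent / 2, n + 1)
            xx, zz = np.meshgrid(g, g, indexing="ij")
            yy = np.sqrt(r**2 - xx**2 - zz**2)
            nodes = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
            tris = []
            for i in range(n):
                for j in range(n):
                    a = i * (n + 1) + j
                    b, c, d = a + 1, a + n + 1, a + n + 2
                    tris += [(a, b, d), (a, d, c)]
            tris = np.array(tris)
            if flip:
                tris = tris[:, ::-1]
            return nodes, tris

        mesh = _surface_only_mesh(
            {"lower": cap(radius, False), "upper": cap(radius + distance, True)}
        )
        mesh.reference_points["sphere_center"] = np.zeros(3)
        return mesh
    raise ValueError(f"unknown analytic_surface_pair variant '{variant}'")
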