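"""C3D10 element kernels: shape functions, stiffness assembly, stress recovery.

Straight-sided 10-node tetrahedra with a 4-point Gauss rule (exact for the
quadratic-displacement stiffness integrand on straight elements).  Voigt
stress/strain order is (xx, yy, zz, xy, yz, xz) with engineering shear
strains.  Units: mm, N, MPa.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .mesh import EDGE_CORNERS, Mesh

_A = (5.0 + 3.0 * np.sqrt(5.0)) / 20.0
_B = (5.0 - np.sqrt(5.0)) / 20.0
#: 4-point quadrature in barycentric coordinates, weights 1/4 each
QUAD_LAM = np.array(
    [
        [_A, _B, _B, _B],
        [_B, _A, _B, _B],
        [_B, _B, _A, _B],
        [_B, _B, _B, _A],
    ]
)


def shape(lam: np.ndarray) -> np.ndarray:
    """Shape function values N (..., 10) at barycentric points (..., 4)."""
    lam = np.asarray(lam)
    out = np.empty(lam.shape[:-1] + (10,))
    for i in range(4):
        out[..., i] = lam[..., i] * (2 * lam[..., i] - 1)
    for k, (a, b) in enumerate(EDGE_CORNERS):
        out[..., 4 + k] = 4 * lam[..., a] * lam[..., b]
    return out


def dshape_dlam(lam: np.ndarray) -> np.ndarray:
    """dN/dlambda (..., 10, 4) at barycentric points (..., 4)."""
    lam = np.asarray(lam)
    out = np.zeros(lam.shape[:-1] + (10, 4))
    for i in range(4):
        out[..., i, i] = 4 * lam[..., i] - 1
    for k, (a, b) in enumerate(EDGE_CORNERS):
        out[..., 4 + k, a] = 4 * lam[..., b]
        out[..., 4 + k, b] = 4 * lam[..., a]
    return out


def grad_lam(x: np.ndarray) -> np.ndarray:
    """Barycentric-coordinate gradients (m, 4, 3) from (m, 4, 3) corners."""
    a = np.swapaxes(x[:, 1:] - x[:, :1], 1, 2)  # columns are edge vectors
    ainv = np.linalg.inv(a)
    g = np.empty((len(x), 4, 3))
    g[:, 1:] = ainv
    g[:, 0] = -ainv.sum(axis=1)
    return g


def elasticity_matrix(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Isotropic 6x6 elasticity matrices (m, 6, 6) in Voigt order."""
    E, nu = np.broadcast_arrays(np.asarray(E, float), np.asarray(nu, float))
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros(E.shape + (6, 6))
    for i in range(3):
        for j in range(3):
            D[..., i, j] = lam
        D[..., i, i] += 2 * mu
        D[..., 3 + i, 3 + i] = mu
    return D


def _b_matrices(dndx: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (m, 6, 30) from dN/dx (m, 10, 3)."""
    m = dndx.shape[0]
    B = np.zeros((m, 6, 30))
    gx, gy, gz = dndx[..., 0], dndx[..., 1], dndx[..., 2]
    B[:, 0, 0::3] = gx
    B[:, 1, 1::3] = gy
    B[:, 2, 2::3] = gz
    B[:, 3, 0::3] = gy
    B[:, 3, 1::3] = gx
    B[:, 4, 1::3] = gz
    B[:, 4, 2::3] = gy
    B[:, 5, 0::3] = gz
    B[:, 5, 2::3] = gx
    return B


def element_dof_ids(elements: np.ndarray) -> np.ndarray:
    """(m, 30) global dof ids, node-major xyz ordering."""
    return (3 * elements[:, :, None] + np.arange(3)).reshape(len(elements), 30)


def assemble_stiffness(
    mesh: Mesh, E_elem: np.ndarray, nu_elem: np.ndarray, chunk: int = 5000
) -> sp.csr_matrix:
    """Assemble the global stiffness matrix (3n x 3n CSR)."""
    n_dof = 3 * mesh.n_nodes
    dNdl = dshape_dlam(QUAD_LAM)  # (4, 10, 4)
    blocks = []
    for lo in range(0, mesh.n_elements, chunk):
        sel = np.arange(lo, min(lo + chunk, mesh.n_elements))
        x = mesh.corner_coords(sel)
        vol = np.abs(np.linalg.det(x[:, 1:] - x[:, :1])) / 6.0
        g = grad_lam(x)  # (m, 4, 3)
        D = elasticity_matrix(E_elem[sel], nu_elem[sel])
        ke = np.zeros((len(sel), 30, 30))
        for q in range(4):
            dndx = np.einsum("nk,mkd->mnd", dNdl[q], g)
            B = _b_matrices(dndx)
            ke += 0.25 * np.einsum(
                "m,mia,mij,mjb->mab", vol, B, D, B, optimize=True
            )
        dofs = element_dof_ids(mesh.elements[sel])
        rows = np.repeat(dofs, 30, axis=1).ravel()
        cols = np.tile(dofs, (1, 30)).ravel()
        blocks.append(
            sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n_dof, n_dof)).tocsr()
        )
    K = blocks[0]
    for b in blocks[1:]:
        K = K + b
    return K


def element_stresses(
    mesh: Mesh, u: np.ndarray, E_elem: np.ndarray, nu_elem: np.ndarray,
    chunk: int = 20000,
) -> np.ndarray:
    """Element-averaged stress tensors (m, 6): mean over integration points.

    Equal quadrature weights on straight tets make this the volume-weighted
    integration-point average used for all reported stress maxima.
    """
    dNdl_avg = dshape_dlam(QUAD_LAM).mean(axis=0)  # average B is exact here:
    # B is linear in lambda, so averaging dN/dlam over the symmetric rule
    # equals evaluating at the centroid.
    out = np.empty((mesh.n_elements, 6))
    ue_flat = u.reshape(-1)
    for lo in range(0, mesh.n_elements, chunk):
        sel = np.arange(lo, min(lo + chunk, mesh.n_elements))
        x = mesh.corner_coords(sel)
        g = grad_lam(x)
        dndx = np.einsum("nk,mkd->mnd", dNdl_avg, g)
        B = _b_matrices(dndx)
        D = elasticity_matrix(E_elem[sel], nu_elem[sel])
        ue = ue_flat[element_dof_ids(mesh.elements[sel])]
        out[sel] = np.einsum("mij,mja,ma->mi", D, B, ue, optimize=True)
    return out


def stress_at(
    mesh: Mesh, u: np.ndarray, E_elem: np.ndarray, nu_elem: np.ndarray,
    elem_ids: np.ndarray, lams: np.ndarray,
) -> np.ndarray:
    """Stress tensors (k, 6) at arbitrary in-element barycentric points."""
    elem_ids = np.asarray(elem_ids)
    x = mesh.corner_coords(elem_ids)
    g = grad_lam(x)
    dndl = dshape_dlam(np.asarray(lams))  # (k, 10, 4)
    dndx = np.einsum("mnk,mkd->mnd", dndl, g)
    B = _b_matrices(dndx)
    D = elasticity_matrix(E_elem[elem_ids], nu_elem[elem_ids])
    ue = u.reshape(-1)[element_dof_ids(mesh.elements[elem_ids])]
    return np.einsum("mij,mja,ma->mi", D, B, ue, optimize=True)


# ---------------------------------------------------------------------------
# surface utilities


def consistent_traction(
    mesh: Mesh, surface: str, traction: np.ndarray
) -> np.ndarray:
    """Consistent nodal load vector (3n,) for a constant traction (3,).

    On straight quadratic triangles the consistent load puts A/3 on each
    midside node and nothing on the corners.
    """
    f = np.zeros(3 * mesh.n_nodes)
    facets = mesh.surface_sets[surface]
    area, _ = mesh.facet_areas_normals(surface)
    for k in range(3):
        nid = facets[:, 3 + k]
        for c in range(3):
            np.add.at(f, 3 * nid + c, traction[c] * area / 3.0)
    return f


def nodal_areas(mesh: Mesh, surface: str) -> tuple[np.ndarray, np.ndarray]:
    """Tributary areas of all nodes of a surface set.

    Each quadratic facet is subdivided into its four corner/midside
    sub-triangles and a third of each sub-triangle area is attributed to its
    vertices.  Returns ``(node_ids, areas)``.
    """
    facets = mesh.surface_sets[surface]
    subs = np.concatenate(
        [
            facets[:, [0, 3, 5]],
            facets[:, [1, 4, 3]],
            facets[:, [2, 5, 4]],
            facets[:, [3, 4, 5]],
        ]
    )
    tri = mesh.nodes[subs]
    area = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    ids = np.unique(facets)
    acc = np.zeros(mesh.n_nodes)
    for c in range(3):
        np.add.at(acc, subs[:, c], area / 3.0)
    return ids, acc[ids]
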