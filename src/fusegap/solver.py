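"""Linear-elastic boundary-value solver with frictional contact.

Small-strain kinematics on quadratic tetrahedra; the only nonlinearity is
the articular penalty contact (node-to-surface, Coulomb friction), resolved
by an active-set / semi-smooth iteration.  Kinematic couplings (rigid load
application, the soft-tissue pivot) are handled by constraint elimination;
screw-to-bone/nail ties by stiff penalty springs scaled with the largest
sampled modulus so that uniform stiffness scaling leaves the problem shape
invariant.

Load convention: the vertical stance force is rotated by the hindfoot tilt
angle phi about the anterior-posterior x-axis while the mesh stays fixed:
F(phi) = force_magnitude * (0, -cos phi, -sin phi).  Negative phi is
inversion, positive eversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import elements
from .gap import pair_surfaces
from .mesh import Mesh


@dataclass
class LoadCase:
    """One tilt configuration of the single-leg-stance load."""

    phi: float = 0.0                     #: degrees, in [-20, 10]
    force_magnitude: float = 650.0       #: N
    load_ref: str | None = "load"        #: reference point of the load coupling
    load_surface: str = "load_coupling"
    pivot_ref: str | None = "pivot"
    pivot_surface: str = "pivot_coupling"
    pivot_axis: tuple = (0.0, 0.0, 1.0)  #: the single free rotation (transverse)
    fixed_surfaces: tuple = ("support",)
    rollers: tuple = ()                  #: (surface, component) single-dof fixes
    tractions: dict = field(default_factory=dict)  #: surface -> (3,) constant
    #: generalized loads (Fx,Fy,Fz,Mx,My,Mz) applied at coupling ref points
    ref_loads: dict = field(default_factory=dict)
    #: apply the tilted stance force at the load reference point
    apply_stance_force: bool = True

    def __post_init__(self):
        if self.force_magnitude <= 0:
            raise ValueError("force_magnitude must be positive")
        if not -20.0 - 1e-9 <= self.phi <= 10.0 + 1e-9:
            raise ValueError("phi outside the physiological range [-20, 10] deg")

    @property
    def force_vector(self) -> np.ndarray:
        """Applied force, rotated by phi about the anterior (x) axis."""
        r = np.radians(self.phi)
        return self.force_magnitude * np.array([0.0, -np.cos(r), -np.sin(r)])


@dataclass
class ContactParams:
    """Penalty-contact settings (defaults follow mu = 0.3 sliding friction)."""

    friction_mu: float = 0.3
    penalty_normal: float | None = None      #: N/mm^3; default 100 E_max / h
    penalty_tangential: float | None = None  #: default = penalty_normal / 10
    tie_penalty: float | None = None         #: N/mm; default 100 E_max h
    max_newton_iter: int = 30
    tol_residual: float = 1e-9

    def __post_init__(self):
        if self.friction_mu < 0:
            raise ValueError("friction_mu must be >= 0")


@dataclass
class Solution:
    """Displacement/stress fields and diagnostics of one solve."""

    u: np.ndarray                 #: (n, 3) nodal displacements, mm
    stress: np.ndarray            #: (m, 6) element-average stress, MPa, Voigt
    converged: bool
    iterations: int
    residual: float               #: relative force residual at free dofs
    reaction_force: np.ndarray    #: (3,) net reaction at fixed+pivot dofs, N
    applied_force: np.ndarray     #: (3,) applied load, N
    contact_active: dict = field(default_factory=dict)  #: pair -> bool array
    master_motion: dict = field(default_factory=dict)   #: ref point -> (6,)

    @property
    def equilibrium_residual(self) -> float:
        fa = np.linalg.norm(self.applied_force)
        return float(np.linalg.norm(self.reaction_force + self.applied_force) / fa)


# ---------------------------------------------------------------------------
# boundary conditions


@dataclass
class BCSet:
    """Assembled boundary-condition set: reduction map + load vectors."""

    T: sp.csr_matrix              #: full-dof = T @ reduced-dof
    f_red: np.ndarray             #: reduced external load vector
    f_full: np.ndarray            #: structural (traction) part of the load
    fixed_mask: np.ndarray        #: (3n,) bool, eliminated dofs
    constrained_nodes: np.ndarray  #: nodes carrying reactions
    master_cols: dict             #: ref name -> (column ids, free component ids)


def apply_load_case(mesh: Mesh, lc: LoadCase) -> BCSet:
    """Translate a :class:`LoadCase` into a dof reduction and load vectors."""
    n = mesh.n_nodes
    ndof = 3 * n
    fixed = np.zeros(ndof, dtype=bool)
    for s in lc.fixed_surfaces:
        _require_surface(mesh, s)
        ids = np.unique(mesh.surface_sets[s])
        fixed[(3 * ids[:, None] + np.arange(3)).ravel()] = True
    for s, comp in lc.rollers:
        _require_surface(mesh, s)
        ids = np.unique(mesh.surface_sets[s])
        fixed[3 * ids + comp] = True

    couplings = []  # (name, ref_xyz, node_ids, free_translations, free_rotations)
    if lc.load_ref is not None:
        _require_surface(mesh, lc.load_surface)
        couplings.append(
            (
                lc.load_ref,
                mesh.reference_points[lc.load_ref],
                np.unique(mesh.surface_sets[lc.load_surface]),
                [0, 1, 2],
                [0, 1, 2],
            )
        )
    if lc.pivot_ref is not None:
        _require_surface(mesh, lc.pivot_surface)
        axis = np.asarray(lc.pivot_axis, dtype=float)
        axis /= np.linalg.norm(axis)
        couplings.append(
            (
                lc.pivot_ref,
                mesh.reference_points[lc.pivot_ref],
                np.unique(mesh.surface_sets[lc.pivot_surface]),
                [],
                [axis],
            )
        )

    coupled = np.zeros(n, dtype=bool)
    for _, _, ids, _, _ in couplings:
        if coupled[ids].any():
            raise ValueError("surfaces of two couplings overlap")
        coupled[ids] = True

    struct_free = ~fixed
    struct_free &= ~np.repeat(coupled, 3)
    n_free = int(struct_free.sum())

    rows = [np.flatnonzero(struct_free)]
    cols = [np.arange(n_free)]
    vals = [np.ones(n_free)]
    col0 = n_free
    master_cols = {}
    for name, ref, ids, ftrans, frots in couplings:
        d = mesh.nodes[ids] - ref  # (k, 3)
        this_cols = []
        for t_axis in ftrans:
            rows.append(3 * ids + t_axis)
            cols.append(np.full(len(ids), col0))
            vals.append(np.ones(len(ids)))
            this_cols.append(col0)
            col0 += 1
        for rot in frots:
            e = np.zeros(3)
            if isinstance(rot, int):
                e[rot] = 1.0
            else:
                e = np.asarray(rot)
            w = np.cross(e[None, :], d)  # u = theta * (e x d)
            rows.append((3 * ids[:, None] + np.arange(3)).ravel())
            cols.append(np.full(3 * len(ids), col0))
            vals.append(w.ravel())
            this_cols.append(col0)
            col0 += 1
        master_cols[name] = (this_cols, (ftrans, frots))
    T = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, col0),
    ).tocsr()

    f_full = np.zeros(ndof)
    for s, trac in lc.tractions.items():
        f_full += elements.consistent_traction(mesh, s, np.asarray(trac, float))
    f_red = T.T @ f_full
    if lc.load_ref is not None and lc.apply_stance_force:
        cols_load, (ftrans, _) = master_cols[lc.load_ref]
        F = lc.force_vector
        for j, t_axis in enumerate(ftrans):
            f_red[cols_load[j]] += F[t_axis]
    for name, gen in lc.ref_loads.items():
        cols_ref, (ftrans, frots) = master_cols[name]
        gen = np.asarray(gen, dtype=float)
        j = 0
        for t_axis in ftrans:
            f_red[cols_ref[j]] += gen[t_axis]
            j += 1
        for rot in frots:
            e = np.zeros(3)
            if isinstance(rot, int):
                e[rot] = 1.0
            else:
                e = np.asarray(rot)
            f_red[cols_ref[j]] += float(gen[3:] @ e)
            j += 1

    constrained = np.unique(
        np.concatenate(
            [np.flatnonzero(fixed) // 3]
            + [ids for nm, _, ids, ft, _ in couplings if nm == lc.pivot_ref]
        )
    )
    return BCSet(
        T=T, f_red=f_red, f_full=f_full, fixed_mask=fixed,
        constrained_nodes=constrained, master_cols=master_cols,
    )


def _require_surface(mesh, name):
    if name not in mesh.surface_sets or len(mesh.surface_sets[name]) == 0:
        raise ValueError(f"mesh is missing surface set '{name}'")


# ---------------------------------------------------------------------------
# contact machinery


class _ContactPair:
    """Precomputed node-to-surface data for one contact pair."""

    def __init__(self, mesh: Mesh, slave: str, master: str):
        self.name = f"{slave}|{master}"
        pairing = pair_surfaces(mesh, slave, master)
        self.g0 = pairing.distance.copy()
        ids, areas = elements.nodal_areas(mesh, slave)
        area_of = dict(zip(ids, areas))
        self.area = np.array([area_of[i] for i in pairing.point_ids])
        n = pairing.normal  # oriented master -> slave
        k = len(pairing.point_ids)
        ndof = 3 * mesh.n_nodes
        # tangent basis
        t1 = np.cross(n, np.tile([1.0, 0.0, 0.0], (k, 1)))
        small = np.linalg.norm(t1, axis=1) < 1e-6
        t1[small] = np.cross(n[small], [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
        t2 = np.cross(n, t1)

        def gmat(direc):
            rows, cols, vals = [], [], []
            r = np.arange(k)
            for c in range(3):
                rows.append(r)
                cols.append(3 * pairing.point_ids + c)
                vals.append(direc[:, c])
                for j in range(6):
                    rows.append(r)
                    cols.append(3 * pairing.facet_nodes[:, j] + c)
                    vals.append(-pairing.facet_weights[:, j] * direc[:, c])
            return sp.coo_matrix(
                (
                    np.concatenate(vals),
                    (np.concatenate(rows), np.concatenate(cols)),
                ),
                shape=(k, ndof),
            ).tocsr()

        self.Gn = gmat(n)   # relative normal displacement (slave - master) . n
        self.Gt1, self.Gt2 = gmat(t1), gmat(t2)
        self.k = k


class _ContactState:
    def __init__(self, pairs):
        self.active = {p.name: np.zeros(p.k, dtype=bool) for p in pairs}
        self.slip = {p.name: np.zeros(p.k, dtype=bool) for p in pairs}

    def same(self, other):
        return all(
            np.array_equal(self.active[k], other.active[k])
            and np.array_equal(self.slip[k], other.slip[k])
            for k in self.active
        )


# ---------------------------------------------------------------------------
# assembled model (stiffness reuse across load cases)


class AssembledModel:
    """Stiffness factorization for one material sample, reusable over angles.

    ``materials`` maps element-set names to ``(E, nu)`` pairs; every element
    must be covered.  Contact pairs are (slave_surface, master_surface)
    tuples.  The stiffness (elements + ties) is assembled once; each
    :meth:`solve` reuses the factorization as long as the contact active set
    stays empty, which is the common case for the ~1 mm articular gap.
    """

    def __init__(
        self,
        mesh: Mesh,
        materials: dict[str, tuple[float, float]],
        contact: ContactParams | None = None,
        contact_pairs: tuple = (),
    ):
        self.mesh = mesh
        self.cp = contact or ContactParams()
        self.E_elem = np.full(mesh.n_elements, np.nan)
        self.nu_elem = np.full(mesh.n_elements, np.nan)
        for name, (E, nu) in materials.items():
            if name not in mesh.element_sets:
                continue
            ids = mesh.element_sets[name]
            self.E_elem[ids] = E
            self.nu_elem[ids] = nu
        if np.isnan(self.E_elem).any():
            raise ValueError("materials do not cover every element set")
        self.E_max = float(np.nanmax(self.E_elem))
        self.h_est = float(np.mean(np.abs(self.mesh.volumes())) ** (1 / 3)) * 1.5

        self.K = elements.assemble_stiffness(mesh, self.E_elem, self.nu_elem)
        if mesh.ties is not None and len(mesh.ties):
            self.K = self.K + self._tie_stiffness()
        self.pairs = [_ContactPair(mesh, s, m) for s, m in contact_pairs]
        self._cache: dict = {}

    # -- assembly helpers --------------------------------------------------

    def _tie_stiffness(self) -> sp.csr_matrix:
        kt = self.cp.tie_penalty or 100.0 * self.E_max * self.h_est
        ties = self.mesh.ties
        slaves = ties[:, 0].astype(int)
        hosts = ties[:, 1].astype(int)
        lam = ties[:, 2:6]
        N = elements.shape(lam)  # (k, 10)
        hnodes = self.mesh.elements[hosts]  # (k, 10)
        k = len(ties)
        rows, cols, vals = [], [], []
        r = np.arange(k)
        for c in range(3):  # one constraint row per displacement component
            rows.append(3 * r + c)
            cols.append(3 * slaves + c)
            vals.append(np.ones(k))
            for j in range(10):
                rows.append(3 * r + c)
                cols.append(3 * hnodes[:, j] + c)
                vals.append(-N[:, j])
        C = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(3 * k, 3 * self.mesh.n_nodes),
        ).tocsr()
        return (C.T @ C) * kt

    def _penalties(self):
        kn = self.cp.penalty_normal or 100.0 * self.E_max / self.h_est
        kt = self.cp.penalty_tangential or kn / 10.0
        return kn, kt

    def _reduction(self, lc: LoadCase):
        key = (
            lc.load_ref, lc.load_surface, lc.pivot_ref, lc.pivot_surface,
            tuple(lc.fixed_surfaces), tuple(lc.rollers),
            tuple(sorted(lc.tractions)),
        )
        if key not in self._cache:
            self._cache[key] = {"Kred": None, "fact": {}}
        return key

    # -- main solve --------------------------------------------------------

    def solve(self, lc: LoadCase) -> Solution:
        mesh, cp = self.mesh, self.cp
        bc = apply_load_case(mesh, lc)
        ckey = self._reduction(lc)
        kn, kt = self._penalties()

        state = _ContactState(self.pairs)
        u_red = None
        converged = False
        it = 0
        for it in range(1, cp.max_newton_iter + 1):
            Kc, fc = self._contact_system(state, kn, kt, u_red)
            skey = tuple(
                (state.active[p.name].tobytes(), state.slip[p.name].tobytes())
                for p in self.pairs
            )
            fact = self._cache[ckey]["fact"].get(skey)
            if fact is None:
                if self._cache[ckey]["Kred"] is None:
                    self._cache[ckey]["Kred"] = (bc.T.T @ self.K @ bc.T).tocsc()
                Ksys = self._cache[ckey]["Kred"]
                if Kc.nnz:
                    Ksys = Ksys + (bc.T.T @ Kc @ bc.T).tocsc()
                fact = spla.splu(Ksys)
                if len(self._cache[ckey]["fact"]) < 4:
                    self._cache[ckey]["fact"][skey] = fact
            u_red = fact.solve(bc.f_red + bc.T.T @ fc)
            new_state = self._update_state(state, kn, kt, bc.T @ u_red)
            if new_state.same(state):
                converged = True
                state = new_state
                break
            state = new_state

        u_full = bc.T @ u_red
        u = u_full.reshape(-1, 3)
        stress = elements.element_stresses(mesh, u, self.E_elem, self.nu_elem)

        f_int = self.K @ u_full + self._contact_internal(state, kn, kt, u_full)
        resid_free = bc.T.T @ f_int - bc.f_red
        applied = (
            lc.force_vector
            if lc.load_ref is not None
            else bc.f_full.reshape(-1, 3).sum(axis=0)
        )
        scale = max(np.linalg.norm(applied), 1e-12)
        residual = float(np.linalg.norm(resid_free) / scale)

        react = f_int.reshape(-1, 3)[bc.constrained_nodes].sum(axis=0)
        masters = {}
        for name, (cols, _) in bc.master_cols.items():
            masters[name] = np.array([u_red[c] for c in cols])
        return Solution(
            u=u, stress=stress, converged=converged, iterations=it,
            residual=residual, reaction_force=react, applied_force=applied,
            contact_active={p.name: state.active[p.name] for p in self.pairs},
            master_motion=masters,
        )

    # -- contact pieces ----------------------------------------------------

    def _contact_system(self, state, kn, kt, u_red_prev):
        ndof = 3 * self.mesh.n_nodes
        Kc = sp.csr_matrix((ndof, ndof))
        fc = np.zeros(ndof)
        for p in self.pairs:
            act = state.active[p.name]
            if not act.any():
                continue
            w = kn * p.area * act
            Kc = Kc + p.Gn.T @ sp.diags(w) @ p.Gn
            fc -= p.Gn.T @ (w * p.g0)
            stick = act & ~state.slip[p.name]
            if self.cp.friction_mu > 0 and stick.any():
                wt = kt * p.area * stick
                Kc = Kc + p.Gt1.T @ sp.diags(wt) @ p.Gt1
                Kc = Kc + p.Gt2.T @ sp.diags(wt) @ p.Gt2
        return Kc, fc

    def _update_state(self, state, kn, kt, u_full):
        new = _ContactState(self.pairs)
        for p in self.pairs:
            g = p.g0 + p.Gn @ u_full
            new.active[p.name] = g < 0
            if self.cp.friction_mu > 0:
                fn = kn * p.area * np.maximum(-g, 0.0)
                ft = np.hypot(
                    kt * p.area * (p.Gt1 @ u_full),
                    kt * p.area * (p.Gt2 @ u_full),
                )
                new.slip[p.name] = new.active[p.name] & (
                    ft > self.cp.friction_mu * fn + 1e-12
                )
        return new

    def _contact_internal(self, state, kn, kt, u_full):
        f = np.zeros_like(u_full)
        for p in self.pairs:
            act = state.active[p.name]
            if not act.any():
                continue
            g = p.g0 + p.Gn @ u_full
            f += p.Gn.T @ (kn * p.area * np.where(act, g, 0.0))
            stick = act & ~state.slip[p.name]
            if self.cp.friction_mu > 0 and stick.any():
                wt = kt * p.area * stick
                f += p.Gt1.T @ (wt * (p.Gt1 @ u_full))
                f += p.Gt2.T @ (wt * (p.Gt2 @ u_full))
        return f


def solve(
    mesh: Mesh,
    materials: dict[str, tuple[float, float]],
    lc: LoadCase,
    cp: ContactParams | None = None,
    contact_pairs: tuple = (),
) -> Solution:
    """One-shot solve; see :class:`AssembledModel` for sweeps."""
    return AssembledModel(mesh, materials, cp, contact_pairs).solve(lc)
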