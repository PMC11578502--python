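"""Scalar stress criteria, region maxima and inversion/eversion sweeps.

Bone can fail in a ductile or a brittle mode, so both the von Mises
(distortion-energy) criterion and the Rankine (maximum-principal-stress)
criterion are evaluated; the titanium implant is assessed with von Mises
only.  All criteria operate on element-averaged stress tensors, which is the
convention behind every reported regional maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mesh import Mesh
from .solver import AssembledModel, ContactParams, LoadCase


def von_mises_field(stress: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress from Voigt tensors (m, 6)."""
    s = np.asarray(stress)
    sx, sy, sz, sxy, syz, sxz = (s[..., i] for i in range(6))
    return np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (sxy**2 + syz**2 + sxz**2)
    )


def max_principal_field(stress: np.ndarray) -> np.ndarray:
    """Largest principal stress (Rankine criterion) per element."""
    s = np.asarray(stress)
    m = s.shape[0]
    T = np.empty((m, 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = s[:, 0], s[:, 1], s[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = s[:, 3]
    T[:, 1, 2] = T[:, 2, 1] = s[:, 4]
    T[:, 0, 2] = T[:, 2, 0] = s[:, 5]
    return np.linalg.eigvalsh(T)[:, -1]


@dataclass
class RegionMax:
    """Maximum of a scalar field over a named element region."""

    region: str
    value: float
    element: int
    location: np.ndarray

    def __iter__(self):  # allows tuple unpacking (value, element)
        yield self.value
        yield self.element


def region_max(mesh: Mesh, field: np.ndarray, region: str) -> RegionMax:
    """Regional maximum; equal values resolve to the lowest element id."""
    ids = mesh.element_sets[region]
    if len(ids) == 0:
        raise ValueError(f"region '{region}' is empty")
    vals = np.asarray(field)[ids]
    j = int(np.argmax(vals))  # argmax returns the first (lowest) id on ties
    e = int(ids[j])
    return RegionMax(
        region=region, value=float(vals[j]), element=e,
        location=mesh.centroids(np.array([e]))[0],
    )


DEFAULT_REGIONS = (
    "nail",
    "cortical_upper",
    "cancellous_upper",
    "cortical_lower",
    "cancellous_lower",
)


def sweep_angles(
    mesh: Mesh,
    samples,
    angles,
    contact: ContactParams | None = None,
    contact_pairs: tuple = (("articular_lower", "articular_upper"),),
    regions: tuple = DEFAULT_REGIONS,
    callbacks: tuple = (),
    verbose: bool = False,
) -> pd.DataFrame:
    """Solve every (sample, angle) pair and tabulate regional stress maxima.

    ``samples`` is a list of :class:`~fusegap.materials.MaterialSample`;
    ``angles`` a list of tilt angles in degrees.  The stiffness is assembled
    and factorized once per sample and reused over the angles.  Extra
    quantities (section moments, gap fields) are harvested through
    ``callbacks``: callables ``(sample, angle, model, solution) -> None``.
    Solver non-convergence is recorded per row and does not abort the sweep.

    Returns a long-format frame with columns (angle, sample_id, region,
    criterion, value, x, y, z, converged).
    """
    rows = []
    for sample in samples:
        model = AssembledModel(
            mesh, sample.set_materials(), contact, contact_pairs
        )
        for phi in angles:
            sol = model.solve(LoadCase(phi=float(phi)))
            if verbose:
                print(
                    f"sample {sample.sample_id} phi {phi:+.0f}: "
                    f"iters {sol.iterations} converged {sol.converged}"
                )
            fields = {
                "von_mises": von_mises_field(sol.stress),
                "max_principal": max_principal_field(sol.stress),
            }
            for crit, fld in fields.items():
                for region in regions:
                    if crit == "max_principal" and region == "nail":
                        continue  # ductile implant: von Mises only
                    rm = region_max(mesh, fld, region)
                    rows.append(
                        {
                            "angle": phi,
                            "sample_id": sample.sample_id,
                            "region": region,
                            "criterion": crit,
                            "value": rm.value,
                            "x": rm.location[0],
                            "y": rm.location[1],
                            "z": rm.location[2],
                            "converged": sol.converged,
                        }
                    )
            for cb in callbacks:
                cb(sample, phi, model, sol)
    return pd.DataFrame(rows)
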