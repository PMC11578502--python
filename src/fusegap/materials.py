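"""Material property tables and Latin-hypercube sampling of Young's moduli.

The four homogeneous, isotropic, linear-elastic phases (cortical bone,
cancellous bone, titanium alloy, PMMA bone cement) carry normally
distributed Young's moduli; Poisson ratios are deterministic.  "Real" and
"artificial" (synthetic-bone surrogate) parameter sets are provided; the
artificial set models the tighter manufacturing tolerances of composite
test bones (10% CoV) against the 20% biological variability of real bone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import PHASE_OF_SET


@dataclass(frozen=True)
class MaterialDistribution:
    """Normal uncertainty model of one phase's Young's modulus (MPa)."""

    name: str
    E_mean: float
    E_sd: float
    poisson: float

    def __post_init__(self):
        if self.E_mean <= 0 or self.E_sd < 0:
            raise ValueError("E_mean must be > 0 and E_sd >= 0")
        if not 0 <= self.poisson < 0.5:
            raise ValueError("poisson must lie in [0, 0.5)")


@dataclass(frozen=True)
class MaterialSample:
    """One sampled set of phase moduli, with provenance."""

    sample_id: int
    E: dict                 #: phase -> Young's modulus, MPa
    poisson: dict           #: phase -> Poisson ratio
    seed: int               #: seed of the LHS draw this sample belongs to

    def set_materials(self, phase_of_set: dict | None = None) -> dict:
        """Per-element-set (E, nu) pairs for the solver."""
        mapping = phase_of_set or PHASE_OF_SET
        return {
            s: (self.E[p], self.poisson[p]) for s, p in mapping.items()
        }


_TABLES = {
    "real": [
        ("cortical", 17000.0, 3400.0, 0.3),
        ("cancellous", 100.0, 20.0, 0.3),
        ("titanium", 110000.0, 4400.0, 0.3),
        ("pmma", 3000.0, 300.0, 0.4),
    ],
    "artificial": [
        ("cortical", 16350.0, 1635.0, 0.3),
        ("cancellous", 155.0, 16.0, 0.3),
        ("titanium", 110000.0, 4400.0, 0.3),
        ("pmma", 3000.0, 300.0, 0.4),
    ],
}


def material_table(kind: str = "real") -> list[MaterialDistribution]:
    """Distributions for the ``real`` or ``artificial`` bone model."""
    if kind not in _TABLES:
        raise ValueError(f"unknown material table '{kind}'")
    return [MaterialDistribution(*row) for row in _TABLES[kind]]


def lhs_sample(
    dists: list[MaterialDistribution], n: int, seed: int
) -> list[MaterialSample]:
    """Draw ``n`` Latin-hypercube samples of the phase moduli.

    Per parameter, exactly one draw falls in each of the ``n`` equal-
    probability strata of its normal CDF (random position within the
    stratum).  Draws are clamped to ``max(E, E_mean - 3 E_sd)`` and kept
    strictly positive, since a normal model with a 20% CoV admits
    non-physical negative stiffness.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = stats.qmc.LatinHypercube(d=len(dists), seed=seed)
    u = sampler.random(n)
    out = []
    E_cols = np.empty((n, len(dists)))
    for j, d in enumerate(dists):
        if d.E_sd == 0.0:
            E_cols[:, j] = d.E_mean
            continue
        x = stats.norm.ppf(u[:, j], loc=d.E_mean, scale=d.E_sd)
        x = np.maximum(x, max(d.E_mean - 3.0 * d.E_sd, 1e-9 * d.E_mean))
        E_cols[:, j] = x
    for i in range(n):
        out.append(
            MaterialSample(
                sample_id=i,
                E={d.name: float(E_cols[i, j]) for j, d in enumerate(dists)},
                poisson={d.name: d.poisson for d in dists},
                seed=seed,
            )
        )
    return out


def samples_to_frame(samples: list[MaterialSample]) -> pd.DataFrame:
    """Long-format table (sample_id, phase, E, poisson, seed) for CSV export."""
    rows = [
        {
            "sample_id": s.sample_id,
            "phase": p,
            "E": s.E[p],
            "poisson": s.poisson[p],
            "seed": s.seed,
        }
        for s in samples
        for p in s.E
    ]
    return pd.DataFrame(rows)
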