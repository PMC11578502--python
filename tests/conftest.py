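"""Shared fixtures: verification solves and the scaled-down probabilistic run.

Expensive FE solves are session-scoped and reused across test modules.
"""

import numpy as np
import pytest

from fusegap import (
    AssembledModel,
    LoadCase,
    ModelParams,
    PipelineConfig,
    build_arthrodesis_model,
    build_verification_fixture,
    material_table,
    run_pipeline,
)
from fusegap.model import PHASE_OF_SET

TITANIUM = (110000.0, 0.3)


def mean_set_materials(kind: str = "real") -> dict:
    mats = {d.name: (d.E_mean, d.poisson) for d in material_table(kind)}
    return {s: mats[p] for s, p in PHASE_OF_SET.items()}


def timoshenko_tip_deflection(F, L=75.0, E=110000.0, nu=0.3, ro=6.0, ri=4.0):
    """Cantilever tube tip deflection: Euler-Bernoulli + Cowper shear term."""
    I = np.pi * (ro**4 - ri**4) / 4
    A = np.pi * (ro**2 - ri**2)
    G = E / (2 * (1 + nu))
    m2 = (ri / ro) ** 2
    kappa = (
        6 * (1 + nu) * (1 + m2) ** 2
        / ((7 + 6 * nu) * (1 + m2) ** 2 + (20 + 12 * nu) * m2)
    )
    return F * L**3 / (3 * E * I) + F * L / (G * A * kappa)


@pytest.fixture(scope="session")
def cantilever():
    """Cantilever tube (nail dimensions, elem <= 2 mm) + assembled stiffness."""
    mesh = build_verification_fixture("cantilever_tube", elem_size=1.75)
    model = AssembledModel(mesh, {"nail": TITANIUM})
    return mesh, model


@pytest.fixture(scope="session")
def cantilever_force(cantilever):
    """Tip transverse force case: (mesh, model, solution, F)."""
    mesh, model = cantilever
    F = 100.0
    area, _ = mesh.facet_areas_normals("tip")
    sol = model.solve(
        LoadCase(
            load_ref=None, pivot_ref=None, fixed_surfaces=("clamp",),
            tractions={"tip": (0.0, F / area.sum(), 0.0)},
        )
    )
    return mesh, model, sol, F


@pytest.fixture(scope="session")
def cantilever_torque(cantilever):
    """Tip axial torque case via rigid tip coupling: (mesh, model, sol, T)."""
    mesh, model = cantilever
    T = 5000.0
    sol = model.solve(
        LoadCase(
            load_ref="tip_center", load_surface="tip", pivot_ref=None,
            fixed_surfaces=("clamp",), apply_stance_force=False,
            ref_loads={"tip_center": [0, 0, 0, T, 0, 0]},
        )
    )
    return mesh, model, sol, T


@pytest.fixture(scope="session")
def arthro_coarse():
    """Coarse arthrodesis mesh + assembled mean-material model."""
    mesh = build_arthrodesis_model(ModelParams(elem_size=7.0))
    model = AssembledModel(
        mesh, mean_set_materials(),
        contact_pairs=(("articular_lower", "articular_upper"),),
    )
    return mesh, model


@pytest.fixture(scope="session")
def arthro_solution(arthro_coarse):
    mesh, model = arthro_coarse
    return model.solve(LoadCase(phi=-20.0))


@pytest.fixture(scope="session")
def sweep_run(tmp_path_factory):
    """Scaled-down probabilistic study: 10 LHS samples, 7 angles, coarse mesh."""
    outdir = tmp_path_factory.mktemp("sweep")
    cfg = PipelineConfig(
        model=ModelParams(elem_size=5.0),
        material_kinds=("real",),
        n_samples=10,
        seed=20240,
        outdir=str(outdir),
    )
    report = run_pipeline(cfg)
    return cfg, report, outdir
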