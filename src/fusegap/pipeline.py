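"""End-to-end probabilistic pipeline: generate, sample, sweep, post-process.

One :func:`run_pipeline` call builds the synthetic arthrodesis mesh, draws
Latin-hypercube material samples, solves the inversion/eversion sweep for
each sample, and reduces the results to the study's headline quantities:
regional stress maxima (von Mises / maximum principal), implant section
moments, monitor-point gap displacements, the displacement-moment
regressions with R^2, material-sensitivity rankings and the real-versus-
artificial bone comparison.  Every artifact is written with provenance
(config hash, seed, package version) and the run is deterministic for a
fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .gap import decompose, pair_surfaces, select_monitor_point
from .materials import lhs_sample, material_table, samples_to_frame
from .model import ModelParams, build_arthrodesis_model
from .moments import SectionCutter, implant_frame
from .regression import aggregate_samples, compare_bone_models, fit_linear, sensitivity
from .solver import ContactParams
from .stress import sweep_angles
from .vtu import save_mesh, save_solution

PHASES = ("cortical", "cancellous", "titanium", "pmma")


@dataclass
class PipelineConfig:
    """Configuration of one probabilistic run."""

    model: ModelParams = field(default_factory=ModelParams)
    material_kinds: tuple = ("real", "artificial")
    n_samples: int = 10          #: per configuration (material kind)
    angles: tuple = (-20.0, -15.0, -10.0, -5.0, 0.0, 5.0, 10.0)
    seed: int | None = None      #: mandatory for probabilistic runs
    contact: ContactParams = field(default_factory=ContactParams)
    station_spacing: float = 1.0
    monitor_region: str = "articular_lower_posterior"
    reference_direction: tuple = (1.0, 0.0, 0.0)
    outdir: str = "fusegap_out"
    save_fields: bool = False    #: write VTU fields of the first sample

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory for probabilistic runs")
        if not self.angles:
            raise ValueError("angle list is empty")
        for a in self.angles:
            if not -20 - 1e-9 <= a <= 10 + 1e-9:
                raise ValueError(f"angle {a} outside [-20, 10] degrees")
        for kind in self.material_kinds:
            material_table(kind)  # raises on unknown kind
        self.model.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        model = ModelParams(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("model", {}).items()
        })
        contact = ContactParams(**raw.pop("contact", {}))
        for key in ("material_kinds", "angles", "reference_direction"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(model=model, contact=contact, **raw)

    def hash(self) -> str:
        blob = json.dumps(
            {"model": asdict(self.model), "contact": asdict(self.contact),
             **{k: v for k, v in asdict(self).items()
                if k not in ("model", "contact")}},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class _Collector:
    """Harvests section-moment curves and gap fields during a sweep."""

    def __init__(self, mesh, cutter, pairing, s_gap, ref_dir):
        self.cutter = cutter
        self.pairing = pairing
        self.s_gap = s_gap
        self.ref_dir = ref_dir
        self.curves = {}
        self.fields = {}
        self.first_solutions = {}

    def __call__(self, sample, phi, model, sol):
        cur = self.cutter.evaluate(sol.u, model.E_elem, model.nu_elem)
        self.curves[(sample.sample_id, phi)] = cur
        self.fields[(sample.sample_id, phi)] = decompose(
            self.pairing, sol.u, reference_direction=self.ref_dir
        )
        if sample.sample_id == 0:
            self.first_solutions[phi] = sol


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the report dict (also on disk)."""
    t_start = time.time()
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
    }

    mesh = build_arthrodesis_model(config.model)
    save_mesh(mesh, out / "mesh.vtu")
    frame = implant_frame(mesh)
    s_gap = float(
        (mesh.reference_points["gap_center"] - frame.origin) @ frame.x_axis
    )
    stations = np.arange(
        config.station_spacing / 2, frame.span - 0.45 * config.station_spacing,
        config.station_spacing,
    )
    cutter = SectionCutter(mesh, frame, stations)
    pairing = pair_surfaces(mesh)

    angles = [float(a) for a in config.angles]
    report = {
        "provenance": provenance,
        "gap_station_mm": s_gap,
        "n_samples": config.n_samples,
        "angles": angles,
        "kinds": {},
    }
    per_kind = {}
    stress_tables = []
    for ki, kind in enumerate(config.material_kinds):
        seed_kind = int(config.seed) + 1000 * ki
        samples = lhs_sample(material_table(kind), config.n_samples, seed_kind)
        samples_to_frame(samples).to_csv(
            out / f"samples_{kind}.csv", index=False
        )
        coll = _Collector(
            mesh, cutter, pairing, s_gap, config.reference_direction
        )
        table = sweep_angles(
            mesh, samples, angles, contact=config.contact, callbacks=(coll,),
        )
        table["kind"] = kind
        stress_tables.append(table)
        per_kind[kind] = _postprocess_kind(
            kind, mesh, pairing, coll, samples, angles, s_gap, table,
            config, out,
        )
        report["kinds"][kind] = per_kind[kind]
        if config.save_fields and coll.first_solutions:
            phi0 = min(coll.first_solutions)
            save_solution(
                mesh, coll.first_solutions[phi0],
                out / f"solution_{kind}_sample0_phi{phi0:+.0f}.vtu",
            )

    pd.concat(stress_tables, ignore_index=True).to_csv(
        out / "stress_sweep.csv", index=False
    )

    if {"real", "artificial"} <= set(config.material_kinds):
        report["real_vs_artificial"] = {
            "max_nail_von_mises_pct": compare_bone_models(
                per_kind["real"]["_summaries"]["nail_von_mises"],
                per_kind["artificial"]["_summaries"]["nail_von_mises"],
            ),
            "max_tangential_displacement_pct": compare_bone_models(
                per_kind["real"]["_summaries"]["max_du_t"],
                per_kind["artificial"]["_summaries"]["max_du_t"],
            ),
        }
    for k in report["kinds"].values():
        k.pop("_summaries", None)

    report["runtime_s"] = round(time.time() - t_start, 2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def _postprocess_kind(
    kind, mesh, pairing, coll, samples, angles, s_gap, table, config, out
):
    n = len(samples)
    sample_ids = [s.sample_id for s in samples]

    # regional stress summaries (mean/SD over samples, per angle)
    summary_rows = []
    for (region, crit), grp in table.groupby(["region", "criterion"]):
        piv = grp.pivot(index="sample_id", columns="angle", values="value")
        piv = piv.reindex(index=sample_ids, columns=angles)
        s = aggregate_samples(piv.values, angles, f"{region}_{crit}")
        summary_rows.append(s.to_frame())
    pd.concat(summary_rows, ignore_index=True).to_csv(
        out / f"stress_summary_{kind}.csv", index=False
    )

    # section-moment curves
    mom = pd.concat(
        [
            coll.curves[(sid, phi)].to_frame(sample_id=sid, angle=phi)
            for sid in sample_ids
            for phi in angles
        ],
        ignore_index=True,
    )
    mom.to_csv(out / f"section_moments_{kind}.csv", index=False)

    # gap displacement fields: per-angle mean over samples
    def mean_field(attr, phi):
        return np.mean(
            [getattr(coll.fields[(sid, phi)], attr) for sid in sample_ids],
            axis=0,
        )

    gap_rows = []
    for phi in angles:
        gap_rows.append(
            pd.DataFrame(
                {
                    "angle": phi,
                    "point_id": pairing.point_ids,
                    "gap": pairing.distance,
                    "du_n": mean_field("du_n", phi),
                    "du_t_signed": mean_field("du_t_signed", phi),
                    "du_t_mag": mean_field("du_t_mag", phi),
                }
            )
        )
    pd.concat(gap_rows, ignore_index=True).to_csv(
        out / f"gap_displacements_{kind}.csv", index=False
    )

    # monitor points from the mean fields at the extreme configurations
    phi_inv, phi_ev = min(angles), max(angles)
    region_nodes = np.unique(mesh.surface_sets[config.monitor_region])
    subset = np.flatnonzero(np.isin(pairing.point_ids, region_nodes))
    i_t = select_monitor_point(
        mean_field("du_t_signed", phi_ev), mean_field("du_t_signed", phi_inv),
        subset if len(subset) else None,
    )
    i_n = select_monitor_point(
        mean_field("du_n", phi_ev), mean_field("du_n", phi_inv),
        subset if len(subset) else None,
    )

    # per-angle mean monitor displacements vs mean gap-station moments
    mean_mom = {
        phi: np.mean(
            [coll.curves[(sid, phi)].at(s_gap) for sid in sample_ids], axis=0
        )
        for phi in angles
    }
    du_t = np.array([mean_field("du_t_signed", phi)[i_t] for phi in angles])
    du_n = np.array([mean_field("du_n", phi)[i_n] for phi in angles])
    Mx = np.array([mean_mom[phi][0] for phi in angles])
    My = np.array([mean_mom[phi][1] for phi in angles])
    reg_t = fit_linear(Mx, du_t)
    reg_n = fit_linear(My, du_n)

    # per-sample sensitivity of both monitor displacements at max inversion
    X = np.array([[s.E[p] for p in PHASES] for s in samples])
    sens = {}
    if n > len(PHASES):
        for name, idx, attr in (
            ("tangential", i_t, "du_t_signed"),
            ("normal", i_n, "du_n"),
        ):
            yv = np.array(
                [
                    getattr(coll.fields[(sid, phi_inv)], attr)[idx]
                    for sid in sample_ids
                ]
            )
            df = sensitivity(X, yv, names=PHASES)
            df.to_csv(out / f"sensitivity_{name}_{kind}.csv", index=False)
            sens[name] = {
                "ranking": df["parameter"].tolist(),
                "coefficients": dict(
                    zip(df["parameter"], df["coefficient"].round(6))
                ),
            }

    # headline summaries reused by the bone-model comparison
    nail_vm = aggregate_samples(
        table.query("region == 'nail' and criterion == 'von_mises'")
        .pivot(index="sample_id", columns="angle", values="value")
        .reindex(index=sample_ids, columns=angles)
        .values,
        angles,
        "nail_von_mises",
    )
    max_dut = aggregate_samples(
        np.array(
            [
                [coll.fields[(sid, phi)].du_t_mag.max() for phi in angles]
                for sid in sample_ids
            ]
        ),
        angles,
        "max_du_t",
    )

    def stress_at(region, crit, phi):
        q = table.query(
            "region == @region and criterion == @crit and angle == @phi"
        )["value"]
        return {"mean": float(q.mean()), "sd": float(q.std(ddof=1)) if n > 1 else 0.0}

    result = {
        "monitor_point_tangential": int(pairing.point_ids[i_t]),
        "monitor_point_normal": int(pairing.point_ids[i_n]),
        "monitor_du_t_mm": dict(zip(map(str, angles), np.round(du_t, 6))),
        "monitor_du_n_mm": dict(zip(map(str, angles), np.round(du_n, 6))),
        "gap_moment_Mx_Nmm": dict(zip(map(str, angles), np.round(Mx, 3))),
        "gap_moment_My_Nmm": dict(zip(map(str, angles), np.round(My, 3))),
        "regression_du_t_vs_Mx": {
            "slope_per_N": reg_t.slope, "intercept_mm": reg_t.intercept,
            "r_squared": reg_t.r_squared,
        },
        "regression_du_n_vs_My": {
            "slope_per_N": reg_n.slope, "intercept_mm": reg_n.intercept,
            "r_squared": reg_n.r_squared,
        },
        "tangential_normal_ratio_inversion": (
            float(du_t[int(np.argmin(np.asarray(angles)))]
                  / du_n[int(np.argmin(np.asarray(angles)))])
            if du_n[int(np.argmin(np.asarray(angles)))] != 0 else None
        ),
        "max_stress_MPa": {
            f"{region}_{crit}_{label}": stress_at(region, crit, phi)
            for region in ("nail", "cortical_upper", "cortical_lower",
                           "cancellous_upper", "cancellous_lower")
            for crit in ("von_mises", "max_principal")
            for label, phi in (
                ("inversion", min(angles)), ("neutral", 0.0),
                ("eversion", max(angles)),
            )
            if not (region == "nail" and crit == "max_principal")
            and phi in angles
        },
        "sensitivity": sens,
        "all_converged": bool(table["converged"].all()),
        "_summaries": {"nail_von_mises": nail_vm, "max_du_t": max_dut},
    }
    return result
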