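"""Study orchestration: mesh once, solve every load case, tabulate.

``run_study`` reproduces the four-load-case protocol (150 / 1000 / 3000 /
5000 microstrain ramp-hold compression) and writes a combined summary
table, probe time series and optional VTU field snapshots.  ``verify``
runs the analytic-oracle suite (Terzaghi column, drained homogeneous
block, constitutive identities) and reports pass/fail.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constitutive as con
from .config import RunConfig
from .constitutive import ECM
from .fem import BiotSolver, LoadCase, octant_boundary_conditions
from .geometry import build_octant_geometry, probe_points
from .io import write_json, write_msh, write_vtu
from .meshing import Mesh, box_mesh, mesh_geometry
from .oracles import ColumnProblem, column_pressure_error, homogeneous_block_solution
from .postprocess import (
    ResultSummary,
    darcy_flux_and_velocity,
    extract_probe_series,
    nodal_strain_magnitude,
    principal_strain_field,
    summarize,
)

__all__ = ["run_study", "run_single_case", "verify", "StudyResult"]

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    summaries: list[ResultSummary]
    table: pd.DataFrame
    probes: pd.DataFrame
    mesh: Mesh
    timings: dict[str, float] = field(default_factory=dict)


def _summary_row(s: ResultSummary) -> dict:
    return {
        "global_strain_ustrain": s.global_strain_ustrain,
        "max_principal_strain_ustrain": s.max_principal_strain_ustrain,
        "amplification_factor": s.amplification_factor,
        "max_cell_pore_pressure_kPa": s.max_cell_pore_pressure_kPa,
        "max_pore_pressure_kPa": s.max_pore_pressure_kPa,
        "max_pore_pressure_time": s.max_pore_pressure_time,
        "max_seepage_velocity_um_s": s.max_seepage_velocity_um_s,
        "transient_peak_strain_ustrain": s.transient_peak_strain_ustrain,
        "max_strain_region": s.max_strain_region,
    }


def run_single_case(cfg: RunConfig, load_case: LoadCase, mesh: Mesh | None = None):
    """Mesh (if needed), solve and summarize one load case."""
    geom = build_octant_geometry(cfg.geometry)
    if mesh is None:
        mesh = mesh_geometry(geom, cfg.resolution)
    solver = BiotSolver(
        mesh,
        cfg.materials,
        c_stab=cfg.c_stab,
        refactor_rtol=cfg.refactor_rtol,
        nonlinear_permeability=cfg.nonlinear_permeability,
    )
    series = solver.run(load_case.times, octant_boundary_conditions(mesh, geom, load_case))
    return series, summarize(series, load_case), mesh


def run_study(cfg: RunConfig, write_outputs: bool = True) -> StudyResult:
    """Run every configured load case on a shared mesh.

    Deterministic: identical configuration produces byte-identical output
    tables.  Writes summary.csv / summary.json / probes.csv / mesh.msh
    (plus per-case VTU series when ``write_fields``) under ``cfg.outdir``.
    """
    t_start = time.perf_counter()
    geom = build_octant_geometry(cfg.geometry)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    mesh = mesh_geometry(geom, cfg.resolution)
    timings["mesh"] = time.perf_counter() - t0
    logger.info("mesh: %d elements, %d nodes (%.1fs)",
                mesh.n_elements, mesh.n_nodes, timings["mesh"])

    probes = probe_points(geom) if geom.params.load_axis in geom.params.canaliculi_axes else None
    summaries: list[ResultSummary] = []
    probe_frames = []
    outdir = Path(cfg.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
        write_msh(outdir / "mesh.msh", mesh)

    for i, lc in enumerate(cfg.load_cases):
        t0 = time.perf_counter()
        try:
            series, summary, _ = run_single_case(cfg, lc, mesh=mesh)
        except Exception as exc:
            raise RuntimeError(
                f"load case {i} ({lc.global_strain*1e6:.0f} microstrain) "
                f"failed during solve: {exc}; partial outputs in {outdir}"
            ) from exc
        timings[f"case_{lc.global_strain*1e6:.0f}ue"] = time.perf_counter() - t0
        summaries.append(summary)
        if probes is not None:
            pf = extract_probe_series(series, probes)
            pf.insert(0, "global_strain_ustrain", lc.global_strain * 1e6)
            probe_frames.append(pf)
        if write_outputs and cfg.write_fields:
            for j, state in enumerate(series):
                write_vtu(
                    outdir / f"case{i}_t{j:03d}.vtu",
                    mesh,
                    point_data={"u": state.u, "p": state.p,
                                "strain_ustrain": nodal_strain_magnitude(mesh, state.u)},
                    cell_data={
                        "principal_strain_ustrain": principal_strain_field(mesh, state.u),
                        "seepage_velocity_um_s": np.linalg.norm(
                            darcy_flux_and_velocity(mesh, state, cfg.materials)[1], axis=1
                        ),
                    },
                )

    table = pd.DataFrame([_summary_row(s) for s in summaries])
    probes_df = (
        pd.concat(probe_frames, ignore_index=True) if probe_frames else pd.DataFrame()
    )
    timings["total"] = time.perf_counter() - t_start
    if write_outputs:
        table.to_csv(outdir / "summary.csv", index=False, float_format="%.10g")
        write_json(outdir / "summary.json", [s.to_dict() for s in summaries])
        if len(probes_df):
            probes_df.to_csv(outdir / "probes.csv", index=False, float_format="%.10g")
        write_json(
            outdir / "metadata.json",
            {
                "n_elements": mesh.n_elements,
                "n_nodes": mesh.n_nodes,
                "resolution": cfg.resolution,
                "c_stab": cfg.c_stab,
                "refactor_rtol": cfg.refactor_rtol,
                "interpolation": "equal-order P1/P1 with Brezzi-Pitkaranta stabilization",
                "timings_s": timings,
            },
        )
    return StudyResult(summaries=summaries, table=table, probes=probes_df,
                       mesh=mesh, timings=timings)


def verify(quick: bool = False, _broken_mobility_sign: bool = False) -> dict:
    """Analytic-oracle verification suite; returns a report dict with an
    overall ``passed`` flag.

    Checks: Terzaghi column pressure (< 1% relative L2 at the stated
    resolution), homogeneous-block drained limit (uniform strain,
    amplification 1 +- 2%, pressure decays to ~0), and the constitutive
    identities (permeability law at the reference state; porosity round
    trip).  ``_broken_mobility_sign`` is a test hook that flips the sign
    of the Darcy mobility in the column problem to prove the check fails
    when the physics is wrong.
    """
    report: dict = {"checks": {}}

    # constitutive identities
    k_id = con.permeability_update(0.053, 0.053, 1.0e-20, 4.638)
    rt = con.void_ratio_from_porosity(con.porosity_from_void_ratio(4.88))
    report["checks"]["permeability_identity"] = {
        "value": k_id, "expected": 1.0e-20, "passed": k_id == 1.0e-20,
    }
    report["checks"]["porosity_round_trip"] = {
        "value": rt, "expected": 4.88, "passed": abs(rt - 4.88) < 1e-12,
    }

    # Terzaghi column
    col = ColumnProblem()
    ny, nsteps = (20, 30) if quick else (40, 60)
    tol = 0.02 if quick else 0.01
    try:
        err = column_pressure_error(
            col, ny=ny, n_steps=nsteps,
            _mobility_sign=-1.0 if _broken_mobility_sign else 1.0,
        )
        terzaghi_check = {"value": err, "tolerance": tol, "passed": err < tol}
    except Exception as exc:  # a broken discretization may diverge outright
        terzaghi_check = {"error": repr(exc), "tolerance": tol, "passed": False}
    report["checks"]["terzaghi_pressure_L2"] = terzaghi_check

    # homogeneous drained block: same material everywhere, permeable
    # enough to drain within the period
    mesh = box_mesh((21.5, 21.5, 21.5), (5, 5, 5))
    mesh.facets["sym_x"] = mesh.facets.pop("x0")
    mesh.facets["sym_y"] = mesh.facets.pop("y0")
    mesh.facets["sym_z"] = mesh.facets.pop("z0")
    mesh.facets["load"] = mesh.facets.pop("y1")
    mesh.facets["exterior_x"] = mesh.facets.pop("x1")
    mesh.facets["exterior_z"] = mesh.facets.pop("z1")
    mat = con.MaterialProps(E=11.0e9, nu=0.38, k0=1.0e-16, e0=0.053)
    geom = build_octant_geometry()
    lc = LoadCase(global_strain=1e-3, n_steps=20, ramp_fraction=0.25)
    solver = BiotSolver(mesh, {ECM: mat}, nonlinear_permeability=False)
    series = solver.run(lc.times, octant_boundary_conditions(mesh, geom, lc))
    final = series[-1]
    eps_el = principal_strain_field(mesh, final.u)
    amp = float(np.abs(eps_el).max()) / 1000.0
    uniformity = float(np.abs(eps_el).std() / np.abs(eps_el).mean())
    p_end = float(np.abs(final.p).max())
    exact = homogeneous_block_solution(1e-3, mat.E, mat.nu)
    report["checks"]["homogeneous_block"] = {
        "amplification": amp,
        "expected_amplification": exact["amplification"],
        "strain_uniformity_cv": uniformity,
        "final_pressure_Pa": p_end,
        "passed": abs(amp - 1.0) < 0.02 and uniformity < 0.01 and p_end < 50.0,
    }

    report["passed"] = all(c["passed"] for c in report["checks"].values())
    return report
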