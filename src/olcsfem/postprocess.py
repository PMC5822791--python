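"""Derived quantities: principal strains, amplification, Darcy flow, probes.

Reporting conventions
---------------------
Strain is evaluated per element (constant on linear tetrahedra) and its
max-magnitude principal value is recovered to the nodes by volume-weighted
averaging before maxima are taken.  Raw element values at the bimaterial
canaliculus-PCM-process junction are non-convergent point samples of a
corner singularity, so the recovered field is what the summary reports.

Headline strain maxima (and the amplification factor) are taken from the
final state of the series, i.e. after the pressure transient of the ramp
has consolidated away; this steady value is robust to mesh, time step and
stabilization.  The much larger strain excursion inside the early-ramp
pressure boundary layer is reported separately as
``transient_peak_strain`` and should be treated as a qualitative
diagnostic only (see the methods note).

Pore pressure and seepage-velocity maxima are taken over the whole period
(they peak at the end of the ramp and then decay).  Units follow the
reporting conventions of the field: microstrain, kPa, um/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .constitutive import CELL, REGION_NAMES, MaterialProps
from .fem import LoadCase, SolutionState, StateSeries
from .meshing import Mesh

__all__ = [
    "ResultSummary",
    "principal_strain_field",
    "strain_tensors",
    "nodal_strain_magnitude",
    "amplification_factor",
    "darcy_flux_and_velocity",
    "extract_probe_series",
    "summarize",
]


def strain_tensors(mesh: Mesh, u: np.ndarray) -> np.ndarray:
    """Per-element small-strain tensors (M, 3, 3) from nodal displacements."""
    if not np.all(mesh.volumes > 0):
        bad = int(np.flatnonzero(mesh.volumes <= 0)[0])
        raise ValueError(f"degenerate element geometry at element {bad}")
    grad_u = np.einsum("eik,eil->ekl", mesh.grads, u[mesh.elems])
    return 0.5 * (grad_u + np.swapaxes(grad_u, 1, 2))


def principal_strain_field(mesh: Mesh, u: np.ndarray) -> np.ndarray:
    """Signed max-magnitude principal strain per element, in microstrain.

    Eigenvalues of the element strain tensor; the one largest in absolute
    value is returned with its sign retained (compression negative).
    """
    eigs = np.linalg.eigvalsh(strain_tensors(mesh, u))
    idx = np.abs(eigs).argmax(axis=1)
    return eigs[np.arange(len(eigs)), idx] * 1.0e6


def nodal_strain_magnitude(mesh: Mesh, u: np.ndarray) -> np.ndarray:
    """Volume-weighted nodal recovery of |principal strain| (microstrain)."""
    mag = np.abs(principal_strain_field(mesh, u))
    w = np.zeros(mesh.n_nodes)
    vol = np.zeros(mesh.n_nodes)
    for i in range(4):
        np.add.at(w, mesh.elems[:, i], mag * mesh.volumes)
        np.add.at(vol, mesh.elems[:, i], mesh.volumes)
    return w / vol


def amplification_factor(max_local_strain: float, global_strain: float) -> float:
    """Ratio of peak local strain to globally applied strain (same units)."""
    if global_strain <= 0:
        raise ValueError("global strain must be positive for an amplification factor")
    return max_local_strain / global_strain


def darcy_flux_and_velocity(
    mesh: Mesh, state: SolutionState, materials: Mapping[int, MaterialProps]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-element Darcy flux q = -(k/mu) grad p and seepage velocity
    v = q / nf, both (M, 3) in um/s."""
    mu = np.zeros(mesh.n_elements)
    for lab, mat in materials.items():
        mu[mesh.labels == lab] = mat.mu_f
    grad_p = np.einsum("eik,ei->ek", mesh.grads, state.p[mesh.elems])
    q = -(state.k_um2 / mu)[:, None] * grad_p
    nf = state.e / (1.0 + state.e)
    if np.any(nf <= 0):
        raise ValueError("pore collapse: zero porosity element")
    return q, q / nf[:, None]


def _locate(mesh: Mesh, point: np.ndarray, tol: float = 1.0e-6) -> int:
    """Element containing ``point`` (barycentric test; nearest-element
    fallback within ``tol`` micrometres for interface points)."""
    point = np.asarray(point, dtype=float)
    v0 = mesh.nodes[mesh.elems[:, 0]]
    # barycentric coords of the last three vertices, first by difference
    lam123 = np.einsum("eik,ek->ei", mesh.grads[:, 1:, :], point[None, :] - v0)
    lam0 = 1.0 - lam123.sum(axis=1)
    lam = np.column_stack([lam0, lam123])
    score = lam.min(axis=1)
    best = int(score.argmax())
    if score[best] < -tol:
        raise ValueError(f"point {point.tolist()} lies outside the mesh")
    return best


def _interp_nodal(mesh: Mesh, elem: int, point: np.ndarray, field: np.ndarray):
    v0 = mesh.nodes[mesh.elems[elem, 0]]
    lam123 = mesh.grads[elem, 1:, :] @ (np.asarray(point) - v0)
    lam = np.concatenate([[1.0 - lam123.sum()], lam123])
    return lam @ field[mesh.elems[elem]]


def extract_probe_series(
    series: StateSeries, points: Mapping[str, np.ndarray]
) -> pd.DataFrame:
    """Tidy time series of strain / pressure / velocity at probe points.

    Strain (recovered nodal magnitude, microstrain) and pore pressure
    (nodal, kPa) are interpolated linearly inside the containing element;
    seepage-velocity magnitude (um/s) is the containing element's value.
    """
    mesh = series.mesh
    located = {name: _locate(mesh, pt) for name, pt in points.items()}
    rows = []
    for state in series:
        nodal_eps = nodal_strain_magnitude(mesh, state.u)
        _, v = darcy_flux_and_velocity(mesh, state, series.materials)
        vmag = np.linalg.norm(v, axis=1)
        for name, pt in points.items():
            el = located[name]
            rows.append((state.t, name, "strain_ustrain",
                         float(_interp_nodal(mesh, el, pt, nodal_eps))))
            rows.append((state.t, name, "pressure_kPa",
                         float(_interp_nodal(mesh, el, pt, state.p)) / 1e3))
            rows.append((state.t, name, "velocity_um_s", float(vmag[el])))
    return pd.DataFrame(rows, columns=["time", "point", "quantity", "value"])


@dataclass
class ResultSummary:
    """Headline outputs of one load case.

    Strain maxima/amplification are steady-state (end of period) values of
    the recovered field; pressure and velocity maxima are over the whole
    period.  ``transient_peak_strain_ustrain`` is the non-converged
    boundary-layer excursion during the ramp (diagnostic only).
    """

    global_strain_ustrain: float
    max_principal_strain_ustrain: float
    amplification_factor: float | None
    max_strain_location: tuple[float, float, float]
    max_strain_region: str
    transient_peak_strain_ustrain: float
    transient_peak_time: float
    transient_peak_location: tuple[float, float, float]
    max_pore_pressure_kPa: float
    max_pore_pressure_time: float
    max_pore_pressure_location: tuple[float, float, float]
    max_cell_pore_pressure_kPa: float
    max_cell_pore_pressure_time: float
    max_seepage_velocity_um_s: float
    max_seepage_velocity_time: float
    max_seepage_velocity_location: tuple[float, float, float]
    max_seepage_velocity_region: str
    region_steady_strain_ustrain: dict[str, float]
    region_peak_pressure_kPa: dict[str, float]
    zero_load: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(series: StateSeries, load_case: LoadCase) -> ResultSummary:
    """Reduce a state series to the reported maxima."""
    if len(series) == 0:
        raise ValueError("empty state series")
    mesh = series.mesh
    labels = mesh.labels
    region_nodes = {
        lab: np.unique(mesh.elems[labels == lab]) for lab in np.unique(labels)
    }

    # pressure maxima over the period (nodal)
    p_best, p_t, p_loc = -np.inf, 0.0, (0.0, 0.0, 0.0)
    p_cell_best, p_cell_t = -np.inf, 0.0
    region_p = {lab: -np.inf for lab in region_nodes}
    v_best, v_t, v_el = -np.inf, 0.0, 0
    trans_best, trans_t = -np.inf, 0.0
    trans_loc = (0.0, 0.0, 0.0)
    for state in series:
        i = int(state.p.argmax())
        if state.p[i] > p_best:
            p_best, p_t, p_loc = float(state.p[i]), state.t, tuple(mesh.nodes[i])
        for lab, nd in region_nodes.items():
            region_p[lab] = max(region_p[lab], float(state.p[nd].max()))
        if CELL in region_nodes:
            pc = float(state.p[region_nodes[CELL]].max())
            if pc > p_cell_best:
                p_cell_best, p_cell_t = pc, state.t
        _, v = darcy_flux_and_velocity(mesh, state, series.materials)
        vmag = np.linalg.norm(v, axis=1)
        j = int(vmag.argmax())
        if vmag[j] > v_best:
            v_best, v_t, v_el = float(vmag[j]), state.t, j
        nodal = nodal_strain_magnitude(mesh, state.u)
        m = float(nodal.max())
        if m > trans_best:
            trans_best, trans_t = m, state.t
            trans_loc = tuple(float(c) for c in mesh.nodes[int(nodal.argmax())])

    # steady-state (final) strain field
    final = series[-1]
    nodal = nodal_strain_magnitude(mesh, final.u)
    i = int(nodal.argmax())
    steady_max = float(nodal[i])
    steady_loc = tuple(float(c) for c in mesh.nodes[i])
    elem_mag = np.abs(principal_strain_field(mesh, final.u))
    region_eps = {
        REGION_NAMES[lab]: float(elem_mag[labels == lab].max())
        for lab in region_nodes
    }
    # region of the peak node: region of the adjacent element with the
    # largest contribution
    adj = np.nonzero((mesh.elems == i).any(axis=1))[0]
    peak_region = REGION_NAMES[labels[adj[elem_mag[adj].argmax()]]]

    g_ustrain = load_case.global_strain * 1e6
    zero = load_case.global_strain == 0.0
    amp = None if zero else steady_max / g_ustrain

    return ResultSummary(
        global_strain_ustrain=g_ustrain,
        max_principal_strain_ustrain=steady_max,
        amplification_factor=amp,
        max_strain_location=steady_loc,
        max_strain_region=peak_region,
        transient_peak_strain_ustrain=trans_best,
        transient_peak_time=trans_t,
        transient_peak_location=trans_loc,
        max_pore_pressure_kPa=p_best / 1e3,
        max_pore_pressure_time=p_t,
        max_pore_pressure_location=tuple(float(c) for c in p_loc),
        max_cell_pore_pressure_kPa=p_cell_best / 1e3,
        max_cell_pore_pressure_time=p_cell_t,
        max_seepage_velocity_um_s=v_best,
        max_seepage_velocity_time=v_t,
        max_seepage_velocity_location=tuple(
            float(c) for c in mesh.centroids[v_el]
        ),
        max_seepage_velocity_region=REGION_NAMES[labels[v_el]],
        region_steady_strain_ustrain=region_eps,
        region_peak_pressure_kPa={
            REGION_NAMES[lab]: v / 1e3 for lab, v in region_p.items()
        },
        zero_load=zero,
    )
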