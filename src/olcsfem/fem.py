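"""Mixed displacement-pressure finite elements for Biot consolidation.

Quasi-static Biot poroelasticity with Biot coefficient 1 and
incompressible constituents (fully saturated, no storativity beyond
skeleton dilatation):

    div( sigma_E(u) - p I ) = 0
    d/dt div u + div q = 0,      q = -(k / mu_f) grad p

discretized with equal-order linear tetrahedra for u and p plus a
Brezzi-Pitkaranta pressure stabilization term (coefficient
c_stab * h_e^2 / (lam + 2G) per element) that suppresses checkerboard
pressure modes in the undrained limit.  Time integration is backward
Euler; the strain-dependent permeability enters semi-implicitly (mobility
evaluated from the previous step's void ratio), and the sparse direct
factorization is reused until the lagged permeability drifts by more than
a configurable relative tolerance.

Internal units: micrometres, pascals, seconds.  In this system the
mobility k/mu_f (permeability converted to um^2) yields Darcy flux in
um/s directly, and the 1e10-range stiffness entries are tamed by a
symmetric diagonal scaling before factorization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from . import constitutive as con
from .constitutive import MaterialProps
from .geometry import _AXIS_INDEX, LabeledGeometry
from .meshing import Mesh

__all__ = [
    "LoadCase",
    "SolutionState",
    "StateSeries",
    "BoundaryConditions",
    "BiotSolver",
    "ramp_hold_displacement",
    "peak_displacement",
    "octant_boundary_conditions",
    "run_consolidation",
]

logger = logging.getLogger(__name__)

M2_TO_UM2 = 1.0e12  # permeability m^2 -> um^2


@dataclass(frozen=True)
class LoadCase:
    """Ramp-hold uniaxial compression protocol.

    The global compressive strain is ramped linearly over
    ``ramp_fraction * period_T`` and then held.  Strain is dimensionless
    (e.g. 1000 microstrain = 1e-3); the four study levels are 150, 1000,
    3000 and 5000 microstrain (disuse / physiological / overuse /
    pathological overload).
    """

    global_strain: float
    ramp_fraction: float = 0.1
    period_T: float = 1.0
    n_steps: int = 50
    load_axis: str = "y"

    def __post_init__(self) -> None:
        if self.global_strain < 0:
            raise ValueError("global_strain must be non-negative")
        if not (0.0 < self.ramp_fraction < 1.0):
            raise ValueError("ramp_fraction must lie in (0, 1)")
        if self.period_T <= 0:
            raise ValueError("period_T must be positive")
        if self.n_steps < 10:
            raise ValueError("need at least 10 time steps")
        if self.n_steps * self.ramp_fraction < 5.0 - 1e-12:
            raise ValueError("need at least 5 time steps inside the ramp")
        if self.load_axis not in _AXIS_INDEX:
            raise ValueError("load_axis must be 'x', 'y' or 'z'")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.period_T, self.n_steps + 1)


def ramp_hold_displacement(t: float, T: float, ramp_fraction: float,
                           u_peak: float) -> float:
    """Applied displacement magnitude at time ``t``: linear from 0 to
    ``u_peak`` over ``[0, ramp_fraction*T]``, constant thereafter."""
    if t < -1e-12 * T or t > T * (1.0 + 1e-12):
        raise ValueError(f"time {t} outside the loading period [0, {T}]")
    t_ramp = ramp_fraction * T
    return u_peak * min(max(t, 0.0) / t_ramp, 1.0)


def peak_displacement(load_case: LoadCase, geom: LabeledGeometry) -> float:
    """Peak face displacement (um) on the octant loading face:
    global strain times the half side length."""
    return load_case.global_strain * geom.params.half_side


@dataclass(frozen=True)
class SolutionState:
    """Fields at one time: nodal displacement u (um), nodal pore pressure
    p (Pa), per-element void ratio e and permeability k (um^2)."""

    t: float
    u: np.ndarray
    p: np.ndarray
    e: np.ndarray
    k_um2: np.ndarray


@dataclass
class StateSeries:
    """Ordered solution states from t = 0 (zero state) to t = T."""

    mesh: Mesh
    materials: dict[int, MaterialProps]
    states: list[SolutionState] = field(default_factory=list)
    residuals: list[float] = field(default_factory=list)
    n_factorizations: int = 0

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    def __iter__(self):
        return iter(self.states)

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i) -> SolutionState:
        return self.states[i]


@dataclass
class BoundaryConditions:
    """Constraint specification for one consolidation run.

    dirichlet_u : list of (node ids, component, value_fn(t) -> um).
    dirichlet_p : node ids held at p = 0 (drained surfaces).
    tractions : list of (facet triangles, value_fn(t) -> traction Pa (3,)).
    """

    dirichlet_u: list[tuple[np.ndarray, int, Callable[[float], float]]]
    dirichlet_p: np.ndarray
    tractions: list[tuple[np.ndarray, Callable[[float], np.ndarray]]] = field(
        default_factory=list
    )


class ConfigurationError(RuntimeError):
    pass


def _material_arrays(mesh: Mesh, materials: dict[int, MaterialProps]):
    """Broadcast per-region constants to per-element arrays."""
    labels = mesh.labels
    missing = set(np.unique(labels)) - set(materials)
    if missing:
        raise ConfigurationError(f"no material assigned to region(s) {missing}")
    out = {}
    for name in ("E", "nu", "k0", "e0", "M", "mu_f"):
        vals = np.zeros(mesh.n_elements)
        for lab, mat in materials.items():
            vals[labels == lab] = getattr(mat, name)
        out[name] = vals
    return out


class BiotSolver:
    """Assembles and time-marches the coupled (u, p) system on a mesh.

    Degree-of-freedom layout: u dofs are ``3*node + component``; p dofs
    follow at ``3*N + node``.
    """

    def __init__(
        self,
        mesh: Mesh,
        materials: dict[int, MaterialProps],
        c_stab: float = 0.1,
        refactor_rtol: float = 1.0e-3,
        nonlinear_permeability: bool = True,
    ) -> None:
        self.mesh = mesh
        self.materials = materials
        self.c_stab = c_stab
        self.refactor_rtol = refactor_rtol
        self.nonlinear_permeability = nonlinear_permeability

        self.mat = _material_arrays(mesh, materials)
        self.lam, self.G = con.lame_parameters(self.mat["E"], self.mat["nu"])
        self.k0_um2 = self.mat["k0"] * M2_TO_UM2

        self.n_u = 3 * mesh.n_nodes
        self.ndof = self.n_u + mesh.n_nodes
        self._mobility_sign = 1.0  # test hook for the negative control
        self._build_constant_matrices()

    # -- assembly ---------------------------------------------------------

    def _build_constant_matrices(self) -> None:
        mesh = self.mesh
        g = mesh.grads          # (M, 4, 3)
        V = mesh.volumes        # (M,)
        elems = mesh.elems
        M = mesh.n_elements

        # elasticity: Ke = V * B^T D B with Voigt order xx,yy,zz,xy,yz,zx
        B = np.zeros((M, 6, 12))
        for i in range(4):
            c = 3 * i
            B[:, 0, c + 0] = g[:, i, 0]
            B[:, 1, c + 1] = g[:, i, 1]
            B[:, 2, c + 2] = g[:, i, 2]
            B[:, 3, c + 0] = g[:, i, 1]
            B[:, 3, c + 1] = g[:, i, 0]
            B[:, 4, c + 1] = g[:, i, 2]
            B[:, 4, c + 2] = g[:, i, 1]
            B[:, 5, c + 0] = g[:, i, 2]
            B[:, 5, c + 2] = g[:, i, 0]
        D = np.zeros((M, 6, 6))
        lam, G = self.lam, self.G
        for a in range(3):
            for b in range(3):
                D[:, a, b] = lam
            D[:, a, a] += 2.0 * G
            D[:, 3 + a, 3 + a] = G
        Ke = np.einsum("eki,ekl,elj,e->eij", B, D, B, V, optimize=True)

        udof = (3 * elems[:, :, None] + np.arange(3)[None, None, :]).reshape(M, 12)
        rows = np.repeat(udof, 12, axis=1).ravel()
        cols = np.tile(udof, (1, 12)).ravel()
        self.K = sparse.coo_matrix(
            (Ke.ravel(), (rows, cols)), shape=(self.n_u, self.n_u)
        ).tocsr()

        # coupling: Qe[3i+d, j] = grad_i_d * V/4  (alpha = 1)
        Qe = np.repeat(g.reshape(M, 12, 1), 4, axis=2) * (V / 4.0)[:, None, None]
        pdof = self.n_u + elems
        rows = np.repeat(udof, 4, axis=1).ravel()
        cols = np.tile(pdof, (1, 12)).ravel()
        self.Q = sparse.coo_matrix(
            (Qe.ravel(), (rows, cols - self.n_u)), shape=(self.n_u, mesh.n_nodes)
        ).tocsr()

        # pressure-Laplacian template, reused for H (k/mu) and S (stab)
        GG = np.einsum("eik,ejk,e->eij", g, g, V)  # (M,4,4) of V*grad.grad
        prow = np.repeat(elems, 4, axis=1).ravel()
        pcol = np.tile(elems, (1, 4)).ravel()
        self._pp_rows, self._pp_cols, self._pp_GG = prow, pcol, GG

        h2 = mesh.edge_lengths**2
        coef = self.c_stab * h2 / (lam + 2.0 * G)
        Se = GG * coef[:, None, None]
        self.S = sparse.coo_matrix(
            (Se.ravel(), (prow, pcol)), shape=(mesh.n_nodes, mesh.n_nodes)
        ).tocsr()

    def _flow_matrix(self, k_um2: np.ndarray) -> sparse.csr_matrix:
        mob = self._mobility_sign * k_um2 / self.mat["mu_f"]
        He = self._pp_GG * mob[:, None, None]
        n = self.mesh.n_nodes
        return sparse.coo_matrix(
            (He.ravel(), (self._pp_rows, self._pp_cols)), shape=(n, n)
        ).tocsr()

    def _traction_rhs(self, bcs: BoundaryConditions, t: float) -> np.ndarray:
        f = np.zeros(self.ndof)
        for tris, fn in bcs.tractions:
            val = np.asarray(fn(t), dtype=float)
            a = self.mesh.nodes[tris[:, 1]] - self.mesh.nodes[tris[:, 0]]
            b = self.mesh.nodes[tris[:, 2]] - self.mesh.nodes[tris[:, 0]]
            area = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
            contrib = area[:, None] / 3.0  # equal lumping over P1 triangle
            for local in range(3):
                for d in range(3):
                    np.add.at(f, 3 * tris[:, local] + d, contrib[:, 0] * val[d])
        return f

    # -- time marching ----------------------------------------------------

    def run(self, times: Sequence[float], bcs: BoundaryConditions) -> StateSeries:
        """March through ``times`` (strictly increasing, starting at 0)."""
        times = np.asarray(times, dtype=float)
        if times[0] != 0.0 or np.any(np.diff(times) <= 0):
            raise ValueError("times must start at 0 and increase strictly")

        mesh = self.mesh
        N, M = mesh.n_nodes, mesh.n_elements

        dir_idx_parts, dir_fns = [], []
        for nodes, comp, fn in bcs.dirichlet_u:
            dir_idx_parts.append(3 * np.asarray(nodes) + comp)
            dir_fns.append((len(dir_idx_parts[-1]), fn))
        dir_idx_parts.append(self.n_u + np.asarray(bcs.dirichlet_p))
        dir_fns.append((len(bcs.dirichlet_p), lambda t: 0.0))
        dir_idx = np.concatenate(dir_idx_parts)
        if len(np.unique(dir_idx)) != len(dir_idx):
            # overlapping sets (e.g. face edges shared between planes with
            # the same component) are merged keeping the first occurrence
            _, keep = np.unique(dir_idx, return_index=True)
            keep.sort()
        else:
            keep = np.arange(len(dir_idx))

        def dirichlet_values(t: float) -> np.ndarray:
            parts = []
            for (n, fn) in dir_fns:
                parts.append(np.full(n, float(fn(t))))
            return np.concatenate(parts)[keep]

        dir_idx = dir_idx[keep]
        free_mask = np.ones(self.ndof)
        free_mask[dir_idx] = 0.0

        if self.K.shape[0] + self.S.shape[0] != self.ndof:
            raise ConfigurationError("inconsistent dof count")

        e = np.full(M, np.nan)
        e[:] = self.mat["e0"]
        k = self.k0_um2.copy()
        u = np.zeros((N, 3))
        p = np.zeros(N)
        series = StateSeries(mesh=mesh, materials=self.materials)
        series.states.append(SolutionState(0.0, u.copy(), p.copy(), e.copy(), k.copy()))

        lu = None
        scale = None
        A = None
        A_dir_cols = None
        k_fact = None
        dt_fact = None

        for n_step in range(1, len(times)):
            t = times[n_step]
            dt = t - times[n_step - 1]

            if self.nonlinear_permeability:
                k = con.permeability_update(e, self.mat["e0"], self.k0_um2,
                                            self.mat["M"])
            refactor = (
                lu is None
                or abs(dt - dt_fact) > 1e-12 * dt
                or np.max(np.abs(k / k_fact - 1.0)) > self.refactor_rtol
            )
            if refactor:
                H = self._flow_matrix(k)
                A = sparse.bmat(
                    [[self.K, -self.Q], [-self.Q.T, -(dt * H + self.S)]],
                    format="csr",
                )
                Dm = sparse.diags(free_mask)
                A_bc = (Dm @ A @ Dm + sparse.diags(1.0 - free_mask)).tocsc()
                diag = np.abs(A_bc.diagonal())
                if np.any(diag == 0.0):
                    bad = int(np.flatnonzero(diag == 0.0)[0])
                    raise ConfigurationError(
                        f"singular system: zero diagonal at dof {bad} "
                        "(insufficient constraints / floating null-space mode)"
                    )
                scale = 1.0 / np.sqrt(diag)
                Ds = sparse.diags(scale)
                A_s = (Ds @ A_bc @ Ds).tocsc()
                lu = splu(A_s)
                A_dir_cols = A[:, dir_idx].tocsc()
                k_fact = k.copy()
                dt_fact = dt
                series.n_factorizations += 1

            rhs = self._traction_rhs(bcs, t)
            rhs[self.n_u:] -= self.Q.T @ u.ravel() + self.S @ p
            vals = dirichlet_values(t)
            rhs = rhs - A_dir_cols @ vals
            rhs[dir_idx] = vals

            b_s = scale * rhs
            y = lu.solve(b_s)
            x = scale * y
            u = x[: self.n_u].reshape(N, 3)
            p = x[self.n_u:]

            nrm = np.linalg.norm(b_s)
            res = float(np.linalg.norm(A_s @ y - b_s) / (nrm if nrm > 0 else 1.0))
            series.residuals.append(res)

            eps_v = np.einsum("eik,eik->e", mesh.grads, u[mesh.elems])
            try:
                e = con.void_ratio_from_volumetric_strain(self.mat["e0"], eps_v)
            except con.PoreCollapseError as exc:
                raise con.PoreCollapseError(
                    f"at step {n_step} (t = {t:.4g} s): {exc}"
                ) from exc
            e = np.asarray(e)
            series.states.append(
                SolutionState(t, u.copy(), p.copy(), e.copy(), k.copy())
            )
            logger.debug("step %d t=%.4g refactor=%s", n_step, t, refactor)

        return series


def octant_boundary_conditions(mesh: Mesh, geom: LabeledGeometry,
                               load_case: LoadCase) -> BoundaryConditions:
    """Study protocol constraints on the octant mesh.

    Zero normal displacement on the three symmetry planes; ramp-hold
    compressive displacement on the loading face (normal component only;
    lateral exterior faces traction-free); p = 0 on every exterior
    (non-symmetry) face; no flux through symmetry planes (natural).
    """
    required = {"sym_x", "sym_y", "sym_z", "load"}
    if not required <= set(mesh.facets):
        raise ConfigurationError(
            f"mesh lacks facet sets {required - set(mesh.facets)}"
        )
    load_dim = _AXIS_INDEX[load_case.load_axis]
    u_peak = peak_displacement(load_case, geom)
    T, rf = load_case.period_T, load_case.ramp_fraction

    def load_fn(t: float) -> float:
        return -ramp_hold_displacement(t, T, rf, u_peak)

    dirichlet_u = []
    for d, nm in enumerate("xyz"):
        dirichlet_u.append((mesh.facet_nodes(f"sym_{nm}"), d, lambda t: 0.0))
    dirichlet_u.append((mesh.facet_nodes("load"), load_dim, load_fn))

    exterior = [k for k in mesh.facets if k.startswith("exterior_")]
    drained = mesh.facet_nodes("load", *exterior)
    return BoundaryConditions(dirichlet_u=dirichlet_u, dirichlet_p=drained)


def run_consolidation(
    mesh: Mesh,
    materials: dict[int, MaterialProps],
    load_case: LoadCase,
    geom: LabeledGeometry,
    c_stab: float = 0.1,
    refactor_rtol: float = 1.0e-3,
    nonlinear_permeability: bool = True,
) -> StateSeries:
    """Run the full ramp-hold consolidation protocol on the octant."""
    solver = BiotSolver(
        mesh,
        materials,
        c_stab=c_stab,
        refactor_rtol=refactor_rtol,
        nonlinear_permeability=nonlinear_permeability,
    )
    bcs = octant_boundary_conditions(mesh, geom, load_case)
    return solver.run(load_case.times, bcs)
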