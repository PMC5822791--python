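"""Closed-form verification problems for the consolidation solver.

The solver is verified against mathematics rather than against other
software: one-dimensional Terzaghi consolidation of a uniformly loaded,
single-drained column (exercising the coupled u-p discretization and the
backward-Euler marching), and the drained homogeneous block limit
(exercising boundary conditions and the elastic limit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fem
from .constitutive import ECM, MaterialProps
from .meshing import Mesh, box_mesh

__all__ = [
    "ColumnProblem",
    "terzaghi_pressure",
    "terzaghi_truncation_bound",
    "run_column_consolidation",
    "column_pressure_error",
    "homogeneous_block_solution",
]


@dataclass(frozen=True)
class ColumnProblem:
    """Single-drained consolidation column (SI units).

    A column of length ``L`` (m) is loaded at its drained top face by a
    constant compressive stress ``sigma0`` (Pa) applied at t = 0+ under
    laterally confined (oedometer) conditions; the bottom and lateral
    faces are impermeable.  With Biot coefficient 1 and incompressible
    constituents the initial excess pore pressure equals ``sigma0`` and
    decays by diffusion with consolidation coefficient
    ``cv = k * M_c / mu`` where ``M_c`` is the constrained modulus.
    """

    L: float = 8.0e-6
    E: float = 40.0e3
    nu: float = 0.40
    k: float = 4.0e-20
    mu: float = 1.0e-3
    sigma0: float = 1.0e3

    def __post_init__(self) -> None:
        for name in ("L", "E", "k", "mu", "sigma0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError("nu must lie in [0, 0.5)")

    @property
    def constrained_modulus(self) -> float:
        E, nu = self.E, self.nu
        return E * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu))

    @property
    def cv(self) -> float:
        """Consolidation coefficient (m^2/s)."""
        return self.k * self.constrained_modulus / self.mu

    @property
    def t_char(self) -> float:
        """Characteristic consolidation time L^2 / cv (s)."""
        return self.L**2 / self.cv


def terzaghi_pressure(z, t, column: ColumnProblem, n_terms: int = 200):
    """Series solution for excess pore pressure.

    ``z`` is the distance from the drained face (0 <= z <= L).  The
    standard single-drained Fourier series

        p(z, t) = sum_m  (4 p0 / (m pi)) sin(m pi z / (2 L)) exp(-(m pi / 2)^2 Tv)

    over odd m, with Tv = cv t / L^2 and p0 = sigma0.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be at least 1")
    z = np.asarray(z, dtype=float)
    if np.any(z < -1e-12) or np.any(z > column.L * (1 + 1e-12)):
        raise ValueError("z must lie in [0, L]")
    Tv = column.cv * t / column.L**2
    m = 2 * np.arange(n_terms) + 1  # odd integers
    amp = 4.0 * column.sigma0 / (m * np.pi)
    decay = np.exp(-((m * np.pi / 2.0) ** 2) * Tv)
    phase = np.sin(m[:, None] * np.pi * z.ravel()[None, :] / (2.0 * column.L))
    p = (amp * decay) @ phase
    return p.reshape(z.shape) if z.ndim else float(p[0])


def terzaghi_truncation_bound(t, column: ColumnProblem, n_terms: int) -> float:
    """Crude bound on the magnitude of the first omitted series term."""
    m = 2 * n_terms + 1
    Tv = column.cv * t / column.L**2
    return float(4.0 * column.sigma0 / (m * np.pi) * np.exp(-((m * np.pi / 2) ** 2) * Tv))


def _column_mesh(column: ColumnProblem, ny: int, n_cross: int = 2) -> Mesh:
    """Box mesh of the column in solver units (micrometres), drainage
    along +y.  The cross-section is structurally inert (confined)."""
    L_um = column.L * 1e6
    a_um = max(L_um / ny, L_um / 8.0)
    return box_mesh(
        (a_um, L_um, a_um), (n_cross, ny, n_cross), label=ECM
    )


def run_column_consolidation(
    column: ColumnProblem,
    ny: int = 40,
    n_steps: int = 60,
    t_end: float | None = None,
    t0_frac: float = 1.0e-3,
    c_stab: float = 0.1,
    _mobility_sign: float = 1.0,
) -> fem.StateSeries:
    """Solve the column numerically with the package's Biot solver.

    The stress step at t = 0+ is applied in full from the first time
    step; time points are geometrically graded between ``t0_frac * t_end``
    and ``t_end`` to resolve the early steep transient.
    """
    if t_end is None:
        t_end = 0.2 * column.t_char
    mesh = _column_mesh(column, ny)
    mat = MaterialProps(E=column.E, nu=column.nu, k0=column.k, e0=1.0,
                        M=0.0, mu_f=column.mu)
    solver = fem.BiotSolver(
        mesh, {ECM: mat}, c_stab=c_stab, nonlinear_permeability=False
    )
    solver._mobility_sign = _mobility_sign  # negative-control test hook

    def traction(t: float) -> np.ndarray:
        return np.array([0.0, -column.sigma0, 0.0])

    bcs = fem.BoundaryConditions(
        dirichlet_u=[
            (mesh.facet_nodes("y0"), 1, lambda t: 0.0),
            (mesh.facet_nodes("x0", "x1"), 0, lambda t: 0.0),
            (mesh.facet_nodes("z0", "z1"), 2, lambda t: 0.0),
        ],
        dirichlet_p=mesh.facet_nodes("y1"),
        tractions=[(mesh.facets["y1"], traction)],
    )
    times = np.concatenate([[0.0], t_end * np.geomspace(t0_frac, 1.0, n_steps)])
    return solver.run(times, bcs)


def column_pressure_error(
    column: ColumnProblem,
    ny: int = 40,
    n_steps: int = 60,
    t_end: float | None = None,
    n_terms: int = 200,
    _mobility_sign: float = 1.0,
) -> float:
    """Relative L2 error of the numerical pressure profile at ``t_end``
    against the Terzaghi series, over the column's pressure nodes."""
    if t_end is None:
        t_end = 0.2 * column.t_char
    series = run_column_consolidation(column, ny=ny, n_steps=n_steps, t_end=t_end,
                                      _mobility_sign=_mobility_sign)
    mesh = series.mesh
    state = series[-1]
    z_from_drained = column.L - mesh.nodes[:, 1] * 1e-6
    p_exact = terzaghi_pressure(z_from_drained, t_end, column, n_terms=n_terms)
    return float(
        np.linalg.norm(state.p - p_exact) / np.linalg.norm(p_exact)
    )


def homogeneous_block_solution(global_strain: float, E: float, nu: float):
    """Uniform drained state of a homogeneous block under uniaxial
    compressive strain with traction-free lateral faces.

    Returns the uniform strain tensor (axial component ``-global_strain``,
    lateral components ``+nu * global_strain``) and zero steady pore
    pressure.  The strain amplification factor of this configuration is
    exactly 1.
    """
    eps = np.diag([nu * global_strain, -global_strain, nu * global_strain])
    return {"strain": eps, "pressure": 0.0, "amplification": 1.0}
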