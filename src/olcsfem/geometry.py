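"""Parametric octant geometry of the osteocyte lacunar-canalicular system.

The idealized model is a cube of mineralized extracellular matrix (ECM)
containing a single triaxial-ellipsoidal lacuna at its centre,

    (x/l)**2 + (y/m)**2 + (z/n)**2 = 1,

with semiaxes (l, m, n) along the minor / major / intermediate local axes.
The osteocyte cell body is a concentric ellipsoid offset inward by the
perilacunar-matrix (PCM) thickness; straight canaliculi (thin cylindrical
channels) radiate from the lacuna to the cube faces along coordinate axes,
each containing a coaxial, thinner cell process.  The annulus between
process and canalicular wall belongs to the PCM region (PCM and canalicular
space are modelled as one solid poroelastic component), so exactly three
regions tile the domain: ECM, PCM (shell + canalicular annuli), CELL
(body + processes).

Because the model is mirror-symmetric about the three coordinate planes
through the lacuna centre, only the positive octant [0, L/2]^3 is built.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import integrate

from .constitutive import CELL, ECM, PCM

__all__ = ["GeometryParams", "LabeledGeometry", "GeometryError",
           "build_octant_geometry", "probe_points"]

_AXES = ("x", "y", "z")
_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class GeometryError(ValueError):
    """A geometry parameter violates a model invariant."""


@dataclass(frozen=True)
class GeometryParams:
    """Parameters of the idealized octant model (lengths in micrometres).

    Defaults: 43 um ECM cube; lacuna semiaxes (3, 9, 5) um -- the lacunar
    dimensions are configuration, not literature constants, chosen
    human-plausible with minor axis x, major axis y, intermediate z;
    0.75 um PCM thickness (middle of the reported 0.5-1 um range);
    0.25 um canaliculi with 0.15 um processes, one canaliculus along each
    positive coordinate axis; compression along y.
    """

    ecm_side: float = 43.0
    lacuna_semiaxes: tuple[float, float, float] = (3.0, 9.0, 5.0)
    pcm_thickness: float = 0.75
    canaliculus_diameter: float = 0.25
    process_diameter: float = 0.15
    canaliculi_axes: tuple[str, ...] = ("x", "y", "z")
    load_axis: str = "y"

    def __post_init__(self) -> None:
        if self.ecm_side <= 0:
            raise GeometryError("ecm_side must be positive")
        if len(self.lacuna_semiaxes) != 3 or any(s <= 0 for s in self.lacuna_semiaxes):
            raise GeometryError("lacuna_semiaxes must be three positive lengths")
        if self.pcm_thickness <= 0:
            raise GeometryError("pcm_thickness must be positive")
        if any(s - self.pcm_thickness <= 0 for s in self.lacuna_semiaxes):
            raise GeometryError(
                "cell-body semiaxes (lacuna semiaxes minus pcm_thickness) "
                "must be strictly positive"
            )
        if any(s >= self.ecm_side / 2 for s in self.lacuna_semiaxes):
            raise GeometryError("lacuna must fit strictly inside the cube "
                                "(each semiaxis < ecm_side/2)")
        if not (0 < self.process_diameter < self.canaliculus_diameter):
            raise GeometryError(
                "process_diameter must satisfy 0 < process < canaliculus "
                f"(got {self.process_diameter} vs {self.canaliculus_diameter})"
            )
        if any(a not in _AXES for a in self.canaliculi_axes):
            raise GeometryError("canaliculi_axes entries must be 'x', 'y' or 'z'")
        if len(set(self.canaliculi_axes)) != len(self.canaliculi_axes):
            raise GeometryError("canaliculi_axes must not repeat")
        if self.load_axis not in _AXES:
            raise GeometryError("load_axis must be one of 'x', 'y', 'z'")

    @property
    def half_side(self) -> float:
        return self.ecm_side / 2.0

    @property
    def cell_semiaxes(self) -> tuple[float, float, float]:
        t = self.pcm_thickness
        return tuple(s - t for s in self.lacuna_semiaxes)

    @property
    def canaliculus_radius(self) -> float:
        return self.canaliculus_diameter / 2.0

    @property
    def process_radius(self) -> float:
        return self.process_diameter / 2.0


def _transverse_r2(pts: np.ndarray, axis: int) -> np.ndarray:
    """Squared distance to the given coordinate axis."""
    others = [i for i in range(3) if i != axis]
    return pts[:, others[0]] ** 2 + pts[:, others[1]] ** 2


def _cap_volume(radius: float, semiaxes, axis: int, half_side: float) -> float:
    """Quarter-cylinder volume outside an origin-centred ellipsoid.

    Volume of {transverse radius <= radius, both transverse coords >= 0,
    axial coordinate between the ellipsoid surface and the octant face}.
    The transverse disk is assumed to lie entirely within the ellipsoid's
    waist, which holds for canalicular radii much smaller than the
    semiaxes.  Evaluated by adaptive quadrature in polar coordinates.
    """
    if radius == 0.0:
        return 0.0
    others = [i for i in range(3) if i != axis]
    sa, sb = semiaxes[others[0]], semiaxes[others[1]]
    s_ax = semiaxes[axis]

    def integrand(rho, theta):
        arg = 1.0 - (rho * np.cos(theta) / sa) ** 2 - (rho * np.sin(theta) / sb) ** 2
        surf = s_ax * np.sqrt(max(arg, 0.0))
        return (half_side - surf) * rho

    val, _ = integrate.dblquad(integrand, 0.0, np.pi / 2.0, 0.0, radius,
                               epsabs=1e-13, epsrel=1e-12)
    return val


def _ellipsoid_octant_volume(semiaxes) -> float:
    a, b, c = semiaxes
    return (4.0 / 3.0) * np.pi * a * b * c / 8.0


@dataclass(frozen=True)
class LabeledGeometry:
    """Region predicate and analytic volumes for the octant model."""

    params: GeometryParams

    def region_of(self, pts: np.ndarray) -> np.ndarray:
        """Classify points of the octant into {ECM, PCM, CELL}.

        Precedence: CELL (body ellipsoid or any process core), then PCM
        (lacunar shell or canalicular annulus), else ECM.  Every octant
        point receives exactly one label.
        """
        p = self.params
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        cs = np.array(p.cell_semiaxes)
        ls = np.array(p.lacuna_semiaxes)

        in_cell_ell = ((pts / cs) ** 2).sum(axis=1) <= 1.0
        in_lacuna = ((pts / ls) ** 2).sum(axis=1) <= 1.0

        in_process = np.zeros(len(pts), dtype=bool)
        in_canal = np.zeros(len(pts), dtype=bool)
        for ax_name in p.canaliculi_axes:
            r2 = _transverse_r2(pts, _AXIS_INDEX[ax_name])
            in_process |= r2 <= p.process_radius**2
            in_canal |= r2 <= p.canaliculus_radius**2

        labels = np.full(len(pts), ECM, dtype=np.int32)
        labels[in_lacuna | in_canal] = PCM
        labels[in_cell_ell | in_process] = CELL
        return labels

    @cached_property
    def region_volumes(self) -> dict[int, float]:
        """Analytic region volumes (um^3) over the octant.

        Ellipsoid octants in closed form; the cylindrical caps between the
        ellipsoid surfaces and the cube faces by high-accuracy quadrature.
        Each region's volume is computed from its own constructive
        expression (no region by subtraction of the others), so summing to
        the octant volume is a genuine consistency check.
        """
        p = self.params
        Y = p.half_side
        cs, ls = p.cell_semiaxes, p.lacuna_semiaxes
        r_p, r_c = p.process_radius, p.canaliculus_radius

        v_cell = _ellipsoid_octant_volume(cs)
        v_pcm = _ellipsoid_octant_volume(ls) - _ellipsoid_octant_volume(cs)
        v_ecm = Y**3 - _ellipsoid_octant_volume(ls)
        for ax_name in p.canaliculi_axes:
            ax = _AXIS_INDEX[ax_name]
            cap_p_cell = _cap_volume(r_p, cs, ax, Y)   # process core beyond cell body
            cap_p_lac = _cap_volume(r_p, ls, ax, Y)    # process core beyond lacuna
            cap_c_lac = _cap_volume(r_c, ls, ax, Y)    # full canaliculus beyond lacuna
            v_cell += cap_p_cell
            # core crossing the shell leaves the PCM; annulus beyond the
            # lacuna joins it
            v_pcm += -(cap_p_cell - cap_p_lac) + (cap_c_lac - cap_p_lac)
            v_ecm -= cap_c_lac
        return {ECM: v_ecm, PCM: v_pcm, CELL: v_cell}

    @property
    def octant_volume(self) -> float:
        return self.params.half_side**3


def build_octant_geometry(params: GeometryParams | None = None) -> LabeledGeometry:
    """Construct the labeled octant geometry (validates parameters)."""
    if params is None:
        params = GeometryParams()
    return LabeledGeometry(params=params)


def probe_points(geom: LabeledGeometry) -> dict[str, np.ndarray]:
    """The five reporting points A-E along the load-axis process line.

    All five lie on the load axis (the straight line through the lacuna
    centre along the loaded canaliculus) and inside the CELL region:

    - A: distal end of the load-axis process, on the loading face;
    - B: on the process just outside the lacuna (process/PCM junction);
    - C: top of the cell body, just inside its surface near that junction;
    - D: mid-height of the octant cell body;
    - E: bottom of the octant cell body (the lacuna centre, on the
      symmetry planes).
    """
    p = geom.params
    if p.load_axis not in p.canaliculi_axes:
        raise GeometryError(
            f"no canaliculus along load axis {p.load_axis!r}; probe points "
            "A and B require the load-axis process"
        )
    ax = _AXIS_INDEX[p.load_axis]
    s_lac = p.lacuna_semiaxes[ax]
    s_cell = p.cell_semiaxes[ax]

    def on_axis(c):
        v = np.zeros(3)
        v[ax] = c
        return v

    pts = {
        "A": on_axis(p.half_side),
        "B": on_axis(s_lac + 0.5 * p.pcm_thickness),
        "C": on_axis(0.98 * s_cell),
        "D": on_axis(0.5 * s_cell),
        "E": on_axis(0.0),
    }
    labels = geom.region_of(np.array(list(pts.values())))
    assert np.all(labels == CELL), "probe points must lie in the CELL region"
    return pts
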