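"""Poroelastic constitutive relations.

The solid skeleton of each region (mineralized matrix, perilacunar matrix,
osteocyte) is isotropic linear elastic.  The pore space is fully saturated by
an incompressible fluid and the Biot effective-stress coefficient is one, so
total stress decomposes as

    sigma_T = sigma_E - p * I

with ``sigma_E`` the effective (skeleton) stress and ``p`` the pore pressure.
Fluid transport follows Darcy's law with an intrinsic permeability that
stiffens or loosens with skeleton dilatation through the void ratio
(exponential strain-dependent permeability law).

All functions accept scalars or numpy arrays and broadcast elementwise.
Units: stresses and moduli in Pa, permeability in m**2, viscosity in Pa*s;
strains, void ratio and porosity are dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ECM",
    "PCM",
    "CELL",
    "REGION_NAMES",
    "MaterialProps",
    "DomainError",
    "PoreCollapseError",
    "default_materials",
    "porosity_from_void_ratio",
    "void_ratio_from_porosity",
    "void_ratio_from_volumetric_strain",
    "permeability_update",
    "lame_parameters",
    "effective_and_total_stress",
]

# Region labels shared across the package (mesh cell data, material tables).
ECM = 1
PCM = 2
CELL = 3
REGION_NAMES = {ECM: "ECM", PCM: "PCM", CELL: "CELL"}


class DomainError(ValueError):
    """Input outside the physical domain of a constitutive relation."""


class PoreCollapseError(RuntimeError):
    """Compaction exhausted the pore space (void ratio dropped to zero)."""


@dataclass(frozen=True)
class MaterialProps:
    """Poroelastic constants of one region.

    Parameters
    ----------
    E : float
        Drained Young's modulus [Pa].
    nu : float
        Drained Poisson ratio.
    k0 : float
        Intrinsic permeability at the reference void ratio [m**2].
    e0 : float
        Reference (initial) void ratio.
    M : float
        Exponent of the strain-dependent permeability law; ``M = 0``
        disables the exponential factor.
    mu_f : float
        Pore-fluid dynamic viscosity [Pa*s] (water at body temperature
        is conventionally taken as 1e-3).
    """

    E: float
    nu: float
    k0: float
    e0: float
    M: float = 4.638
    mu_f: float = 1.0e-3

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise DomainError(f"Young's modulus must be positive, got {self.E}")
        if not (0.0 <= self.nu < 0.5):
            raise DomainError(f"Poisson ratio must satisfy 0 <= nu < 0.5, got {self.nu}")
        if not self.k0 > 0:
            raise DomainError(f"permeability k0 must be positive, got {self.k0}")
        if not self.e0 > 0:
            raise DomainError(f"void ratio e0 must be positive, got {self.e0}")
        if not self.mu_f > 0:
            raise DomainError(f"viscosity mu_f must be positive, got {self.mu_f}")

    @property
    def nf0(self) -> float:
        """Reference porosity e0 / (1 + e0)."""
        return float(porosity_from_void_ratio(self.e0))


def default_materials() -> dict[int, MaterialProps]:
    """Default material table for the three regions.

    ECM: stiff mineralized bone matrix (11 GPa, nearly dense: e0 = 0.053,
    i.e. ~5% lacunocanalicular porosity).  PCM: soft hydrated pericellular
    layer (40 kPa, e0 = 4).  CELL: osteocyte body and processes
    (3.1 kPa, e0 = 4.88).  Permeabilities are of order 1e-20..1e-19 m**2.
    """
    return {
        ECM: MaterialProps(E=11.0e9, nu=0.38, k0=1.0e-20, e0=0.053),
        PCM: MaterialProps(E=40.0e3, nu=0.40, k0=4.0e-20, e0=4.0),
        CELL: MaterialProps(E=3.1e3, nu=0.35, k0=0.6e-19, e0=4.88),
    }


def porosity_from_void_ratio(e):
    """Porosity nf = e / (1 + e) from void ratio ``e``.

    Raises
    ------
    DomainError
        If any ``e <= -1`` (total volume would be non-positive).
    """
    e = np.asarray(e, dtype=float)
    if np.any(e <= -1.0):
        raise DomainError("void ratio must exceed -1")
    out = e / (1.0 + e)
    return out if out.ndim else float(out)


def void_ratio_from_porosity(nf):
    """Inverse of :func:`porosity_from_void_ratio`: e = nf / (1 - nf)."""
    nf = np.asarray(nf, dtype=float)
    if np.any(nf >= 1.0):
        raise DomainError("porosity must be below 1")
    out = nf / (1.0 - nf)
    return out if out.ndim else float(out)


def void_ratio_from_volumetric_strain(e0, eps_v, where=None):
    """Current void ratio under volumetric strain ``eps_v``.

    The solid grains are volume-conserving, so at small strain the whole
    volume change is carried by the pore space:

        e = e0 + (1 + e0) * eps_v

    Parameters
    ----------
    e0 : array_like
        Reference void ratio.
    eps_v : array_like
        Volumetric strain (trace of the small-strain tensor; negative in
        compaction).
    where : array_like of int, optional
        Element ids used to identify offenders in the pore-collapse error.
    """
    e0 = np.asarray(e0, dtype=float)
    eps_v = np.asarray(eps_v, dtype=float)
    e = e0 + (1.0 + e0) * eps_v
    if np.any(e <= 0.0):
        bad = np.nonzero(np.atleast_1d(e <= 0.0))[0]
        ids = bad if where is None else np.asarray(where)[bad]
        raise PoreCollapseError(
            f"compaction exhausted the pore space in {bad.size} element(s); "
            f"first offending element id: {ids.flat[0]}"
        )
    return e if e.ndim else float(e)


def permeability_update(e, e0, k0, M):
    """Strain-dependent intrinsic permeability.

        k = k0 * [ e (1 + e0) / (e0 (1 + e)) ]**2
               * exp( M * ( (1 + e) / (1 + e0) - 1 ) )

    The squared factor is the Kozeny-like porosity-ratio term
    (nf/nf0)**2 and the exponential captures additional loosening of the
    pore network with dilatation.  ``k(e0) == k0`` identically.
    """
    e = np.asarray(e, dtype=float)
    e0 = np.asarray(e0, dtype=float)
    if np.any(e <= 0.0) or np.any(e0 <= 0.0):
        raise DomainError("void ratios must be positive in the permeability law")
    ratio = (e * (1.0 + e0)) / (e0 * (1.0 + e))
    k = k0 * ratio**2 * np.exp(M * ((1.0 + e) / (1.0 + e0) - 1.0))
    return k if k.ndim else float(k)


def lame_parameters(E, nu):
    """Lame constants (lam, G) of an isotropic solid."""
    E = np.asarray(E, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if np.any(nu >= 0.5):
        raise DomainError("nu >= 0.5 (incompressible limit) not supported pointwise")
    G = E / (2.0 * (1.0 + nu))
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return lam, G


def effective_and_total_stress(eps, p, E, nu):
    """Effective (skeleton) and total stress from strain and pore pressure.

    Parameters
    ----------
    eps : array_like, shape (..., 3, 3)
        Small-strain tensor(s).
    p : array_like
        Pore pressure, broadcastable against the leading axes of ``eps``.

    Returns
    -------
    (sigma_E, sigma_T) : ndarray pair, shape (..., 3, 3)
        ``sigma_E`` by the isotropic Hooke law, ``sigma_T = sigma_E - p I``.
    """
    eps = np.asarray(eps, dtype=float)
    if eps.shape[-2:] != (3, 3):
        raise ValueError("strain must have trailing shape (3, 3)")
    lam, G = lame_parameters(E, nu)
    tr = np.trace(eps, axis1=-2, axis2=-1)
    eye = np.eye(3)
    sigma_e = (
        np.asarray(lam)[..., None, None] * tr[..., None, None] * eye
        + 2.0 * np.asarray(G)[..., None, None] * eps
    )
    sigma_t = sigma_e - np.asarray(p, dtype=float)[..., None, None] * eye
    return sigma_e, sigma_t


def with_overrides(mat: MaterialProps, **kwargs) -> MaterialProps:
    """Copy of ``mat`` with selected fields replaced (validated)."""
    return replace(mat, **kwargs)
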