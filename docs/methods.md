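# Methods

`olcsfem` simulates the mechanical and fluid environment of a single
osteocyte embedded in mineralized bone — the osteocyte–lacunar–canalicular
system (OLCS) — under ramped uniaxial compression, using linear Biot
poroelasticity with a strain-dependent permeability law.  This note
records the model, its assumptions, the numerical scheme, the choices made
where the design was genuinely open, and the limits of what the results
mean.

## Model

**Domain.** A cube of extracellular matrix (ECM) of side `L = 43 um`
contains a triaxial-ellipsoidal lacuna at its centre,
`(x/l)^2 + (y/m)^2 + (z/n)^2 = 1`, holding the osteocyte cell body; the
gap between cell and mineralized wall is the perilacunar matrix (PCM),
a soft hydrated layer 0.5–1 um thick.  Thin straight canaliculi
(diameter 0.25 um) run from the lacuna to the cube faces along the
coordinate axes, each containing a coaxial cell process; the annulus
between process and canalicular wall is part of the PCM component, so the
domain is tiled by exactly three materials: ECM, PCM (shell + annuli) and
CELL (body + processes).  All three mirror symmetries are exploited and
only the positive octant `[0, L/2]^3` is discretized, with symmetry
boundary conditions on the coordinate planes.

**Field equations.**  With displacement `u` and pore pressure `p`,

    div( sigma_E(u) - p I ) = 0
    d/dt (div u) + div q = 0,        q = -(k/mu_f) grad p

i.e. quasi-static momentum balance with the effective-stress split
`sigma_T = sigma_E - p I` (Biot coefficient 1), and mass balance of an
incompressible pore fluid in an incompressible solid skeleton (no
storativity beyond skeleton dilatation — the medium is fully saturated).
`sigma_E` is isotropic linear elasticity per region.

**Strain-dependent permeability.**  Porosity `nf = e/(1+e)` and void
ratio `e` evolve with volumetric strain as `e = e0 + (1+e0) eps_v`
(solid-grain volume conserved at small strain), and the intrinsic
permeability follows the exponential void-ratio law

    k = k0 [ e(1+e0) / (e0(1+e)) ]^2 exp( M ((1+e)/(1+e0) - 1) )

with `k(e0) = k0` identically.  `M` is not experimentally constrained for
this system; the default `M = 4.638` is a standard soft-tissue literature
value and `M = 0` disables the exponential factor.  At the strain levels
simulated the law perturbs `k` by at most tens of percent.

**Loading protocol.**  Displacement-controlled compression along one axis
(default `y`): the octant loading face moves by
`u(t) = -eps_global * L/2 * min(t/(0.1 T), 1)` — a linear ramp over the
first tenth of the period, then held.  Four load levels are studied:
150, 1000, 3000 and 5000 microstrain (disuse, physiological, overuse,
pathological overload).  All exterior (non-symmetry) faces are drained
(`p = 0`, no osmotic pressure); lateral exterior faces are traction-free;
symmetry planes carry zero normal displacement and zero flux.  Region
interfaces are perfectly bonded (shared nodes).

## Parameters

| parameter | default | units | status |
|---|---|---|---|
| ECM: `E, nu, k0, e0` | 11 GPa, 0.38, 1e-20 m², 0.053 | — | literature table |
| PCM: `E, nu, k0, e0` | 40 kPa, 0.40, 4e-20 m², 4.0 | — | literature table |
| CELL: `E, nu, k0, e0` | 3.1 kPa, 0.35, 6e-20 m², 4.88 | — | literature table |
| fluid viscosity `mu_f` | 1e-3 | Pa·s | water |
| lacuna semiaxes `(l, m, n)` | (3, 9, 5) | um | **configuration** — chosen human-plausible (minor x, major y, intermediate z); not a measured value |
| PCM thickness | 0.75 | um | midpoint of the reported 0.5–1 um range |
| canaliculus / process diameter | 0.25 / 0.15 | um | canaliculus from literature; process chosen < canaliculus |
| canaliculi | one per positive axis (3) | — | configuration; count/layout not constrained |
| period `T` | 1.0 | s | **configuration — rate matters, see below** |
| permeability exponent `M` | 4.638 | — | soft-tissue literature default |

**The period `T` is a material choice of this package, and pore pressure
and fluid velocity scale with loading *rate*, roughly as `1/T` during the
ramp.**  Nothing in the system pins `T`; reported pressures (kPa) and
velocities (um/s) must be read conditional on `T = 1 s`.  Strain maxima at
steady state are essentially `T`-independent.

## Discretization

* Mesh: deterministic graded tensor-product grid with breakpoints at every
  geometric feature radius/semiaxis, each hexahedral cell split into six
  tetrahedra (Kuhn pattern, conforming).  Elements are classified into
  regions by centroid, giving a staircase approximation of the curved
  interfaces whose region volumes match the analytic values to <1% at the
  default resolution (verified in the tests against closed-form ellipsoid
  volumes plus quadrature for the canalicular caps).  The default study
  mesh has ~3.7e4 tetrahedra / ~7.2e3 nodes (~2.9e4 coupled unknowns);
  `resolution` rescales all target spacings by 1.35 per level.
* Elements: equal-order linear (P1/P1) displacement–pressure interpolation
  with Brezzi–Pitkäranta pressure stabilization, coefficient
  `c_stab * h_e^2 / (lambda + 2G)` per element, `c_stab = 0.1`.  The
  undrained first step of the Terzaghi column shows no checkerboarding
  (over/undershoot < 2%).
* Time: backward Euler, 50 uniform steps per period (5 inside the ramp).
  The nonlinear permeability is lagged one step; the sparse LU
  factorization (SuperLU, COLAMD ordering, symmetric diagonal scaling of
  the 1e10-conditioned block system) is reused until the lagged
  permeability drifts by more than `refactor_rtol = 2%` anywhere, which
  bounds the extra lag error by the same 2% in mobility.
* Internal units are micrometres / pascals / seconds, in which Darcy flux
  is um/s directly and matrix entries stay within a tractable dynamic
  range before scaling.

## Verification

All checks run in the test suite against closed forms, not other software:

* **Terzaghi column** (single-drained, stress step, oedometer
  confinement): relative L2 pressure error < 1% at the stated resolution
  (40 axial elements, 60 geometrically graded steps, comparison at 20% of
  the characteristic time), strictly decreasing under refinement.
* **Drained homogeneous block**: uniform strain equal to the applied
  strain to 1e-6, amplification factor 1 within 2%, end-of-period pressure
  at the numerical-zero level.
* **Constitutive identities**: `k(e0) = k0` exactly; porosity/void-ratio
  round trips to machine precision; permeability monotone in `e` for
  `M >= 0` (checked against numerical differentiation).
* **Negative control**: flipping the sign of the Darcy mobility makes the
  verification suite fail (the anti-diffusive system collapses the pore
  space), so the checks genuinely constrain the physics.
* **Monotonicity**: peak pore pressure decreases when permeability
  increases tenfold and increases for sharper ramps; all reported maxima
  increase with the global load.

## Reporting conventions (and why they matter here)

The elastic contrast across the cell boundary is nearly seven orders of
magnitude (11 GPa vs 3.1 kPa).  Two consequences shape what this package
reports:

1. **Element-wise strain maxima do not converge.**  The
   canaliculus–PCM–process junction is a bimaterial corner; raw
   element-constant strain values there grow under mesh refinement.  The
   reported field is therefore the volume-weighted nodal recovery of the
   element principal-strain magnitudes (the same smoothing any contouring
   of FE output applies); raw element values remain available.
2. **The ramp creates a pressure boundary layer in the soft regions.**
   During the ramp the ECM carries a rate-driven pore pressure (~24 kPa at
   1000 microstrain, T = 1 s) while the much less diffusive PCM/cell
   interior lags behind; the pressure drop is accommodated in a layer of
   thickness `sqrt(c_v t)` — below 0.1 um in the cell at early times —
   whose effective-stress gradient strains the 3.1 kPa material by percent
   levels.  The peak of this excursion is *not* numerically converged at
   feasible resolutions: it changes severalfold with the stabilization
   constant and grows under time-step refinement.  The summary therefore
   reports the **steady-state (end-of-period) strain maximum** — robust
   across mesh, step and stabilization sweeps (amplification 4.1–4.2 in
   all variants) — as the headline maximum principal strain and
   amplification factor, and carries the transient excursion separately as
   `transient_peak_strain_ustrain`, flagged as a qualitative diagnostic.

Pore-pressure and velocity maxima are well-behaved and are reported over
the whole period; they peak at the end of the ramp (`t = 0.1 T`) at the
canaliculus–PCM–process junctions and decay during the hold.

## What the defaults predict

At the default conditions the four load cases give near-constant steady
amplification factors (~4.0, spread < 2%), steady maximum principal
strains of roughly 0.6e3 / 4.0e3 / 12.0e3 / 20.2e3 microstrain, peak
cell/process pore pressures of ~3.7 / 24.6 / 74.9 / 126.8 kPa at
`t = 0.1 T`, and peak seepage velocities of order 0.1–4 um/s located in
the ECM next to a canalicular wall.  Pressures and velocities scale with
loading rate: halving `T` roughly doubles both.  Literature peak-velocity
estimates for loaded bone (tens of um/s) correspond to faster effective
loading and/or a much more permeable mineralized matrix than the default
table assumes; with `k_ECM ~ 5e-15 m²` the model instead gives velocities
of 5–7 um/s, smooth ramp-peaked strain histories and near-zero cell
pressure.  The two regimes bracket the published range of OLCS
permeability estimates, which spans eight orders of magnitude; per-region
permeabilities are a one-line config change.

## The geometry generator as synthetic data

The geometry module *is* the data source of this package: it emulates an
idealized OLCS, not an imaged one.  Real lacunae are irregular, canaliculi
are numerous (tens to hundreds per lacuna), curved and branched, and the
PCM thickness varies.  Passing tests therefore demonstrate correctness of
the solver and pipeline under the idealized geometry, and the
physically-expected trends (amplification ~4, rate-driven kPa pressures,
junction concentration); they do not validate absolute magnitudes for real
osteocytes, which are sensitive to canalicular number and to the
permeability table.

## Limitations

* Staircase (centroid-labeled) material interfaces; no boundary-fitted
  meshing of the ellipsoid.
* Small-strain kinematics, although local transients in the cell reach
  percent strain during the ramp under the default material contrast.
* Equal-order stabilization adds a small artificial storage; its effect is
  quantified above and bounded in the verification problems.
* No osmotic pressure, no cyclic/frequency-domain loading, no
  viscoelasticity of the cell, isotropic permeability only.
* Probe-point orderings along the process line depend strongly on the ECM
  permeability regime (see above) and should not be over-interpreted.
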