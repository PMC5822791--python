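"""Run configuration: one YAML file drives the whole pipeline.

Schema (all keys optional; defaults reproduce the four-load-case study)::

    geometry:
      ecm_side: 43.0            # um
      lacuna_semiaxes: [3.0, 9.0, 5.0]
      pcm_thickness: 0.75
      canaliculus_diameter: 0.25
      process_diameter: 0.15
      canaliculi_axes: [x, y, z]
      load_axis: y
    materials:                  # per region; SI units
      ECM:  {E: 11.0e9, nu: 0.38, k0: 1.0e-20, e0: 0.053, M: 4.638, mu_f: 1.0e-3}
      PCM:  {E: 40.0e3, nu: 0.40, k0: 4.0e-20, e0: 4.0}
      CELL: {E: 3.1e3,  nu: 0.35, k0: 0.6e-19, e0: 4.88}
    load_cases:                 # list; strains in microstrain
      - {global_strain_ustrain: 150, period_T: 1.0, n_steps: 50, ramp_fraction: 0.1}
    solver:
      resolution: 1.0
      c_stab: 0.1
      refactor_rtol: 0.02
      nonlinear_permeability: true
    output:
      dir: results
      write_fields: false       # VTU snapshot series per case
    seed: 0                     # reserved; meshing is deterministic
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .constitutive import CELL, ECM, PCM, MaterialProps, default_materials
from .fem import LoadCase
from .geometry import GeometryParams

__all__ = ["RunConfig", "load_config", "default_load_cases"]

_REGION_BY_NAME = {"ECM": ECM, "PCM": PCM, "CELL": CELL}

#: The four compressive loading levels of the study, in microstrain:
#: disuse, physiological, overuse, pathological overload.
STUDY_LOADS_USTRAIN = (150.0, 1000.0, 3000.0, 5000.0)


def default_load_cases() -> list[LoadCase]:
    return [LoadCase(global_strain=u * 1e-6) for u in STUDY_LOADS_USTRAIN]


@dataclass
class RunConfig:
    geometry: GeometryParams = field(default_factory=GeometryParams)
    materials: dict[int, MaterialProps] = field(default_factory=default_materials)
    load_cases: list[LoadCase] = field(default_factory=default_load_cases)
    resolution: float = 1.0
    c_stab: float = 0.1
    refactor_rtol: float = 0.02
    nonlinear_permeability: bool = True
    outdir: Path = Path("results")
    write_fields: bool = False
    seed: int = 0

    def validate(self) -> "RunConfig":
        """Re-run every nested invariant check (dataclass constructors
        validate on construction; this re-validates after mutation)."""
        GeometryParams(**vars(self.geometry))
        for lab, mat in self.materials.items():
            if lab not in _REGION_BY_NAME.values():
                raise ValueError(f"unknown region label {lab}")
            MaterialProps(**{k: getattr(mat, k) for k in
                             ("E", "nu", "k0", "e0", "M", "mu_f")})
        for lc in self.load_cases:
            LoadCase(**{k: getattr(lc, k) for k in
                        ("global_strain", "ramp_fraction", "period_T",
                         "n_steps", "load_axis")})
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        return self


def _geometry_from(d: dict) -> GeometryParams:
    kw = dict(d)
    for key in ("lacuna_semiaxes", "canaliculi_axes"):
        if key in kw:
            kw[key] = tuple(kw[key])
    return GeometryParams(**kw)


def _materials_from(d: dict) -> dict[int, MaterialProps]:
    mats = default_materials()
    for name, fields_ in d.items():
        if name not in _REGION_BY_NAME:
            raise ValueError(f"unknown material region {name!r}")
        lab = _REGION_BY_NAME[name]
        mats[lab] = replace(mats[lab], **{k: float(v) for k, v in fields_.items()})
    return mats


def _load_case_from(d: dict) -> LoadCase:
    kw = dict(d)
    if "global_strain_ustrain" in kw:
        kw["global_strain"] = float(kw.pop("global_strain_ustrain")) * 1e-6
    return LoadCase(**kw)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Build a validated RunConfig from a YAML file plus overrides."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}

    cfg = RunConfig()
    if "geometry" in raw:
        cfg.geometry = _geometry_from(raw["geometry"])
    if "materials" in raw:
        cfg.materials = _materials_from(raw["materials"])
    if "load_cases" in raw:
        cfg.load_cases = [_load_case_from(d) for d in raw["load_cases"]]
    solver = raw.get("solver", {})
    cfg.resolution = float(solver.get("resolution", cfg.resolution))
    cfg.c_stab = float(solver.get("c_stab", cfg.c_stab))
    cfg.refactor_rtol = float(solver.get("refactor_rtol", cfg.refactor_rtol))
    cfg.nonlinear_permeability = bool(
        solver.get("nonlinear_permeability", cfg.nonlinear_permeability)
    )
    output = raw.get("output", {})
    cfg.outdir = Path(output.get("dir", cfg.outdir))
    cfg.write_fields = bool(output.get("write_fields", cfg.write_fields))
    cfg.seed = int(raw.get("seed", cfg.seed))
    return cfg.validate()
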