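# Default four-load-case study; every key is optional (defaults shown in
# src/olcsfem/config.py).  Strains are in microstrain; SI elsewhere.
geometry:
  ecm_side: 43.0
  lacuna_semiaxes: [3.0, 9.0, 5.0]
  pcm_thickness: 0.75
  canaliculus_diameter: 0.25
  process_diameter: 0.15
  canaliculi_axes: [x, y, z]
  load_axis: y
materials:
  ECM:  {E: 11.0e9, nu: 0.38, k0: 1.0e-20, e0: 0.053}
  PCM:  {E: 40.0e3, nu: 0.40, k0: 4.0e-20, e0: 4.0}
  CELL: {E: 3.1e3,  nu: 0.35, k0: 0.6e-19, e0: 4.88}
load_cases:
  - {global_strain_ustrain: 150}
  - {global_strain_ustrain: 1000}
  - {global_strain_ustrain: 3000}
  - {global_strain_ustrain: 5000}
solver:
  resolution: 1.0
  c_stab: 0.1
  refactor_rtol: 0.02
  nonlinear_permeability: true
output:
  dir: results
  write_fields: false
seed: 0
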