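import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from olcsfem.constitutive import default_materials
from olcsfem.fem import BiotSolver, LoadCase, octant_boundary_conditions
from olcsfem.geometry import build_octant_geometry
from olcsfem.meshing import mesh_geometry


@pytest.fixture(scope="session")
def geom():
    return build_octant_geometry()


@pytest.fixture(scope="session")
def materials():
    return default_materials()


@pytest.fixture(scope="session")
def coarse_mesh(geom):
    """Coarse octant mesh for fast unit tests (not the study default)."""
    return mesh_geometry(geom, resolution=0.3)


@pytest.fixture(scope="session")
def coarse_run_1000(geom, materials, coarse_mesh):
    """One full 1000-microstrain consolidation on the coarse mesh."""
    lc = LoadCase(global_strain=1000e-6)
    solver = BiotSolver(coarse_mesh, materials, refactor_rtol=0.02)
    series = solver.run(lc.times, octant_boundary_conditions(coarse_mesh, geom, lc))
    return lc, series
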