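"""Octant geometry: invariants, region predicate, analytic volumes."""

import numpy as np
import pytest

from olcsfem.constitutive import CELL, ECM, PCM
from olcsfem.geometry import (
    GeometryError,
    GeometryParams,
    build_octant_geometry,
    probe_points,
)


class TestParamsValidation:
    def test_defaults_valid(self):
        p = GeometryParams()
        assert p.half_side == pytest.approx(21.5)
        assert p.cell_semiaxes == pytest.approx((2.25, 8.25, 4.25))

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            ({"pcm_thickness": -0.1}, "pcm_thickness"),
            ({"pcm_thickness": 3.5}, "cell-body semiaxes"),
            ({"lacuna_semiaxes": (3.0, 25.0, 5.0)}, "fit strictly inside"),
            ({"process_diameter": 0.3}, "process"),
            ({"process_diameter": 0.0}, "process"),
            ({"canaliculi_axes": ("x", "w")}, "canaliculi_axes"),
            ({"load_axis": "q"}, "load_axis"),
        ],
    )
    def test_invariant_violations_named(self, kwargs, match):
        with pytest.raises(GeometryError, match=match):
            GeometryParams(**kwargs)


class TestRegionsAndVolumes:
    def test_octant_bounding_box(self, geom):
        # half of the 43 um cube side in every direction
        assert geom.params.half_side == pytest.approx(21.5)
        corners = np.array([[0, 0, 0], [21.5, 21.5, 21.5]])
        assert geom.region_of(corners).shape == (2,)

    def test_volumes_sum_to_octant(self, geom):
        # each region volume has its own constructive expression; the sum
        # matching the octant volume is a real consistency check
        vols = geom.region_volumes
        assert sum(vols.values()) == pytest.approx(21.5**3, rel=1e-9)
        assert all(v > 0 for v in vols.values())

    def test_predicate_partition_and_volumes_monte_carlo(self, geom):
        # seeded Monte Carlo integration of the predicate against the
        # quadrature volumes; biased sampling near the lacuna where the
        # small regions live
        rng = np.random.default_rng(20261001)
        n = 400_000
        box = np.array([4.0, 10.0, 6.0])   # contains lacuna + canal stubs
        pts_in = rng.random((n, 3)) * box
        labels = geom.region_of(pts_in)
        v_box = box.prod()
        vols = geom.region_volumes
        for lab in (PCM, CELL):
            mc = v_box * np.mean(labels == lab)
            # inner-box MC misses the canalicular parts beyond the box
            analytic_in_box = vols[lab] - _canal_volume_outside(geom, box, lab)
            assert mc == pytest.approx(analytic_in_box, rel=0.05)

    def test_every_point_exactly_one_region(self, geom):
        rng = np.random.default_rng(7)
        pts = rng.random((10_000, 3)) * 21.5
        labels = geom.region_of(pts)
        assert set(np.unique(labels)) <= {ECM, PCM, CELL}

    def test_empty_canaliculi_gives_pure_shell(self):
        geom = build_octant_geometry(GeometryParams(canaliculi_axes=()))
        vols = geom.region_volumes
        ell = lambda s: 4.0 / 3.0 * np.pi * s[0] * s[1] * s[2] / 8.0
        assert vols[CELL] == pytest.approx(ell((2.25, 8.25, 4.25)), rel=1e-12)
        assert vols[PCM] == pytest.approx(
            ell((3.0, 9.0, 5.0)) - ell((2.25, 8.25, 4.25)), rel=1e-12
        )
        # a point inside where the y canaliculus would run is now ECM
        assert geom.region_of(np.array([[0.05, 15.0, 0.05]]))[0] == ECM

    def test_mirror_symmetry_of_predicate(self, geom):
        # the octant predicate extends evenly: labels depend on |x|,|y|,|z|
        rng = np.random.default_rng(3)
        pts = rng.random((2000, 3)) * np.array([4.0, 10.0, 6.0])
        base = geom.region_of(pts)
        assert np.array_equal(base, geom.region_of(np.abs(pts * [1, 1, 1])))


def _canal_volume_outside(geom, box, lab):
    """Volume of the canalicular parts of region ``lab`` beyond the
    sampling box (straight channels of known radii along the axes)."""
    p = geom.params
    total = 0.0
    for ax_name, ax in (("x", 0), ("y", 1), ("z", 2)):
        if ax_name not in p.canaliculi_axes:
            continue
        length = p.half_side - box[ax]
        r_p, r_c = p.process_radius, p.canaliculus_radius
        if lab == CELL:
            total += 0.25 * np.pi * r_p**2 * length
        elif lab == PCM:
            total += 0.25 * np.pi * (r_c**2 - r_p**2) * length
    return total


class TestProbePoints:
    def test_positions(self, geom):
        pts = probe_points(geom)
        assert set(pts) == {"A", "B", "C", "D", "E"}
        # A on the loading face plane (load axis y)
        assert pts["A"][1] == pytest.approx(21.5)
        # E at the lacuna centre, on the symmetry planes
        np.testing.assert_allclose(pts["E"], 0.0)
        # all on the load-axis line
        for v in pts.values():
            assert v[0] == 0.0 and v[2] == 0.0

    def test_all_points_in_cell_region(self, geom):
        pts = probe_points(geom)
        labels = geom.region_of(np.array(list(pts.values())))
        assert np.all(labels == CELL)

    def test_requires_load_axis_canaliculus(self):
        geom = build_octant_geometry(GeometryParams(canaliculi_axes=("x", "z")))
        with pytest.raises(GeometryError, match="load axis"):
            probe_points(geom)
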