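"""Derived fields: principal strain, Darcy flow, probes, summaries."""

import numpy as np
import pytest

from olcsfem.constitutive import ECM, MaterialProps, default_materials
from olcsfem.fem import LoadCase, SolutionState, StateSeries
from olcsfem.meshing import box_mesh
from olcsfem.postprocess import (
    amplification_factor,
    darcy_flux_and_velocity,
    extract_probe_series,
    nodal_strain_magnitude,
    principal_strain_field,
    summarize,
)


@pytest.fixture(scope="module")
def tiny_mesh():
    return box_mesh((2.0, 3.0, 1.0), (2, 3, 2))


def _state(mesh, u=None, p=None, e=1.0, k_um2=1e-8, t=0.0):
    M = mesh.n_elements
    return SolutionState(
        t=t,
        u=np.zeros((mesh.n_nodes, 3)) if u is None else u,
        p=np.zeros(mesh.n_nodes) if p is None else p,
        e=np.full(M, float(e)),
        k_um2=np.full(M, float(k_um2)),
    )


class TestPrincipalStrain:
    def test_uniform_uniaxial_field(self, tiny_mesh):
        # affine displacement u_y = -eps * y with lateral Poisson expansion
        eps, nu = 1e-3, 0.35
        u = tiny_mesh.nodes * np.array([nu * eps, -eps, nu * eps])
        ps = principal_strain_field(tiny_mesh, u)
        # max-magnitude principal strain is the compressive axial one
        np.testing.assert_allclose(ps, -eps * 1e6, rtol=1e-9)
        np.testing.assert_allclose(
            nodal_strain_magnitude(tiny_mesh, u), eps * 1e6, rtol=1e-9
        )

    def test_rigid_translation_zero_strain(self, tiny_mesh):
        u = np.ones((tiny_mesh.n_nodes, 3)) * 0.37
        assert np.max(np.abs(principal_strain_field(tiny_mesh, u))) < 1e-6


class TestAmplification:
    @pytest.mark.parametrize(
        "local, global_, expected",
        [(4272.0, 1000.0, 4.272), (21528.0, 5000.0, 4.3056), (1000.0, 1000.0, 1.0)],
    )
    def test_ratio(self, local, global_, expected):
        assert amplification_factor(local, global_) == pytest.approx(expected)

    def test_zero_global_strain_rejected(self):
        with pytest.raises(ValueError):
            amplification_factor(1.0, 0.0)


class TestDarcyFlow:
    def test_uniform_pressure_no_flow(self, tiny_mesh):
        mats = {ECM: MaterialProps(E=1e6, nu=0.3, k0=1e-20, e0=1.0)}
        state = _state(tiny_mesh, p=np.full(tiny_mesh.n_nodes, 123.0))
        q, v = darcy_flux_and_velocity(tiny_mesh, state, mats)
        assert np.max(np.abs(q)) < 1e-12 and np.max(np.abs(v)) < 1e-12

    def test_linear_pressure_closed_form(self, tiny_mesh):
        # p drops by dP over the length L along y: q_y = (k/mu) dP / L
        mats = {ECM: MaterialProps(E=1e6, nu=0.3, k0=1e-20, e0=1.0)}
        dP, L = 500.0, 3.0
        k_um2, mu = 2e-8, 1e-3
        p = dP * (1.0 - tiny_mesh.nodes[:, 1] / L)
        state = _state(tiny_mesh, p=p, e=1.0, k_um2=k_um2)
        q, v = darcy_flux_and_velocity(tiny_mesh, state, mats)
        np.testing.assert_allclose(q[:, 1], (k_um2 / mu) * dP / L, rtol=1e-9)
        np.testing.assert_allclose(q[:, 0], 0.0, atol=1e-12)
        # nf = e/(1+e) = 0.5 here, so v = 2 q
        np.testing.assert_allclose(v, 2.0 * q, rtol=1e-12)

    def test_velocity_inverse_in_porosity_and_flux_in_viscosity(self, tiny_mesh):
        p = 100.0 * tiny_mesh.nodes[:, 0]
        mats1 = {ECM: MaterialProps(E=1e6, nu=0.3, k0=1e-20, e0=1.0, mu_f=1e-3)}
        mats2 = {ECM: MaterialProps(E=1e6, nu=0.3, k0=1e-20, e0=1.0, mu_f=2e-3)}
        s_half = _state(tiny_mesh, p=p, e=1.0)        # nf = 1/2
        s_third = _state(tiny_mesh, p=p, e=0.5)       # nf = 1/3
        q1, v1 = darcy_flux_and_velocity(tiny_mesh, s_half, mats1)
        q2, v2 = darcy_flux_and_velocity(tiny_mesh, s_third, mats1)
        np.testing.assert_allclose(q1, q2, rtol=1e-12)        # same mobility
        np.testing.assert_allclose(v2, 1.5 * v1, rtol=1e-12)  # nf halves+
        q3, _ = darcy_flux_and_velocity(tiny_mesh, s_half, mats2)
        np.testing.assert_allclose(q3, 0.5 * q1, rtol=1e-12)  # double mu_f


class TestProbeSeries:
    def test_linear_field_interpolated_exactly(self, tiny_mesh):
        mats = {ECM: MaterialProps(E=1e6, nu=0.3, k0=1e-20, e0=1.0)}
        p = 7.0 + 3.0 * tiny_mesh.nodes[:, 1]
        series = StateSeries(mesh=tiny_mesh, materials=mats)
        series.states = [_state(tiny_mesh, p=p, t=t) for t in (0.0, 1.0)]
        pt = {"Q": np.array([0.9, 1.7, 0.4])}
        df = extract_probe_series(series, pt)
        got = df[(df.quantity == "pressure_kPa") & (df.time == 1.0)].value.iloc[0]
        assert got == pytest.approx((7.0 + 3.0 * 1.7) / 1e3, rel=1e-9)
        assert sorted(df.time.unique()) == [0.0, 1.0]

    def test_point_outside_mesh_rejected(self, tiny_mesh):
        mats = {ECM: MaterialProps(E=1e6, nu=0.3, k0=1e-20, e0=1.0)}
        series = StateSeries(mesh=tiny_mesh, materials=mats)
        series.states = [_state(tiny_mesh)]
        with pytest.raises(ValueError, match="outside"):
            extract_probe_series(series, {"X": np.array([5.0, 5.0, 5.0])})


class TestSummarize:
    def _random_series(self, mesh, n_states=3, seed=11):
        rng = np.random.default_rng(seed)
        mats = {ECM: MaterialProps(E=1e6, nu=0.3, k0=1e-20, e0=1.0)}
        series = StateSeries(mesh=mesh, materials=mats)
        for i in range(n_states):
            series.states.append(
                _state(
                    mesh,
                    u=rng.normal(scale=1e-3, size=(mesh.n_nodes, 3)),
                    p=rng.normal(scale=1e3, size=mesh.n_nodes),
                    t=float(i),
                )
            )
        return series

    def test_maxima_match_exhaustive_scan(self, tiny_mesh):
        series = self._random_series(tiny_mesh)
        lc = LoadCase(global_strain=1e-3)
        summary = summarize(series, lc)
        brute_p = max(float(s.p.max()) for s in series)
        assert summary.max_pore_pressure_kPa == pytest.approx(brute_p / 1e3)
        brute_v = 0.0
        for s in series:
            _, v = darcy_flux_and_velocity(tiny_mesh, s, series.materials)
            brute_v = max(brute_v, float(np.linalg.norm(v, axis=1).max()))
        assert summary.max_seepage_velocity_um_s == pytest.approx(brute_v)
        brute_eps = float(nodal_strain_magnitude(tiny_mesh, series[-1].u).max())
        assert summary.max_principal_strain_ustrain == pytest.approx(brute_eps)
        # the reported (location, time) pairs exist in the series
        assert summary.max_pore_pressure_time in [s.t for s in series]

    def test_zero_load_flagged(self, tiny_mesh):
        mats = {ECM: MaterialProps(E=1e6, nu=0.3, k0=1e-20, e0=1.0)}
        series = StateSeries(mesh=tiny_mesh, materials=mats)
        series.states = [_state(tiny_mesh, t=0.0), _state(tiny_mesh, t=1.0)]
        lc = LoadCase(global_strain=0.0)
        summary = summarize(series, lc)
        assert summary.zero_load
        assert summary.amplification_factor is None
        assert summary.max_principal_strain_ustrain == 0.0
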