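"""Pointwise poroelastic relations: porosity, permeability, stress."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olcsfem import constitutive as con


class TestPorosityVoidRatio:
    @pytest.mark.parametrize(
        "e, nf",
        [
            (0.0, 0.0),                      # no voids
            (0.053, 0.053 / 1.053),          # mineralized matrix reference
            (4.0, 0.8),
            (4.88, 4.88 / 5.88),
        ],
    )
    def test_values(self, e, nf):
        assert con.porosity_from_void_ratio(e) == pytest.approx(nf, rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(con.DomainError):
            con.porosity_from_void_ratio(-1.0)
        with pytest.raises(con.DomainError):
            con.void_ratio_from_porosity(1.0)

    @given(st.floats(min_value=-0.99, max_value=50.0))
    @settings(deadline=None)
    def test_round_trip(self, e):
        nf = con.porosity_from_void_ratio(e)
        assert con.void_ratio_from_porosity(nf) == pytest.approx(e, rel=1e-10, abs=1e-12)


class TestVoidRatioFromStrain:
    @pytest.mark.parametrize(
        "e0, eps_v, expected",
        [
            (0.5, 0.0, 0.5),                 # reference state
            (0.053, -0.001, 0.051947),
            (4.0, 0.01, 4.05),
        ],
    )
    def test_values(self, e0, eps_v, expected):
        assert con.void_ratio_from_volumetric_strain(e0, eps_v) == pytest.approx(
            expected, rel=1e-12
        )

    def test_pore_collapse_identifies_element(self):
        with pytest.raises(con.PoreCollapseError, match="element id: 7"):
            con.void_ratio_from_volumetric_strain(
                np.full(9, 0.05), np.r_[np.zeros(7), -0.5, 0.0],
                where=np.arange(9),
            )


class TestPermeabilityLaw:
    def test_reference_identity_exact(self):
        # k(e0) == k0 with no roundoff for representative constants
        for e0, k0, M in [(0.053, 1e-20, 4.638), (4.0, 4e-20, 0.0), (4.88, 6e-20, 2.0)]:
            assert con.permeability_update(e0, e0, k0, M) == k0

    def test_hand_computed_ratio(self):
        # M = 0, e0 = 1, e = 3: squared factor (3*2/(1*4))^2 = 2.25
        assert con.permeability_update(3.0, 1.0, 1.0, 0.0) == pytest.approx(2.25)

    @given(
        e0=st.floats(min_value=0.01, max_value=10.0),
        k0=st.floats(min_value=1e-22, max_value=1e-14),
        M=st.floats(min_value=0.0, max_value=10.0),
    )
    @settings(deadline=None)
    def test_identity_property(self, e0, k0, M):
        assert con.permeability_update(e0, e0, k0, M) == pytest.approx(k0, rel=1e-14)

    def test_monotone_in_void_ratio(self):
        # numerical-derivative oracle on a grid, M >= 0
        for M in (0.0, 4.638):
            e = np.linspace(0.02, 8.0, 200)
            k = con.permeability_update(e, 1.5, 1e-20, M)
            assert np.all(np.diff(k) > 0)

    def test_domain_errors(self):
        with pytest.raises(con.DomainError):
            con.permeability_update(-1.0, 1.0, 1e-20, 1.0)
        with pytest.raises(con.DomainError):
            con.permeability_update(1.0, 0.0, 1e-20, 1.0)


class TestStressDecomposition:
    def test_dry_case_total_equals_effective(self):
        eps = np.diag([1e-3, -2e-3, 0.5e-3])
        se, stt = con.effective_and_total_stress(eps, 0.0, 11e9, 0.38)
        np.testing.assert_allclose(stt, se)

    def test_pure_pressure(self):
        se, stt = con.effective_and_total_stress(np.zeros((3, 3)), 500.0, 1e6, 0.3)
        np.testing.assert_allclose(se, 0.0)
        np.testing.assert_allclose(stt, -500.0 * np.eye(3))

    def test_uniaxial_strain_closed_form(self):
        # constrained-modulus closed form: sigma_yy = (lam + 2G) eps_yy,
        # sigma_xx = sigma_zz = lam * eps_yy
        E, nu, e_yy = 11e9, 0.38, -1e-3
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        G = E / (2 * (1 + nu))
        eps = np.diag([0.0, e_yy, 0.0])
        se, _ = con.effective_and_total_stress(eps, 0.0, E, nu)
        assert se[1, 1] == pytest.approx((lam + 2 * G) * e_yy, rel=1e-12)
        assert se[0, 0] == pytest.approx(lam * e_yy, rel=1e-12)
        assert se[2, 2] == pytest.approx(lam * e_yy, rel=1e-12)

    @given(p=st.floats(min_value=-1e6, max_value=1e6))
    @settings(deadline=None)
    def test_total_stress_affine_in_pressure(self, p):
        eps = np.diag([2e-4, -1e-3, 3e-4])
        se, st0 = con.effective_and_total_stress(eps, 0.0, 1e9, 0.3)
        _, stp = con.effective_and_total_stress(eps, p, 1e9, 0.3)
        np.testing.assert_allclose(stp, st0 - p * np.eye(3), rtol=1e-12, atol=1e-6)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(con.DomainError):
            con.effective_and_total_stress(np.zeros((3, 3)), 0.0, 1e6, 0.5)


class TestMaterialProps:
    def test_validation(self):
        with pytest.raises(con.DomainError):
            con.MaterialProps(E=-1.0, nu=0.3, k0=1e-20, e0=1.0)
        with pytest.raises(con.DomainError):
            con.MaterialProps(E=1.0, nu=0.6, k0=1e-20, e0=1.0)

    def test_default_table_regions(self):
        mats = con.default_materials()
        assert set(mats) == {con.ECM, con.PCM, con.CELL}
        assert mats[con.ECM].E == pytest.approx(11e9)
        assert mats[con.CELL].nf0 == pytest.approx(4.88 / 5.88)
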