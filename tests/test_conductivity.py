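"""Conductivity formulas: F-correction, migration/advection/slip, hybrid vs PNP."""

import math

import numpy as np
import pytest

import porecond as pc
from porecond.errors import DegenerateInputError, InvalidParameterError
from conftest import pore_with_sigma_star


class TestFCorrection:
    def test_limits_and_closed_form_value(self):
        assert pc.F_correction(0.0) == 1.0
        assert pc.F_correction(2.0) == pytest.approx(2 - 2 * math.log(2), rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(InvalidParameterError):
            pc.F_correction(-0.1)

    def test_monotone_decreasing(self):
        x = np.logspace(-6, 3, 400)
        f = pc.F_correction(x)
        assert np.all(np.diff(f) < 0)
        assert np.all(f <= 1.0)

    def test_series_closed_form_continuity(self):
        below, above = 1e-3 * (1 - 1e-9), 1e-3 * (1 + 1e-9)
        assert abs(pc.F_correction(below) - pc.F_correction(above)) < 1e-9

    def test_large_sigma_star_asymptote(self):
        assert pc.F_correction(100.0) == pytest.approx(4 / 100.0, rel=0.25)

    @pytest.mark.parametrize("target", np.logspace(-3, 2, 11).tolist())
    def test_against_electroosmotic_quadrature(self, nacl, target):
        """Closed form equals the integral of e n(r) v(r) over the GCE profile."""
        pore = pore_with_sigma_star(nacl, target)
        sigma = abs(pore.surface_charge)
        f_quad = pc.kappa_ad_gce_quadrature(nacl, pore) / (
            sigma**2 / (2 * nacl.viscosity)
        )
        assert abs(pc.F_correction(target) - f_quad) / f_quad < 1e-6


class TestKappaParts:
    def test_em_neutral_equals_bulk(self, nacl):
        pore = pc.PoreModel.from_nm(5, 6)
        for c in [1e-4, 0.1, 2.0]:
            assert pc.kappa_em_hom(nacl, pore, c) == pytest.approx(
                pc.bulk_conductivity(nacl, c), rel=1e-12
            )

    def test_em_gce_plateau(self, nacl, reference_pore):
        # c_s -> 0: 2 |sigma| mu+ / R = 0.208 S/m for 0.01 C/m^2, R = 5 nm
        plateau = pc.kappa_em_hom(nacl, reference_pore, 1e-9)
        assert plateau == pytest.approx(0.208, rel=1e-2)

    def test_ad_gce_zero_charge(self, nacl):
        assert pc.kappa_ad_gce(nacl, pc.PoreModel.from_nm(5, 6)) == 0.0

    def test_ad_gce_hand_value(self, nacl, reference_pore):
        # sigma^2/(2 eta) F(1.40) with the quadrature-checked F
        assert pc.kappa_ad_gce(nacl, reference_pore) == pytest.approx(0.0386, rel=1e-2)

    def test_ad_gce_large_charge_asymptote(self, nacl):
        pore = pore_with_sigma_star(nacl, 500.0)
        limit = pc.kappa_gce_limit(nacl, pore)
        migration = 2 * abs(pore.surface_charge) / pore.radius * pc.mobility(
            nacl.cation, nacl.temperature
        )
        assert pc.kappa_ad_gce(nacl, pore) == pytest.approx(
            limit - migration, rel=0.025
        )

    def test_slip_term(self, nacl):
        pore = pc.PoreModel.from_nm(5, 6, surface_charge=-0.01, slip_length_nm=30)
        assert pc.kappa_slip(nacl, pore) == pytest.approx(1.34, rel=1e-2)
        no_slip = pc.PoreModel.from_nm(5, 6, surface_charge=-0.01)
        assert pc.kappa_slip(nacl, no_slip) == 0.0

    def test_slip_to_homogeneous_advection_ratio(self, nacl):
        """kappa_slip / (sigma^2/2eta) = 4 b / R, independent of sigma."""
        for b_nm, r_nm in [(30, 5), (10, 2), (100, 20)]:
            pore = pc.PoreModel.from_nm(
                r_nm, 6, surface_charge=-0.003, slip_length_nm=b_nm
            )
            k_ad_hom = pore.surface_charge**2 / (2 * nacl.viscosity)
            assert pc.kappa_slip(nacl, pore) / k_ad_hom == pytest.approx(
                4 * b_nm / r_nm, rel=1e-12
            )


class TestHybrid:
    def test_neutral_pore_is_bulk(self, nacl):
        pore = pc.PoreModel.from_nm(5, 6)
        for c in [1e-4, 0.01, 1.0]:
            br = pc.kappa_hybrid(nacl, pore, c)
            assert br.kappa_total == pytest.approx(
                pc.bulk_conductivity(nacl, c), rel=1e-12
            )
            assert br.kappa_ad == br.kappa_slip == 0.0

    def test_breakdown_sums_and_signs(self, nacl):
        pore = pc.PoreModel.from_nm(4, 6, surface_charge=-0.015, slip_length_nm=30)
        br = pc.kappa_hybrid(nacl, pore, 0.01)
        assert br.kappa_total == pytest.approx(
            br.kappa_em + br.kappa_ad + br.kappa_slip
        )
        assert min(br.kappa_em, br.kappa_ad, br.kappa_slip) >= 0

    def test_low_salt_plateau(self, nacl, reference_pore):
        g = [
            pc.conductance(pc.kappa_hybrid(nacl, reference_pore, c).kappa_total,
                           reference_pore)
            for c in (1e-6, 1e-5)
        ]
        assert abs(g[1] - g[0]) / g[0] < 0.02  # flat over a decade

    def test_plateau_conductance_is_a_few_picosiemens(self, nacl, reference_pore):
        br = pc.kappa_hybrid(nacl, reference_pore, 1e-6)
        g = pc.conductance(br.kappa_total, reference_pore)
        assert 1e-12 < g < 1e-11

    def test_monotone_and_converges_to_bulk(self, nacl, reference_pore):
        c = np.logspace(-6, 0.7, 40)
        g = np.array(
            [pc.conductance(pc.kappa_hybrid(nacl, reference_pore, ci).kappa_total,
                            reference_pore) for ci in c]
        )
        assert np.all(np.diff(g) > 0)
        g_bulk = reference_pore.area / reference_pore.length * np.asarray(
            pc.bulk_conductivity(nacl, c)
        )
        # surface conduction dominates at low salt ...
        assert np.all(g[c < 0.01] > g_bulk[c < 0.01])
        # ... and the relative excess vanishes toward the bulk-like branch
        assert abs(g[-1] / g_bulk[-1] - 1) < 1e-3


class TestNumericOracle:
    def test_neutral_pore(self, nacl):
        br = pc.kappa_numeric_oracle(nacl, pc.PoreModel.from_nm(5, 6), 0.1)
        assert br.kappa_ad == 0.0
        assert br.kappa_total == pytest.approx(pc.bulk_conductivity(nacl, 0.1), rel=1e-9)

    @pytest.mark.parametrize("c_s", [1e-4, 1e-2, 1.0])
    def test_hybrid_agrees_in_homogeneous_regime(self, nacl, c_s):
        pore = pore_with_sigma_star(nacl, 0.4)
        orc = pc.kappa_numeric_oracle(nacl, pore, c_s)
        hyb = pc.kappa_hybrid(nacl, pore, c_s)
        assert hyb.kappa_total == pytest.approx(orc.kappa_total, rel=0.05)

    def test_advective_part_reaches_gce_value_at_low_salt(self, nacl):
        pore = pore_with_sigma_star(nacl, 2.0)
        orc = pc.kappa_numeric_oracle(nacl, pore, 1e-6)
        assert orc.kappa_ad == pytest.approx(pc.kappa_ad_gce(nacl, pore), rel=0.01)

    @pytest.mark.parametrize("c_s", [1e-4, 1e-2, 0.5])
    def test_slip_difference_is_exact_plug_term(self, nacl, c_s):
        """Adding slip shifts the oracle conductivity by exactly 2 sigma^2 b/(eta R)."""
        b = 30e-9
        base = pc.PoreModel.from_nm(5, 6, surface_charge=-0.01)
        slip = pc.PoreModel.from_nm(5, 6, surface_charge=-0.01, slip_length_nm=30)
        k0 = pc.kappa_numeric_oracle(nacl, base, c_s).kappa_total
        k1 = pc.kappa_numeric_oracle(nacl, slip, c_s).kappa_total
        expected = 2 * 0.01**2 * b / (nacl.viscosity * base.radius)
        assert abs((k1 - k0) - expected) / expected < 0.005


class TestConductance:
    def test_zero(self, reference_pore):
        assert pc.conductance(0.0, reference_pore) == 0.0

    def test_geometry_factor(self, nacl, reference_pore):
        assert pc.conductance(1.0, reference_pore) == pytest.approx(1.31e-11, rel=1e-2)

    def test_length_scaling(self, nacl):
        short = pc.PoreModel.from_nm(5, 3)
        long = pc.PoreModel.from_nm(5, 6)
        assert pc.conductance(1.0, short) == pytest.approx(
            2 * pc.conductance(1.0, long)
        )

    def test_negative_kappa_rejected(self, reference_pore):
        with pytest.raises(InvalidParameterError):
            pc.conductance(-1.0, reference_pore)


class TestGeometryBookkeeping:
    def test_no_deposition(self):
        assert pc.pore_geometry_diameter(10.0, 0, 0) == 10.0

    @pytest.mark.parametrize(
        "d0, nb, nz, expected",
        [(39.6, 5, 11, 10.4), (90.8, 17, 0, 6.48)],
    )
    def test_deposition_arithmetic(self, d0, nb, nz, expected):
        assert pc.pore_geometry_diameter(d0, nb, nz) == pytest.approx(expected)

    def test_closed_pore_rejected(self):
        with pytest.raises(DegenerateInputError):
            pc.pore_geometry_diameter(4.0, 1, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            pc.pore_geometry_diameter(10.0, -1, 0)
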