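"""Cylindrical Poisson-Boltzmann electrostatics: Donnan, GCE, numeric solver."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

import porecond as pc
from porecond.constants import ELEMENTARY_CHARGE, number_density
from porecond.errors import DegenerateInputError, InvalidParameterError
from conftest import pore_with_sigma_star


class TestPoreModel:
    def test_validation(self):
        with pytest.raises(InvalidParameterError):
            pc.PoreModel(radius=0.0, length=1e-6)
        with pytest.raises(InvalidParameterError):
            pc.PoreModel(radius=1e-9, length=1e-6, slip_length=-1e-9)

    def test_short_pore_warns(self):
        with pytest.warns(pc.pb_cylinder.AspectRatioWarning):
            pc.PoreModel(radius=1e-9, length=50e-9)


class TestSigmaStar:
    def test_zero_charge(self, nacl):
        assert pc.sigma_star(pc.PoreModel.from_nm(5, 6), nacl) == 0.0

    def test_hand_value(self, nacl, reference_pore):
        # 2 pi l_B R |sigma| / e with l_B = 0.716 nm, R = 5 nm, 0.01 C/m^2
        assert pc.sigma_star(reference_pore, nacl) == pytest.approx(1.40, rel=1e-2)


class TestDonnan:
    def test_neutral_pore(self, nacl):
        st8 = pc.donnan_partition(pc.PoreModel.from_nm(5, 6), nacl, 0.1)
        assert st8.k_plus_bar == st8.k_minus_bar == 1.0
        assert st8.phi_donnan == 0.0

    def test_hand_values(self, nacl, reference_pore):
        st8 = pc.donnan_partition(reference_pore, nacl, 0.1)
        assert st8.k_plus_bar == pytest.approx(1.229, rel=2e-3)
        assert st8.k_minus_bar == pytest.approx(0.814, rel=2e-3)

    @given(
        st.floats(1e-4, 0.5),
        st.floats(0.5, 25.0),
        st.floats(1e-5, 5.0),
    )
    def test_electroneutrality_and_product_identities(self, nacl, sigma, r_nm, c):
        pore = pc.PoreModel.from_nm(r_nm, 6.0, surface_charge=-sigma)
        d = pc.donnan_partition(pore, nacl, c)
        n_s = number_density(c)
        lhs = ELEMENTARY_CHARGE * n_s * (d.k_plus_bar - d.k_minus_bar) * pore.radius / 2
        assert lhs == pytest.approx(sigma, rel=1e-10)
        assert d.k_plus_bar * d.k_minus_bar == pytest.approx(1.0, rel=1e-12)

    def test_positive_charge_swaps_roles(self, nacl):
        neg = pc.donnan_partition(
            pc.PoreModel.from_nm(5, 6, surface_charge=-0.01), nacl, 0.1
        )
        pos = pc.donnan_partition(
            pc.PoreModel.from_nm(5, 6, surface_charge=+0.01), nacl, 0.1
        )
        assert pos.k_plus_bar == pytest.approx(neg.k_minus_bar)
        assert pos.phi_donnan == pytest.approx(-neg.phi_donnan)

    def test_invalid_concentration(self, nacl, reference_pore):
        with pytest.raises(InvalidParameterError):
            pc.donnan_partition(reference_pore, nacl, 0.0)


class TestGCEProfile:
    def test_neutral_pore_is_degenerate(self, nacl):
        with pytest.raises(DegenerateInputError):
            pc.gce_profile(pc.PoreModel.from_nm(5, 6), nacl)

    def test_wall_potential_at_sigma_star_two(self, nacl):
        pore = pore_with_sigma_star(nacl, 2.0)
        prof = pc.gce_profile(pore, nacl)
        assert prof.t == pytest.approx(0.5)
        assert prof.phi[-1] == pytest.approx(2 * math.log(0.5), rel=1e-12)

    @pytest.mark.parametrize("target", [0.05, 0.5, 2.0, 20.0, 100.0])
    def test_satisfies_pb_equation(self, nacl, target):
        """Discrete-Laplacian residual of the GCE solution is ~0."""
        pore = pore_with_sigma_star(nacl, target)
        prof = pc.gce_profile(pore, nacl, n_grid=4001)
        lb = pc.bjerrum_length(nacl)
        r, phi = prof.r, prof.phi
        h = r[1] - r[0]
        lap = (phi[2:] - 2 * phi[1:-1] + phi[:-2]) / h**2 + (
            phi[2:] - phi[:-2]
        ) / (2 * r[1:-1] * h)
        rhs = -4 * math.pi * lb * prof.n[1:-1]
        scale = np.abs(rhs).max()
        # away from the wall (stencil error grows with the quartic profile)
        interior = slice(0, int(0.9 * len(lap)))
        assert np.max(np.abs(lap - rhs)[interior]) / scale < 1e-5

    @pytest.mark.parametrize("target", [0.1, 1.0, 10.0])
    def test_global_electroneutrality_exact(self, nacl, target):
        pore = pore_with_sigma_star(nacl, target)
        prof = pc.gce_profile(pore, nacl)
        val, _ = quad(lambda r: prof.n_fn(r) * r, 0, pore.radius, epsrel=1e-13)
        line_charge = ELEMENTARY_CHARGE * 2 * math.pi * val
        expected = 2 * math.pi * pore.radius * abs(pore.surface_charge)
        assert line_charge == pytest.approx(expected, rel=1e-10)

    def test_gauss_boundary_condition(self, nacl):
        pore = pore_with_sigma_star(nacl, 3.0)
        prof = pc.gce_profile(pore, nacl)
        lb = pc.bjerrum_length(nacl)
        eps = 1e-7 * pore.radius
        slope = (prof.phi_fn(pore.radius) - prof.phi_fn(pore.radius - eps)) / eps
        expected = 4 * math.pi * lb * pore.surface_charge / ELEMENTARY_CHARGE
        assert slope == pytest.approx(expected, rel=1e-5)


class TestNumericPB:
    def test_neutral_pore_trivial(self, nacl):
        sol = pc.solve_pb_numeric(pc.PoreModel.from_nm(5, 6), nacl, 0.1)
        assert np.all(sol.phi == 0.0)
        assert sol.k_plus_bar == sol.k_minus_bar == 1.0

    def test_pointwise_partition_product(self, nacl, reference_pore):
        sol = pc.solve_pb_numeric(reference_pore, nacl, 0.05)
        assert np.allclose(sol.k_plus * sol.k_minus, 1.0, rtol=1e-12)

    @pytest.mark.parametrize("c_s", [1e-4, 1e-2, 1.0])
    def test_homogeneous_limit_matches_donnan(self, nacl, c_s):
        pore = pore_with_sigma_star(nacl, 0.1)
        sol = pc.solve_pb_numeric(pore, nacl, c_s)
        don = pc.donnan_partition(pore, nacl, c_s)
        assert sol.k_plus_bar == pytest.approx(don.k_plus_bar, rel=1e-2)
        assert sol.k_minus_bar == pytest.approx(don.k_minus_bar, rel=1e-2)

    def test_dilute_limit_matches_gce_shape(self, nacl):
        pore = pore_with_sigma_star(nacl, 2.0)
        sol = pc.solve_pb_numeric(pore, nacl, 1e-6)
        prof = pc.gce_profile(pore, nacl)
        shape_num = sol.phi - sol.phi[0]
        shape_gce = prof.phi_fn(sol.r) - prof.phi_fn(0.0)
        amplitude = np.abs(shape_gce).max()
        assert np.max(np.abs(shape_num - shape_gce)) / amplitude < 0.02

    @pytest.mark.parametrize("seed", range(5))
    def test_electroneutrality_invariant(self, nacl, seed):
        rng = np.random.default_rng(seed)
        sigma = 10 ** rng.uniform(-3, -1.3)
        r_nm = 10 ** rng.uniform(0, 1)
        c = 10 ** rng.uniform(-4, 0)
        pore = pc.PoreModel.from_nm(r_nm, 6.0, surface_charge=-sigma)
        sol = pc.solve_pb_numeric(pore, nacl, c)
        n_s = number_density(c)
        lhs = ELEMENTARY_CHARGE * n_s * (sol.k_plus_bar - sol.k_minus_bar)
        rhs = 2 * sigma / pore.radius
        assert abs(lhs - rhs) / rhs < 1e-5

    def test_monotonicity_in_surface_charge(self, nacl):
        kp, km = [], []
        for sigma in [0.001, 0.005, 0.02, 0.08]:
            pore = pc.PoreModel.from_nm(5, 6, surface_charge=-sigma)
            sol = pc.solve_pb_numeric(pore, nacl, 0.05)
            kp.append(sol.k_plus_bar)
            km.append(sol.k_minus_bar)
        assert np.all(np.diff(kp) > 0)
        assert np.all(np.diff(km) < 0)

    def test_grid_refinement_convergence(self, nacl, reference_pore):
        coarse = pc.solve_pb_numeric(reference_pore, nacl, 0.01, n_grid=2000)
        fine = pc.solve_pb_numeric(reference_pore, nacl, 0.01, n_grid=4000)
        assert abs(coarse.k_plus_bar - fine.k_plus_bar) / fine.k_plus_bar < 1e-5
        assert abs(coarse.k_minus_bar - fine.k_minus_bar) / fine.k_minus_bar < 1e-5

    def test_zero_concentration_disallowed(self, nacl, reference_pore):
        with pytest.raises(InvalidParameterError):
            pc.solve_pb_numeric(reference_pore, nacl, 0.0)
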