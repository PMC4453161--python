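"""Conductivity and conductance formulas for a charged cylindrical nanopore.

The in-pore conductivity splits into three non-negative parts:

* ``kappa_em`` -- electrical migration, driven by gradients in the
  electrostatic chemical potential; in the homogeneous (Donnan)
  approximation kappa_em = e n_s (mu+ k+_bar + mu- k-_bar).
* ``kappa_ad`` -- electro-osmotic advection of ions by the voltage-driven
  solvent flow (no-slip part); in the GCE regime it is exactly
  sigma^2/(2 eta) * F(sigma*) with
  F(x) = 4/x - (8/x^2) ln(1 + x/2), independent of salt concentration.
* ``kappa_slip`` -- extra plug-flow conduction from hydrodynamic slip,
  2 sigma^2 b / (eta R); exact within the PNP model because it depends
  only on global electroneutrality in the pore.

The hybrid formula (kappa_em_hom + kappa_ad_gce + kappa_slip) is exact in
both the homogeneous and full-GCE limits and an excellent approximation
in between; it is the forward model used to fit conductance-concentration
data. A full numeric PNP evaluation on top of :func:`~porecond.pb_cylinder.
solve_pb_numeric` serves as the independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .constants import (
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    VACUUM_PERMITTIVITY,
    number_density,
)
from .electrolyte import (
    Electrolyte,
    bjerrum_length,
    bulk_conductivity,
    mobility,
)
from .errors import DegenerateInputError, InvalidParameterError
from .pb_cylinder import (
    PoreModel,
    donnan_partition,
    gce_profile,
    sigma_star,
    solve_pb_numeric,
)

__all__ = [
    "ConductivityBreakdown",
    "F_correction",
    "kappa_em_hom",
    "kappa_ad_gce",
    "kappa_ad_gce_quadrature",
    "kappa_slip",
    "kappa_hybrid",
    "kappa_gce_limit",
    "kappa_numeric_oracle",
    "conductance",
    "pore_geometry_diameter",
    "MODEL_IDS",
]

MODEL_IDS = ("phenomenological", "homogeneous", "hybrid", "hybrid_slip")


@dataclass(frozen=True)
class ConductivityBreakdown:
    """Per-mechanism conductivities (S m^-1) at one salt concentration."""

    kappa_em: float
    kappa_ad: float
    kappa_slip: float
    model_id: str

    @property
    def kappa_total(self) -> float:
        return self.kappa_em + self.kappa_ad + self.kappa_slip


def F_correction(sigma_star_value):
    """Advective GCE correction F(sigma*) = 4/x - (8/x^2) ln(1 + x/2).

    Monotonically decreasing from F(0) = 1 to the asymptote 4/sigma*;
    corrects the homogeneous electro-osmotic term sigma^2/(2 eta) for the
    pile-up of counter-ions near a strongly charged wall. A Taylor series
    is used below 1e-3 to avoid cancellation.
    """
    x = np.asarray(sigma_star_value, dtype=float)
    if np.any(x < 0):
        raise InvalidParameterError("sigma* must be >= 0")
    small = x < 1e-3
    xs = np.where(small, x, 1.0)  # safe placeholder
    series = 1.0 - xs / 3.0 + xs**2 / 8.0 - xs**3 / 20.0 + xs**4 / 48.0
    xl = np.where(small, 1.0, x)
    closed = 4.0 / xl - 8.0 / xl**2 * np.log1p(xl / 2.0)
    out = np.where(small, series, closed)
    if np.ndim(sigma_star_value) == 0:
        return float(out)
    return out


def kappa_em_hom(electrolyte: Electrolyte, pore: PoreModel, c_s: float) -> float:
    """Electrical-migration conductivity in the homogeneous (Donnan) regime.

    kappa_em = e n_s (mu+ k+_bar + mu- k-_bar). Reduces to the bulk
    conductivity for sigma = 0 and to the GCE plateau 2|sigma| mu_counter / R
    as c_s -> 0.
    """
    state = donnan_partition(pore, electrolyte, c_s)
    n_s = number_density(c_s)
    mu_p = mobility(electrolyte.cation, electrolyte.temperature)
    mu_m = mobility(electrolyte.anion, electrolyte.temperature)
    return ELEMENTARY_CHARGE * n_s * (mu_p * state.k_plus_bar + mu_m * state.k_minus_bar)


def kappa_ad_gce(electrolyte: Electrolyte, pore: PoreModel) -> float:
    """Electro-osmotic (advective, no-slip) conductivity in the GCE regime.

    kappa_ad = sigma^2 / (2 eta) * F(sigma*); independent of c_s, it
    depends only on the surface charge density and pore radius.
    """
    sigma = pore.surface_charge
    if sigma == 0.0:
        return 0.0
    ss = sigma_star(pore, electrolyte)
    return sigma * sigma / (2.0 * electrolyte.viscosity) * F_correction(ss)


def kappa_ad_gce_quadrature(electrolyte: Electrolyte, pore: PoreModel) -> float:
    """Numerical-quadrature route to the GCE advective conductivity.

    Integrates the electro-osmotic current e n(r) v(r) over the exact GCE
    profile, with the Stokes velocity
    v(r) = (e E / (4 pi l_B eta)) (phi(r) - phi(R)) and no-slip at the
    wall. Serves as the independent oracle for the closed form
    sigma^2 F(sigma*) / (2 eta).
    """
    sigma = pore.surface_charge
    if sigma == 0.0:
        return 0.0
    prof = gce_profile(pore, electrolyte, n_grid=2)
    lb = prof.bjerrum
    radius = pore.radius
    phi_wall = float(prof.phi_fn(radius))

    def integrand(r):
        return prof.n_fn(r) * abs(prof.phi_fn(r) - phi_wall) * r

    val, _ = quad(integrand, 0.0, radius, epsabs=0.0, epsrel=1e-12, limit=200)
    e = ELEMENTARY_CHARGE
    return 2.0 * e * e / (4.0 * math.pi * lb * electrolyte.viscosity * radius**2) * val


def kappa_slip(electrolyte: Electrolyte, pore: PoreModel) -> float:
    """Slip contribution 2 sigma^2 b / (eta R) to the advective conductivity.

    Exact within the PNP model: the plug-flow velocity couples to the net
    in-pore charge, which is fixed by global electroneutrality.
    """
    sigma = pore.surface_charge
    return 2.0 * sigma * sigma * pore.slip_length / (
        electrolyte.viscosity * pore.radius
    )


def kappa_gce_limit(electrolyte: Electrolyte, pore: PoreModel) -> float:
    """High-|sigma| / large-R limiting conductivity (no slip).

    (2|sigma|/R) (mu_counter + e / (2 pi l_B eta)): the counter-ion
    migration plateau plus the asymptotic advective term; a widely used
    low-salt fitting formula (some authors replace the single counter-ion
    mobility by mu+ + mu-).
    """
    sigma = abs(pore.surface_charge)
    counter = electrolyte.cation if pore.counterion_sign() > 0 else electrolyte.anion
    mu_c = mobility(counter, electrolyte.temperature)
    lb = bjerrum_length(electrolyte)
    return (2.0 * sigma / pore.radius) * (
        mu_c + ELEMENTARY_CHARGE / (2.0 * math.pi * lb * electrolyte.viscosity)
    )


def kappa_hybrid(
    electrolyte: Electrolyte, pore: PoreModel, c_s: float
) -> ConductivityBreakdown:
    """Hybrid conductivity: Donnan migration + GCE advection + slip.

    Exact in the homogeneous limit (sigma* << 1) and in the full GCE
    regime, and an excellent interpolation in between; the parts are
    reported separately.
    """
    model = "hybrid_slip" if pore.slip_length > 0 else "hybrid"
    return ConductivityBreakdown(
        kappa_em=kappa_em_hom(electrolyte, pore, c_s),
        kappa_ad=kappa_ad_gce(electrolyte, pore),
        kappa_slip=kappa_slip(electrolyte, pore),
        model_id=model,
    )


def kappa_numeric_oracle(
    electrolyte: Electrolyte,
    pore: PoreModel,
    c_s: float,
    n_grid: int = 2000,
    tol: float = 1e-10,
) -> ConductivityBreakdown:
    """Full PNP conductivity evaluated on the numeric PB solution.

    kappa_em = e n_s (mu+ k+_bar + mu- k-_bar) with PB-averaged partition
    coefficients; kappa_ad = (eps0 eps_r k_B T n_s / eta) *
    <(k+(r) - k-(r)) (phi(r) - phi(R))> with <.> the area average (the
    electro-osmotic integral written directly in terms of the PB
    potential); the slip term is evaluated from the numeric solution's net
    ion content, 2 sigma_eff^2 b / (eta R) with
    sigma_eff = e n_s |k+_bar - k-_bar| R / 2, so it inherits the
    solution's electroneutrality rather than assuming it.
    """
    sol = solve_pb_numeric(pore, electrolyte, c_s, tol=tol, n_grid=n_grid)
    n_s = number_density(c_s)
    mu_p = mobility(electrolyte.cation, electrolyte.temperature)
    mu_m = mobility(electrolyte.anion, electrolyte.temperature)
    k_em = ELEMENTARY_CHARGE * n_s * (mu_p * sol.k_plus_bar + mu_m * sol.k_minus_bar)

    phi_wall = sol.phi[-1]
    integrand = (sol.k_plus - sol.k_minus) * (sol.phi - phi_wall) * sol.r
    avg = 2.0 / pore.radius**2 * np.trapezoid(integrand, sol.r)
    k_ad = (
        VACUUM_PERMITTIVITY
        * electrolyte.relative_permittivity
        * BOLTZMANN
        * electrolyte.temperature
        * n_s
        / electrolyte.viscosity
        * avg
    )

    sigma_eff = (
        ELEMENTARY_CHARGE
        * n_s
        * abs(sol.k_plus_bar - sol.k_minus_bar)
        * pore.radius
        / 2.0
    )
    k_sl = 2.0 * sigma_eff**2 * pore.slip_length / (
        electrolyte.viscosity * pore.radius
    )
    return ConductivityBreakdown(
        kappa_em=float(k_em),
        kappa_ad=float(k_ad),
        kappa_slip=float(k_sl),
        model_id="pnp_numeric",
    )


def conductance(kappa: float, pore: PoreModel, residual: float = 0.0) -> float:
    """Ohmic conductance G = pi R^2 kappa / L + G_r, in S.

    ``residual`` is the phenomenological, concentration-independent
    residual conductance G_r (used only by the phenomenological model).
    """
    if kappa < 0:
        raise InvalidParameterError("kappa must be >= 0")
    return pore.area * kappa / pore.length + residual


def pore_geometry_diameter(
    initial_diameter_nm: float,
    n_bilayers: int,
    n_zno_cycles: int,
    hmds_thickness_nm: float = 0.0,
) -> float:
    """Final pore diameter (nm) after atomic-layer deposition and grafting.

    Each Al2O3/ZnO bilayer deposits 2.48 nm and each extra ZnO cycle
    0.2 nm on the wall; an optional grafted-monolayer thickness (per side)
    can be supplied. D_final = D_init - 2 (2.48 n_bilayers +
    0.2 n_zno + t_graft).
    """
    if n_bilayers < 0 or n_zno_cycles < 0 or hmds_thickness_nm < 0:
        raise InvalidParameterError("deposition counts and thicknesses must be >= 0")
    final = initial_diameter_nm - 2.0 * (
        2.48 * n_bilayers + 0.2 * n_zno_cycles + hmds_thickness_nm
    )
    if final <= 0:
        raise DegenerateInputError(
            f"deposition closes the pore (final diameter {final:.2f} nm)"
        )
    return final
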