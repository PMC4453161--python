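"""Radial electrostatics inside a long cylindrical pore.

Three levels of description of the mean-field ion distribution between a
charged cylindrical wall (surface charge density sigma, taken negative by
convention so cations are the counter-ions) and a salt reservoir at bulk
molarity c_s:

* :func:`donnan_partition` -- the homogeneous (Donnan) approximation where
  the reduced potential is uniform and fixed by electroneutrality; valid
  for dimensionless surface charge sigma* <~ 1.
* :func:`gce_profile` -- the exact counter-ion-only Poisson-Boltzmann
  solution in the good co-ion exclusion (GCE) regime, reached when the
  reservoir is very dilute and all co-ions are expelled.
* :func:`solve_pb_numeric` -- a full numerical solution of the radial
  Poisson-Boltzmann equation at finite c_s, used as the independent
  oracle for the closed-form transport formulas.

All potentials are reduced (units of k_B T / e). The theory assumes a
high aspect ratio L >> R so that in-pore concentrations do not depend on
the axial coordinate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .constants import ELEMENTARY_CHARGE, number_density
from .electrolyte import Electrolyte, bjerrum_length, debye_length
from .errors import DegenerateInputError, InvalidParameterError, NumericalError

__all__ = [
    "PoreModel",
    "DonnanState",
    "GCEProfile",
    "PBSolution",
    "AspectRatioWarning",
    "sigma_star",
    "donnan_partition",
    "gce_profile",
    "solve_pb_numeric",
]


class AspectRatioWarning(UserWarning):
    """The pore is not long enough for the axial-invariance assumption."""


@dataclass(frozen=True)
class PoreModel:
    """Cylindrical pore geometry and surface properties (SI units).

    Parameters
    ----------
    radius : float
        Pore radius R in m.
    length : float
        Pore length L in m; the theory assumes L >> R (a warning is issued
        below L/R = 100).
    surface_charge : float
        Surface charge density sigma in C m^-2, sign carried (negative means
        cations are counter-ions). Fits report the magnitude.
    slip_length : float
        Hydrodynamic slip length b >= 0 in m.
    """

    radius: float
    length: float
    surface_charge: float = 0.0
    slip_length: float = 0.0

    def __post_init__(self):
        if not self.radius > 0:
            raise InvalidParameterError("radius must be > 0")
        if not self.length > 0:
            raise InvalidParameterError("length must be > 0")
        if not self.slip_length >= 0:
            raise InvalidParameterError("slip_length must be >= 0")
        if self.length / self.radius < 100:
            warnings.warn(
                f"aspect ratio L/R = {self.length / self.radius:.1f} < 100; the "
                "axially invariant theory may be inaccurate",
                AspectRatioWarning,
                stacklevel=2,
            )

    @classmethod
    def from_nm(
        cls,
        radius_nm: float,
        length_um: float,
        surface_charge: float = 0.0,
        slip_length_nm: float = 0.0,
    ) -> "PoreModel":
        """Convenience constructor with radius in nm and length in um."""
        return cls(
            radius=radius_nm * 1e-9,
            length=length_um * 1e-6,
            surface_charge=surface_charge,
            slip_length=slip_length_nm * 1e-9,
        )

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def area(self) -> float:
        return math.pi * self.radius**2

    def counterion_sign(self) -> int:
        """+1 if cations are the counter-ions (sigma <= 0), else -1."""
        return 1 if self.surface_charge <= 0 else -1


@dataclass(frozen=True)
class DonnanState:
    """Homogeneous (Donnan) partitioning state.

    ``phi_donnan`` is the uniform reduced potential (k_B T / e units);
    ``k_plus_bar`` / ``k_minus_bar`` are the mean partition coefficients
    of cations and anions. Exactly, k+ * k- = 1 and
    k+ - k- = 2|sigma|/(e R n_s) for sigma < 0 (electroneutrality).
    """

    phi_donnan: float
    k_plus_bar: float
    k_minus_bar: float


@dataclass(frozen=True)
class GCEProfile:
    """Counter-ion-only PB solution in the GCE regime.

    phi(r) = s_c * 2 ln(1 - alpha^2 r^2), with alpha^2 = t / R^2 and
    t = sigma*/(2 + sigma*) in [0, 1); the counter-ion density is
    n(r) = (2 alpha^2 / (pi l_B)) (1 - alpha^2 r^2)^-2. s_c = +1 for
    sigma < 0 (phi <= 0, cations inside), -1 for sigma > 0.
    """

    sigma_star: float
    t: float
    alpha_sq: float
    r: np.ndarray
    phi: np.ndarray
    n: np.ndarray
    radius: float
    bjerrum: float
    sign: int  # counter-ion valence sign

    def phi_fn(self, r) -> np.ndarray:
        """Reduced potential at arbitrary radii (signed)."""
        r = np.asarray(r, dtype=float)
        return self.sign * 2.0 * np.log1p(-self.alpha_sq * r * r)

    def n_fn(self, r) -> np.ndarray:
        """Counter-ion number density (m^-3) at arbitrary radii."""
        r = np.asarray(r, dtype=float)
        return (
            2.0
            * self.alpha_sq
            / (math.pi * self.bjerrum)
            * (1.0 - self.alpha_sq * r * r) ** -2
        )


@dataclass(frozen=True)
class PBSolution:
    """Converged numerical PB solution on a uniform radial grid.

    ``phi`` is the reduced potential; local partition coefficients are
    k+(r) = exp(-phi), k-(r) = exp(+phi) (so k+ k- = 1 pointwise); the
    mean coefficients are area averages (2/R^2) int k(r) r dr.
    """

    r: np.ndarray
    phi: np.ndarray
    k_plus: np.ndarray
    k_minus: np.ndarray
    k_plus_bar: float
    k_minus_bar: float
    iterations: int
    residual: float
    radius: float
    c_s: float


def sigma_star(pore: PoreModel, electrolyte: Electrolyte) -> float:
    """Dimensionless surface charge sigma* = 2 pi l_B R |sigma| / e.

    Ratio of the pore radius to the Gouy-Chapman length; controls the
    validity of the homogeneous approximation (good for sigma* <~ 1).
    """
    lb = bjerrum_length(electrolyte)
    return (
        2.0
        * math.pi
        * lb
        * pore.radius
        * abs(pore.surface_charge)
        / ELEMENTARY_CHARGE
    )


def donnan_partition(pore: PoreModel, electrolyte: Electrolyte, c_s: float) -> DonnanState:
    """Donnan partitioning of a 1:1 salt in the homogeneous approximation.

    With X = |sigma| / (e R n_s), electroneutrality inside the pore gives
    mean partition coefficients k_counter = sqrt(1 + X^2) + X and
    k_co = sqrt(1 + X^2) - X, and a Donnan potential
    phi_D = -sign asinh(X) where sign = +1 for sigma < 0.
    """
    if not c_s > 0:
        raise InvalidParameterError(f"c_s must be > 0 mol/l, got {c_s}")
    n_s = number_density(c_s)
    x = abs(pore.surface_charge) / (ELEMENTARY_CHARGE * pore.radius * n_s)
    k_counter = math.sqrt(1.0 + x * x) + x
    k_co = 1.0 / k_counter  # = sqrt(1+X^2) - X, without cancellation
    s = pore.counterion_sign()  # +1: cations are counter-ions
    phi_d = -s * math.asinh(x)
    if s > 0:
        k_plus, k_minus = k_counter, k_co
    else:
        k_plus, k_minus = k_co, k_counter
    return DonnanState(phi_donnan=phi_d, k_plus_bar=k_plus, k_minus_bar=k_minus)


def gce_profile(pore: PoreModel, electrolyte: Electrolyte, n_grid: int = 512) -> GCEProfile:
    """Exact counter-ion-only PB solution in the good co-ion exclusion regime.

    Solves (1/r)(r phi')' = -4 pi l_B n(r) with the Gauss condition
    phi'(R) = 4 pi l_B sigma / e and regularity at the axis. Global
    electroneutrality (2/R^2) int e n(r) r dr = 2|sigma|/R is built in.
    """
    if pore.surface_charge == 0:
        raise DegenerateInputError(
            "sigma = 0: no counter-ion-only solution exists (nothing to neutralize)"
        )
    lb = bjerrum_length(electrolyte)
    ss = sigma_star(pore, electrolyte)
    t = ss / (2.0 + ss)
    alpha_sq = t / pore.radius**2
    r = np.linspace(0.0, pore.radius, n_grid)
    sign = pore.counterion_sign()
    phi = sign * 2.0 * np.log1p(-alpha_sq * r * r)
    n = 2.0 * alpha_sq / (math.pi * lb) * (1.0 - alpha_sq * r * r) ** -2
    return GCEProfile(
        sigma_star=ss,
        t=t,
        alpha_sq=alpha_sq,
        r=r,
        phi=phi,
        n=n,
        radius=pore.radius,
        bjerrum=lb,
        sign=sign,
    )


def _newton_pb(
    radius: float,
    lam: float,
    slope_wall: float,
    phi0: np.ndarray,
    tol: float,
    max_iter: int,
    max_step: float = 2.0,
) -> tuple[np.ndarray, int, float]:
    """Damped Newton iteration for (1/r)(r phi')' = sinh(phi)/lam^2.

    Uniform grid, second-order stencils; r = 0 handled by the regularized
    Laplacian 4 (phi_1 - phi_0)/h^2; the wall Neumann condition enters via
    a ghost node. Returns (phi, iterations, last max update).
    """
    n = phi0.size - 1
    h = radius / n
    r = np.linspace(0.0, radius, n + 1)
    inv_lam2 = 1.0 / (lam * lam)
    phi = phi0.copy()

    # banded Jacobian structure (constant off-diagonals)
    upper = np.zeros(n + 1)
    lower = np.zeros(n + 1)
    upper[1] = 4.0 / h**2  # J[0,1]
    upper[2 : n + 1] = 1.0 / h**2 + 1.0 / (2.0 * r[1:n] * h)
    lower[0 : n - 1] = 1.0 / h**2 - 1.0 / (2.0 * r[1:n] * h)
    lower[n - 1] = 2.0 / h**2  # J[n, n-1]

    update = np.inf
    for it in range(1, max_iter + 1):
        sinh_phi = np.sinh(phi)
        cosh_phi = np.cosh(phi)
        res = np.empty(n + 1)
        res[0] = 4.0 * (phi[1] - phi[0]) / h**2 - sinh_phi[0] * inv_lam2
        lap = (phi[2:] - 2.0 * phi[1:-1] + phi[:-2]) / h**2 + (
            phi[2:] - phi[:-2]
        ) / (2.0 * r[1:-1] * h)
        res[1:n] = lap - sinh_phi[1:n] * inv_lam2
        res[n] = (
            2.0 * (phi[n - 1] - phi[n]) / h**2
            + 2.0 * slope_wall / h
            + slope_wall / radius
            - sinh_phi[n] * inv_lam2
        )

        diag = np.empty(n + 1)
        diag[0] = -4.0 / h**2 - cosh_phi[0] * inv_lam2
        diag[1:n] = -2.0 / h**2 - cosh_phi[1:n] * inv_lam2
        diag[n] = -2.0 / h**2 - cosh_phi[n] * inv_lam2

        ab = np.zeros((3, n + 1))
        ab[0] = upper
        ab[1] = diag
        ab[2] = lower
        delta = solve_banded((1, 1), ab, -res)

        update = float(np.max(np.abs(delta)))
        if update > max_step:  # damping: cap the Newton step
            delta *= max_step / update
        phi += delta
        if update < tol:
            return phi, it, update
    raise NumericalError(
        f"PB Newton iteration did not converge in {max_iter} iterations "
        f"(last max update {update:.3e})",
        residual=update,
        iterations=max_iter,
    )


def solve_pb_numeric(
    pore: PoreModel,
    electrolyte: Electrolyte,
    c_s: float,
    tol: float = 1e-10,
    n_grid: int = 2000,
    max_iter: int = 400,
) -> PBSolution:
    """Full numerical radial PB solution at bulk molarity ``c_s``.

    Solves (1/r)(r phi')' = -4 pi l_B n_s (e^-phi - e^phi) on [0, R] with
    phi'(0) = 0 and phi'(R) = 4 pi l_B sigma / e, by damped Newton
    relaxation on a uniform grid; iterates until the maximum potential
    update falls below ``tol``. Mean partition coefficients are trapezoidal
    area averages, so the discrete electroneutrality
    e n_s (k+_bar - k-_bar) = 2|sigma|/R holds to the discretization error
    (~1e-6 relative at the default grid).
    """
    if not c_s > 0:
        raise InvalidParameterError(
            "c_s must be > 0 for the numeric solver (the grand-canonical "
            "reference is the bulk); use gce_profile for the salt-free limit"
        )
    lb = bjerrum_length(electrolyte)
    lam = debye_length(electrolyte, c_s)
    sigma = pore.surface_charge
    r = np.linspace(0.0, pore.radius, n_grid + 1)
    if sigma == 0.0:
        phi = np.zeros_like(r)
        ones = np.ones_like(r)
        return PBSolution(r, phi, ones, ones.copy(), 1.0, 1.0, 0, 0.0, pore.radius, c_s)

    # solve for the |sigma|, cations-as-counter-ions case and mirror if needed
    slope_wall = -4.0 * math.pi * lb * abs(sigma) / ELEMENTARY_CHARGE
    n_s = number_density(c_s)
    x = abs(sigma) / (ELEMENTARY_CHARGE * pore.radius * n_s)
    phi0 = np.full(r.shape, -math.asinh(x))  # Donnan initial guess
    phi, iters, resid = _newton_pb(pore.radius, lam, slope_wall, phi0, tol, max_iter)
    if sigma > 0:
        phi = -phi
    k_plus = np.exp(-phi)
    k_minus = np.exp(phi)
    area = pore.radius**2 / 2.0
    k_plus_bar = float(np.trapezoid(k_plus * r, r) / area)
    k_minus_bar = float(np.trapezoid(k_minus * r, r) / area)
    return PBSolution(
        r=r,
        phi=phi,
        k_plus=k_plus,
        k_minus=k_minus,
        k_plus_bar=k_plus_bar,
        k_minus_bar=k_minus_bar,
        iterations=iters,
        residual=resid,
        radius=pore.radius,
        c_s=c_s,
    )
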