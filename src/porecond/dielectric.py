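"""Dielectric exclusion of ions from a pore in a low-permittivity membrane.

An ion inside a water-filled pore surrounded by a membrane with
epsilon_m << epsilon_w pays a self-energy penalty DeltaW(r): its Born
screening cloud is truncated (the pore interior is screened with inverse
length kappa_v <= kappa_b) and its image charges in the membrane are
repulsive. Within the variational (one-loop) treatment the mean-field
partition coefficients acquire a factor Gamma in (0, 1],

    Gamma = (2/R^2) int_0^R exp(-DeltaW(r; kappa_v)) r dr,
    kappa_v^2 = Gamma kappa_b^2,

solved as a damped fixed point. DeltaW is

    DeltaW(r) = (l_B/2) [ (kappa_b - kappa_v) + dG(r, r; kappa_v) ],

where dG is the correction to the Debye-Hueckel Green function from the
pore geometry: a sum over angular modes m >= 0 and an axial-wavenumber
quadrature, with coefficients fixed by matching the potential and the
normal displacement field at r = R between the screened interior
(epsilon_w, kappa_v) and the unscreened membrane (epsilon_m, kappa = 0).
Each mode contributes proportionally to I_m^2(sqrt(kappa_v^2 + k^2) r).

Gamma does not depend on the surface charge; it increases with c_s and R
and decreases with the dielectric jump. The module is interpretive: it is
not part of the default fitting pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammaln, ive, kve
from numpy.polynomial.legendre import leggauss

from .constants import ELEMENTARY_CHARGE, number_density
from .electrolyte import (
    Electrolyte,
    bjerrum_length,
    bulk_conductivity,
    debye_length,
    mobility,
)
from .errors import InvalidParameterError, NumericalError
from .pb_cylinder import PoreModel

__all__ = [
    "DielectricConfig",
    "GammaResult",
    "delta_w",
    "gamma_selfconsistent",
    "kappa_em_dielectric",
]


@dataclass(frozen=True)
class DielectricConfig:
    """Numerical configuration of the dielectric self-energy calculation.

    ``eps_membrane`` defaults to 3.0 (typical of polymer/oxide membranes);
    ``max_modes`` is the angular-mode cutoff (with geometric tail
    extrapolation beyond it); ``n_k`` the Gauss-Legendre order of the
    wavenumber quadrature; ``n_r`` the radial Gauss-Legendre order of the
    Gamma integral; ``deltaw_cap`` the self-energy (k_B T) above which the
    Boltzmann factor is treated as zero; ``tail_tol`` the admissible
    relative mode-sum tail at radii where the self-energy is below
    ``tail_relevance_kt`` (i.e. where the Boltzmann factor still matters)
    (a gross-failure guard: the image self-energy diverges at the wall,
    so wall-adjacent values carry cutoff uncertainty by design, while the
    Gamma integral is converged to ~1e-3 at these defaults).
    """

    eps_membrane: float = 3.0
    max_modes: int = 30
    n_k: int = 160
    n_r: int = 32
    deltaw_cap: float = 40.0
    tail_relevance_kt: float = 6.0
    tail_tol: float = 2.0

    def __post_init__(self):
        if not self.eps_membrane > 0:
            raise InvalidParameterError("eps_membrane must be > 0")


@dataclass(frozen=True)
class GammaResult:
    """Self-consistent dielectric-exclusion factor and its ingredients."""

    gamma: float
    kappa_v: float  # in-pore inverse screening length, m^-1
    kappa_b: float  # bulk inverse screening length, m^-1
    r_grid: np.ndarray
    delta_w_profile: np.ndarray  # k_B T
    converged: bool
    iterations: int


def _log_iv(m: int, x: np.ndarray) -> np.ndarray:
    """log I_m(x), stable down to the x << m regime where ive underflows."""
    with np.errstate(divide="ignore"):
        scaled = ive(m, x)
        direct = np.log(scaled) + x
        series = m * np.log(x / 2.0) - gammaln(m + 1)  # leading small-x term
    return np.where(scaled > 0, direct, series)


def _log_kv(m: int, x: np.ndarray) -> np.ndarray:
    """log K_m(x), stable down to the x << m regime where kve overflows."""
    with np.errstate(over="ignore"):
        scaled = kve(m, x)
    direct = np.where(np.isfinite(scaled), np.log(scaled) - x, np.inf)
    if m == 0:
        return direct
    series = gammaln(m) - math.log(2.0) + m * np.log(2.0 / x)
    return np.where(np.isfinite(scaled), direct, series)


def _rho_k(m: int, x: np.ndarray) -> np.ndarray:
    """Logarithmic derivative K_m'(x)/K_m(x) = -K_{m+1}/K_m + m/x, stable."""
    with np.errstate(over="ignore", invalid="ignore"):
        num = kve(m + 1, x)
        den = kve(m, x)
        direct = -num / den + m / x
    ok = np.isfinite(num) & np.isfinite(den) & (den > 0)
    return np.where(ok, direct, -m / x)  # x << m: K'/K -> -m/x


def _rho_i(m: int, x: np.ndarray) -> np.ndarray:
    """Logarithmic derivative I_m'(x)/I_m(x) = I_{m+1}/I_m + m/x, stable."""
    with np.errstate(invalid="ignore", divide="ignore"):
        num = ive(m + 1, x)
        den = ive(m, x)
        direct = num / den + m / x
    ok = (den > 0) & np.isfinite(num)
    # x << m: I'/I -> m/x + x/(2(m+1))
    return np.where(ok, direct, m / x + x / (2.0 * (m + 1.0)))


def _delta_green_self(
    r: np.ndarray,
    radius: float,
    kappa_v: float,
    eps_w: float,
    eps_m: float,
    max_modes: int,
    n_k: int,
    tail_tol: float,
    cap_energy: Optional[float] = None,
    lb_half: Optional[float] = None,
) -> np.ndarray:
    """Pore correction dG(r, r) to the DH Green function, in m^-1.

    dG(r,r) = (2/pi) int_0^inf dk sum_m (2 - delta_m0) F_m(k) I_m^2(p r),
    p = sqrt(kappa_v^2 + k^2), with F_m from field matching at r = R
    against the unscreened membrane (radial decay q = k outside). The
    matching coefficient is evaluated as
    F_m I_m^2(p r) = (num*/den*) K_m(pR) I_m^2(pr) / I_m(pR) with
    num* = eps_w p K'/K|_pR - eps_m q K'/K|_qR and
    den* = eps_m q K'/K|_qR - eps_w p I'/I|_pR -- ratios and a log-domain
    Bessel combination, stable at large mode index and small argument.
    The mode sum is accelerated by a geometric tail estimate (the image
    interaction diverges logarithmically at the wall, so a fixed cutoff
    cannot converge pointwise at r = R). Raises NumericalError if the
    tail is both large and physically relevant (self-energy below
    ``cap_energy``).
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r < 0) or np.any(r > radius):
        raise InvalidParameterError("radii must lie in [0, R]")
    if kappa_v < 0:
        raise InvalidParameterError("kappa_v must be >= 0")

    # wavenumber quadrature: k = s u/(1-u), Gauss-Legendre on u in (0, 1)
    u, w = leggauss(n_k)
    u = 0.5 * (u + 1.0)
    w = 0.5 * w
    scale = kappa_v + 1.0 / radius
    k = scale * u / (1.0 - u)
    jac = scale / (1.0 - u) ** 2

    p = np.sqrt(kappa_v**2 + k**2)  # interior radial decay
    q = k  # membrane radial decay (unscreened)
    pr_wall = p * radius
    qr_wall = q * radius
    pr = np.outer(r, p)  # (nr, nk)

    total = np.zeros(r.size)
    prev_term = None
    ratio = np.zeros(r.size)

    for m in range(max_modes + 1):
        rho_kp = _rho_k(m, pr_wall)
        rho_kq = _rho_k(m, qr_wall)
        rho_ip = _rho_i(m, pr_wall)
        num = eps_w * p * rho_kp - eps_m * q * rho_kq
        den = eps_m * q * rho_kq - eps_w * p * rho_ip

        log_b = _log_kv(m, pr_wall) - _log_iv(m, pr_wall)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_i_pr2 = 2.0 * _log_iv(m, pr)
        kernel = np.exp(log_b[None, :] + log_i_pr2)  # K(pR) I^2(pr) / I(pR)

        weight = 2.0 if m > 0 else 1.0
        term = weight * (2.0 / math.pi) * (
            (num / den * jac * w)[None, :] * kernel
        ).sum(axis=1)
        total += term
        if prev_term is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(
                    np.abs(prev_term) > 0, np.abs(term) / np.abs(prev_term), 0.0
                )
        prev_term = term

    # geometric extrapolation of the neglected modes
    ratio = np.clip(ratio, 0.0, 0.9995)
    tail = np.abs(prev_term) * ratio / (1.0 - ratio)
    total_with_tail = total + np.sign(prev_term) * tail
    if cap_energy is not None and lb_half is not None:
        relevant = lb_half * total < cap_energy
        rel_tail = tail / np.maximum(np.abs(total_with_tail), 1e-300)
        bad = relevant & (rel_tail > tail_tol)
        if np.any(bad):
            raise NumericalError(
                "angular mode sum not converged at max_modes for radii where the "
                "Boltzmann factor is non-negligible",
                max_rel_tail=float(rel_tail[bad].max()),
                n_bad=int(bad.sum()),
            )
    return total_with_tail


def delta_w(
    r_grid,
    radius: float,
    kappa_v: float,
    kappa_b_screen: float,
    electrolyte: Electrolyte,
    config: Optional[DielectricConfig] = None,
) -> np.ndarray:
    """Ion self-energy difference DeltaW(r) between pore and bulk, in k_B T.

    DeltaW(r) = (l_B/2) [(kappa_b - kappa_v) + dG(r, r; kappa_v)]: the lost
    Born screening energy plus the repulsive image interaction with the
    low-permittivity membrane. Non-negative for eps_m <= eps_w and
    kappa_v <= kappa_b, and increasing toward the wall (diverging
    logarithmically at contact).
    """
    cfg = config if config is not None else DielectricConfig()
    if kappa_v < 0 or kappa_b_screen < 0:
        raise InvalidParameterError("inverse screening lengths must be >= 0")
    lb = bjerrum_length(electrolyte)
    eps_w = electrolyte.relative_permittivity
    if cfg.eps_membrane > eps_w:
        raise InvalidParameterError("eps_membrane must not exceed the water value")
    if cfg.eps_membrane == eps_w and kappa_v == 0.0 and kappa_b_screen == 0.0:
        return np.zeros(np.atleast_1d(np.asarray(r_grid, dtype=float)).size)
    dg = _delta_green_self(
        r_grid,
        radius,
        kappa_v,
        eps_w,
        cfg.eps_membrane,
        cfg.max_modes,
        cfg.n_k,
        cfg.tail_tol,
        cap_energy=cfg.tail_relevance_kt,
        lb_half=lb / 2.0,
    )
    return lb / 2.0 * ((kappa_b_screen - kappa_v) + dg)


def gamma_selfconsistent(
    electrolyte: Electrolyte,
    radius: float,
    c_s: float,
    config: Optional[DielectricConfig] = None,
    tol: float = 1e-10,
    max_iter: int = 300,
    damping: float = 1.0,
) -> GammaResult:
    """Fixed point of Gamma = (2/R^2) int exp(-DeltaW(r; kappa_v)) r dr.

    kappa_v^2 = Gamma kappa_b^2 couples the in-pore screening to the
    exclusion it causes; (optionally damped) fixed-point iteration from
    Gamma_0 = 1 -- the map is monotone, so full steps converge without
    oscillation. The radial
    integral uses Gauss-Legendre nodes (interior to (0, R), where the
    wall-divergent self-energy is finite).
    """
    if not c_s > 0:
        raise InvalidParameterError("c_s must be > 0 mol/l")
    if not radius > 0:
        raise InvalidParameterError("radius must be > 0")
    cfg = config if config is not None else DielectricConfig()
    kappa_b = 1.0 / debye_length(electrolyte, c_s)

    x, w = leggauss(cfg.n_r)
    r_nodes = 0.5 * radius * (x + 1.0)
    r_weights = 0.5 * radius * w

    gamma = 1.0
    dw = np.zeros(cfg.n_r)
    trace = []
    for it in range(1, max_iter + 1):
        kappa_v = math.sqrt(gamma) * kappa_b
        dw = delta_w(r_nodes, radius, kappa_v, kappa_b, electrolyte, cfg)
        boltz = np.exp(-np.minimum(dw, cfg.deltaw_cap))
        gamma_new = 2.0 / radius**2 * float(np.sum(r_weights * boltz * r_nodes))
        gamma_new = min(max(gamma_new, 1e-12), 1.0)
        step = gamma_new - gamma
        trace.append(gamma_new)
        gamma = gamma + damping * step
        if abs(step) < tol:
            return GammaResult(
                gamma=gamma,
                kappa_v=math.sqrt(gamma) * kappa_b,
                kappa_b=kappa_b,
                r_grid=r_nodes,
                delta_w_profile=dw,
                converged=True,
                iterations=it,
            )
    raise NumericalError(
        f"Gamma fixed point not converged in {max_iter} iterations",
        trace=trace[-10:],
    )


def kappa_em_dielectric(
    electrolyte: Electrolyte,
    pore: PoreModel,
    c_s: float,
    gamma_result: GammaResult,
) -> float:
    """Electrical-migration conductivity with dielectric exclusion.

    Partition coefficients become k_bar+- = Gamma e^{-+phi_D} with the
    Donnan potential re-solved from electroneutrality,
    Gamma (e^{-phi_D} - e^{phi_D}) = 2|sigma|/(e R n_s), i.e.
    phi_D = -sign asinh(X / Gamma). Limits: sigma = 0 gives Gamma kappa_b
    (pure dielectric suppression); c_s -> 0 at fixed sigma < 0 gives the
    unchanged electroneutrality plateau 2|sigma| mu+ / R.
    """
    if not c_s > 0:
        raise InvalidParameterError("c_s must be > 0 mol/l")
    gamma = gamma_result.gamma
    if not 0 < gamma <= 1:
        raise InvalidParameterError("Gamma must lie in (0, 1]")
    n_s = number_density(c_s)
    x = abs(pore.surface_charge) / (ELEMENTARY_CHARGE * pore.radius * n_s)
    s = pore.counterion_sign()
    phi_d = -s * math.asinh(x / gamma)
    k_plus = gamma * math.exp(-phi_d)
    k_minus = gamma * math.exp(phi_d)
    mu_p = mobility(electrolyte.cation, electrolyte.temperature)
    mu_m = mobility(electrolyte.anion, electrolyte.temperature)
    return ELEMENTARY_CHARGE * n_s * (mu_p * k_plus + mu_m * k_minus)
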