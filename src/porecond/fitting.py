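"""Inference of pore radius and surface charge from conductance-salt curves.

Two fitting protocols mirror the two descriptions of the data:

* :func:`fit_phenomenological` -- G(c_s) = (pi R^2 / L) kappa_b(c_s) + G_r,
  free parameters (R, G_r): bulk-like conduction plus an unexplained
  residual plateau.
* :func:`fit_mesoscopic` -- G(c_s) = (pi R^2 / L) kappa_hybrid(c_s; R,
  sigma, b), free parameters (R, |sigma|) with the slip length b held fixed
  (b = 0 or a literature value such as 30 nm); the plateau is produced by
  surface-charge-governed counter-ion conduction and electro-osmosis.

Residuals are taken in log G: the data span several decades in both c_s
and G, and linear residuals would let the high-concentration branch
dominate the loss. Optimization is multi-start trust-region least squares
(log-parameterized, bounded); standard errors come from the Gauss-Newton
covariance at the optimum and are approximate.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .electrolyte import Electrolyte, bulk_conductivity, default_nacl
from .errors import InvalidParameterError, NumericalError
from .conductivity import (
    conductance,
    kappa_hybrid,
    sigma_star,
)
from .pb_cylinder import PoreModel

__all__ = [
    "ConductanceDataset",
    "FitResult",
    "fit_phenomenological",
    "fit_mesoscopic",
    "breakdown_report",
    "BOUNDS_RADIUS_M",
    "BOUNDS_SIGMA",
    "BOUNDS_RESIDUAL_S",
]

# parameter bounds (magnitudes), shared by both protocols
BOUNDS_RADIUS_M = (0.2e-9, 50e-9)
BOUNDS_SIGMA = (1e-4, 1.0)  # C m^-2
BOUNDS_RESIDUAL_S = (1e-14, 1e-9)


@dataclass
class ConductanceDataset:
    """A per-pore table of (salt molarity, conductance) points.

    Points are sorted by concentration on construction; concentrations
    must be positive and distinct and conductances positive. A mesoscopic
    fit additionally requires >= 4 points spanning >= 2 decades in c_s.
    """

    pore_label: str
    c_s: np.ndarray  # mol l^-1
    conductance: np.ndarray  # S
    length: float  # m

    def __post_init__(self):
        c = np.asarray(self.c_s, dtype=float)
        g = np.asarray(self.conductance, dtype=float)
        if c.shape != g.shape or c.ndim != 1:
            raise InvalidParameterError("c_s and conductance must be 1-D and matched")
        if np.any(c <= 0) or np.any(g <= 0):
            raise InvalidParameterError("concentrations and conductances must be > 0")
        order = np.argsort(c)
        c, g = c[order], g[order]
        if np.any(np.diff(c) <= 0):
            raise InvalidParameterError("duplicate concentrations in dataset")
        if not self.length > 0:
            raise InvalidParameterError("pore length must be > 0")
        self.c_s, self.conductance = c, g

    def __len__(self) -> int:
        return self.c_s.size

    @property
    def decades(self) -> float:
        return math.log10(self.c_s[-1] / self.c_s[0])

    def require_mesoscopic(self) -> None:
        if len(self) < 4 or self.decades < 2:
            raise InvalidParameterError(
                "mesoscopic fit requires >= 4 points spanning >= 2 decades in c_s"
            )


@dataclass
class FitResult:
    """Outcome of a conductance-curve fit.

    ``params``/``stderr`` map unit-suffixed names (``R_m``, ``sigma_C_per_m2``,
    ``b_m``, ``G_r_S``) to values; ``loss`` is the sum of squared log-G
    residuals actually minimized; ``predict`` evaluates the fitted forward
    model on arbitrary concentrations.
    """

    model_id: str
    params: Dict[str, float]
    stderr: Dict[str, float]
    residuals: np.ndarray
    loss: float
    n_points: int
    pore_label: str
    length: float
    apply_correction: bool = False
    derived: Dict[str, float] = field(default_factory=dict)
    _predict: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def predict(self, c_s) -> np.ndarray:
        if self._predict is None:
            raise NumericalError("fit carries no forward model")
        return self._predict(np.asarray(c_s, dtype=float))

    @property
    def diameter(self) -> float:
        return 2.0 * self.params["R_m"]

    def pore(self) -> PoreModel:
        """PoreModel at the fitted parameters (mesoscopic fits only)."""
        return PoreModel(
            radius=self.params["R_m"],
            length=self.length,
            surface_charge=-self.params.get("sigma_C_per_m2", 0.0),
            slip_length=self.params.get("b_m", 0.0),
        )

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "pore_label": self.pore_label,
            "L_m": self.length,
            "apply_correction": self.apply_correction,
            "params": self.params,
            "stderr": self.stderr,
            "loss": self.loss,
            "n_points": self.n_points,
            "derived": self.derived,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def summary(self) -> str:
        lines = [
            f"model: {self.model_id}   pore: {self.pore_label}   "
            f"n = {self.n_points}   loss = {self.loss:.4e}"
        ]
        for k, v in self.params.items():
            se = self.stderr.get(k, float("nan"))
            lines.append(f"  {k:>16s} = {v:.6e} +/- {se:.2e}")
        for k, v in self.derived.items():
            lines.append(f"  {k:>16s} = {v:.6e}")
        return "\n".join(lines)


def _multistart(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    heuristic_start: np.ndarray,
    log_bounds: Tuple[np.ndarray, np.ndarray],
    n_starts: int,
    seed: int,
):
    """Bounded least squares from a heuristic start plus log-uniform restarts."""
    rng = np.random.default_rng(seed)
    lo, hi = log_bounds
    starts = [np.clip(heuristic_start, lo + 1e-9, hi - 1e-9)]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(lo + rng.random(lo.size) * (hi - lo))
    best = None
    for x0 in starts:
        try:
            res = least_squares(residual_fn, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise NumericalError("all optimizer starts failed", n_starts=n_starts)
    return best


def _stderr_from_jac(res, params: np.ndarray) -> np.ndarray:
    """Approximate standard errors of the natural parameters.

    Gauss-Newton covariance of the log-parameters, s^2 (J^T J)^-1 with
    s^2 = 2 cost / (n - k), propagated to the natural scale by
    se(p) = p se(ln p).
    """
    n, k = res.fun.size, params.size
    if n <= k:
        return np.full(k, np.nan)
    s2 = 2.0 * res.cost / (n - k)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.pinv(jtj) * s2
    except np.linalg.LinAlgError:
        return np.full(k, np.nan)
    se_log = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    return params * se_log


def fit_phenomenological(
    dataset: ConductanceDataset,
    electrolyte: Optional[Electrolyte] = None,
    apply_correction: bool = False,
    n_starts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Fit G = (pi R^2 / L) kappa_b(c_s) [chi] + G_r over (R, G_r).

    The residual conductance G_r captures the low-salt plateau without
    attributing it to a mechanism. With ``apply_correction`` the bulk
    conductivity is multiplied by the electrolyte's chi(c_s) table.
    """
    elec = electrolyte if electrolyte is not None else default_nacl()
    if len(dataset) < 3:
        raise InvalidParameterError("need >= 3 points to fit (R, G_r)")
    c, g, length = dataset.c_s, dataset.conductance, dataset.length
    kb = np.asarray(bulk_conductivity(elec, c, apply_correction=apply_correction))
    log_g = np.log(g)

    def model(theta):
        r_m, g_r = np.exp(theta)
        return math.pi * r_m**2 / length * kb + g_r

    def residual_fn(theta):
        return np.log(model(theta)) - log_g

    # heuristic: R from the highest-concentration point (bulk-like), G_r from the lowest
    r_guess = math.sqrt(g[-1] * length / (math.pi * kb[-1]))
    lo = np.log([BOUNDS_RADIUS_M[0], BOUNDS_RESIDUAL_S[0]])
    hi = np.log([BOUNDS_RADIUS_M[1], BOUNDS_RESIDUAL_S[1]])
    x0 = np.log([r_guess, g[0]])
    res = _multistart(residual_fn, x0, (lo, hi), n_starts, seed)
    params = np.exp(res.x)
    se = _stderr_from_jac(res, params)
    r_fit, gr_fit = params

    def predict(cc):
        kbb = np.asarray(bulk_conductivity(elec, cc, apply_correction=apply_correction))
        return math.pi * r_fit**2 / length * kbb + gr_fit

    return FitResult(
        model_id="phenomenological",
        params={"R_m": float(r_fit), "G_r_S": float(gr_fit)},
        stderr={"R_m": float(se[0]), "G_r_S": float(se[1])},
        residuals=res.fun.copy(),
        loss=float(2.0 * res.cost),
        n_points=len(dataset),
        pore_label=dataset.pore_label,
        length=length,
        apply_correction=apply_correction,
        derived={"D_m": float(2 * r_fit)},
        _predict=predict,
    )


def fit_mesoscopic(
    dataset: ConductanceDataset,
    b_fixed: float = 0.0,
    electrolyte: Optional[Electrolyte] = None,
    n_starts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Fit G = (pi R^2 / L) kappa_hybrid(c_s; R, sigma, b) over (R, |sigma|).

    The slip length is held fixed (never fitted jointly with sigma: at the
    low-salt plateau the two are degenerate), the pore length at the
    experimental value, and mobilities/viscosity at their bulk values.
    """
    if b_fixed < 0:
        raise InvalidParameterError("b_fixed must be >= 0")
    dataset.require_mesoscopic()
    elec = electrolyte if electrolyte is not None else default_nacl()
    c, g, length = dataset.c_s, dataset.conductance, dataset.length
    kb = np.asarray(bulk_conductivity(elec, c))
    log_g = np.log(g)

    def g_model(r_m, sigma, cc):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # candidate pores may be short-aspect
            pore = PoreModel(r_m, length, -abs(sigma), b_fixed)
        out = np.empty(len(cc))
        for i, ci in enumerate(cc):
            out[i] = conductance(kappa_hybrid(elec, pore, ci).kappa_total, pore)
        return out

    def residual_fn(theta):
        r_m, sigma = np.exp(theta)
        return np.log(g_model(r_m, sigma, c)) - log_g

    r_guess = math.sqrt(g[-1] * length / (math.pi * kb[-1]))
    lo = np.log([BOUNDS_RADIUS_M[0], BOUNDS_SIGMA[0]])
    hi = np.log([BOUNDS_RADIUS_M[1], BOUNDS_SIGMA[1]])
    x0 = np.log([np.clip(r_guess, *BOUNDS_RADIUS_M), 1e-2])
    res = _multistart(residual_fn, x0, (lo, hi), n_starts, seed)
    params = np.exp(res.x)
    se = _stderr_from_jac(res, params)
    r_fit, sigma_fit = params

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pore_fit = PoreModel(r_fit, length, -sigma_fit, b_fixed)
    ss = sigma_star(pore_fit, elec)
    model_id = "hybrid_slip" if b_fixed > 0 else "hybrid"

    def predict(cc):
        return g_model(r_fit, sigma_fit, np.atleast_1d(cc))

    return FitResult(
        model_id=model_id,
        params={
            "R_m": float(r_fit),
            "sigma_C_per_m2": float(sigma_fit),
            "b_m": float(b_fixed),
        },
        stderr={
            "R_m": float(se[0]),
            "sigma_C_per_m2": float(se[1]),
            "b_m": 0.0,
        },
        residuals=res.fun.copy(),
        loss=float(2.0 * res.cost),
        n_points=len(dataset),
        pore_label=dataset.pore_label,
        length=length,
        derived={"D_m": float(2 * r_fit), "sigma_star": float(ss)},
        _predict=predict,
    )


def breakdown_report(
    fit: FitResult,
    c_grid: Sequence[float],
    electrolyte: Optional[Electrolyte] = None,
) -> pd.DataFrame:
    """Per-concentration conductivity fractions at the fitted parameters.

    Columns: the three kappa parts and total, their fractions of the
    total, the slip/migration ratio, and the predicted conductance.
    """
    if "sigma_C_per_m2" not in fit.params:
        raise InvalidParameterError("breakdown_report requires a mesoscopic fit")
    elec = electrolyte if electrolyte is not None else default_nacl()
    pore = fit.pore()
    rows = []
    for c in np.asarray(c_grid, dtype=float):
        br = kappa_hybrid(elec, pore, c)
        tot = br.kappa_total
        rows.append(
            {
                "c_mol_per_l": c,
                "kappa_em": br.kappa_em,
                "kappa_ad": br.kappa_ad,
                "kappa_slip": br.kappa_slip,
                "kappa_total": tot,
                "frac_em": br.kappa_em / tot if tot > 0 else np.nan,
                "frac_ad": br.kappa_ad / tot if tot > 0 else np.nan,
                "frac_slip": br.kappa_slip / tot if tot > 0 else np.nan,
                "slip_over_em": br.kappa_slip / br.kappa_em
                if br.kappa_em > 0
                else np.nan,
                "G_total": conductance(tot, pore),
            }
        )
    return pd.DataFrame(rows)
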