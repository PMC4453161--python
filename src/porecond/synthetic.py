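"""Synthetic data generators emulating the experimental pipeline.

Voltage-clamp I-V traces (Ohmic, with Gaussian noise and optional
two-state telegraph switching mimicking metastable wetting/dewetting
oscillations), slope-based conductance extraction, conductance-salt
datasets from any forward model in the family, and shell-structured
particle snapshots for the radial-profile machinery. All generators are
pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .electrolyte import Electrolyte, bulk_conductivity, default_nacl
from .errors import DegenerateInputError, InvalidParameterError
from .conductivity import conductance, kappa_em_hom, kappa_hybrid, kappa_slip
from .fitting import ConductanceDataset
from .pb_cylinder import PoreModel

__all__ = [
    "NoiseSpec",
    "TelegraphSpec",
    "IVTrace",
    "DEFAULT_VOLTAGES",
    "DEFAULT_C_GRID",
    "gen_iv_trace",
    "slope_conductance",
    "gen_conductance_dataset",
    "gen_particle_snapshots",
]

#: voltage-clamp protocol: 0 to 200 mV in 10 mV steps
DEFAULT_VOLTAGES = np.round(np.arange(0.0, 0.2000001, 0.01), 10)

#: 13 log-spaced molarities covering 1e-4 to 5 mol/l
DEFAULT_C_GRID = np.logspace(math.log10(1e-4), math.log10(5.0), 13)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise specification.

    ``relative_sigma`` is the multiplicative Gaussian scale applied to the
    conductance sample-by-sample (I-V traces) or as a log-normal factor on
    G (datasets); ``current_floor`` an additive instrument noise floor in
    A. A seed is mandatory: every generated artifact must be reproducible.
    """

    seed: int
    relative_sigma: float = 0.05
    current_floor: float = 0.0

    def __post_init__(self):
        if self.relative_sigma < 0 or self.current_floor < 0:
            raise InvalidParameterError("noise scales must be >= 0")


@dataclass(frozen=True)
class TelegraphSpec:
    """Two-state Markov switching of the pore conductance.

    The pore dwells in the high/low conductance state for exponentially
    distributed times with the given means (seconds), mimicking
    oscillations between the stable and metastable wetting branches.
    """

    g_high: float
    g_low: float
    dwell_high: float
    dwell_low: float

    def __post_init__(self):
        if self.g_high <= 0 or self.g_low <= 0:
            raise InvalidParameterError("conductance levels must be > 0")
        if self.dwell_high <= 0 or self.dwell_low <= 0:
            raise InvalidParameterError("dwell times must be > 0")


@dataclass(frozen=True)
class IVTrace:
    """Per-voltage-step mean currents from a voltage-clamp protocol."""

    voltages: np.ndarray  # V, strictly increasing
    currents: np.ndarray  # A, mean over samples at each step
    g_true: float
    samples: Optional[np.ndarray] = None  # (n_steps, n_samples) raw currents

    def __post_init__(self):
        if np.any(np.diff(self.voltages) <= 0):
            raise InvalidParameterError("voltages must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"V_volt": self.voltages, "I_amp": self.currents})


def gen_iv_trace(
    g_true: float,
    voltages: Optional[Sequence[float]] = None,
    noise: Optional[NoiseSpec] = None,
    telegraph: Optional[TelegraphSpec] = None,
    n_samples: int = 200,
    sample_dt: float = 1e-3,
    keep_samples: bool = False,
) -> IVTrace:
    """Simulate a voltage-clamp recording of an Ohmic pore.

    At every step V the sampled current is I = G_eff (1 + s Z) V + floor Z'
    with Z, Z' standard normal; when a telegraph spec is given, G_eff
    switches between its two levels as a two-state Markov chain advanced
    sample-by-sample (switching probability sample_dt / dwell), the state
    persisting across voltage steps. The stored current per step is the
    sample mean.
    """
    if not g_true > 0:
        raise InvalidParameterError("g_true must be > 0")
    v = np.asarray(DEFAULT_VOLTAGES if voltages is None else voltages, dtype=float)
    if noise is None:
        rng = None
        rel, floor = 0.0, 0.0
    else:
        rng = np.random.default_rng(noise.seed)
        rel, floor = noise.relative_sigma, noise.current_floor

    n_steps = v.size
    if telegraph is None:
        g_eff = np.full((n_steps, n_samples), g_true)
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        p_leave_high = min(sample_dt / telegraph.dwell_high, 1.0)
        p_leave_low = min(sample_dt / telegraph.dwell_low, 1.0)
        state = np.empty(n_steps * n_samples, dtype=bool)  # True = high
        u = rng.random(n_steps * n_samples)
        s = True
        for i in range(state.size):
            p = p_leave_high if s else p_leave_low
            if u[i] < p:
                s = not s
            state[i] = s
        g_eff = np.where(state, telegraph.g_high, telegraph.g_low).reshape(
            n_steps, n_samples
        )

    if rng is not None and (rel > 0 or floor > 0):
        g_sample = g_eff * (1.0 + rel * rng.standard_normal(g_eff.shape))
        currents = g_sample * v[:, None] + floor * rng.standard_normal(g_eff.shape)
    else:
        currents = g_eff * v[:, None]
    mean_i = currents.mean(axis=1)
    return IVTrace(
        voltages=v,
        currents=mean_i,
        g_true=g_true,
        samples=currents if keep_samples else None,
    )


def slope_conductance(trace: IVTrace) -> Tuple[float, float]:
    """Conductance as the OLS slope of mean current vs voltage, with its
    standard error (both in S).

    An intercept is fitted (and discarded) so a constant offset current
    does not bias the slope.
    """
    if trace.voltages.size < 3:
        raise DegenerateInputError("need >= 3 voltage steps for a slope estimate")
    res = linregress(trace.voltages, trace.currents)
    return float(res.slope), float(res.stderr)


def gen_conductance_dataset(
    pore: PoreModel,
    electrolyte: Optional[Electrolyte] = None,
    model_id: str = "hybrid",
    c_grid: Optional[Sequence[float]] = None,
    noise: Optional[NoiseSpec] = None,
    residual_conductance: float = 0.0,
    label: str = "synthetic",
) -> ConductanceDataset:
    """Forward-model conductance-concentration dataset with log-normal noise.

    ``model_id``: ``hybrid``/``hybrid_slip`` (the mesoscopic model,
    slip taken from the pore), ``homogeneous`` (Donnan migration plus the
    uncorrected advective term sigma^2/(2 eta) and slip), or
    ``phenomenological`` (bulk + residual). Noise multiplies G by
    exp(s Z) -- conductances span decades, so multiplicative errors are
    the realistic model.
    """
    elec = electrolyte if electrolyte is not None else default_nacl()
    c = np.asarray(DEFAULT_C_GRID if c_grid is None else c_grid, dtype=float)
    g = np.empty(c.size)
    for i, ci in enumerate(c):
        if model_id in ("hybrid", "hybrid_slip"):
            kap = kappa_hybrid(elec, pore, ci).kappa_total
            g[i] = conductance(kap, pore)
        elif model_id == "homogeneous":
            sig = pore.surface_charge
            kap = (
                kappa_em_hom(elec, pore, ci)
                + sig * sig / (2.0 * elec.viscosity)
                + kappa_slip(elec, pore)
            )
            g[i] = conductance(kap, pore)
        elif model_id == "phenomenological":
            kap = bulk_conductivity(elec, ci)
            g[i] = conductance(kap, pore, residual=residual_conductance)
        else:
            raise InvalidParameterError(f"unknown model_id {model_id!r}")
    if noise is not None and noise.relative_sigma > 0:
        rng = np.random.default_rng(noise.seed)
        g = g * np.exp(noise.relative_sigma * rng.standard_normal(c.size))
    return ConductanceDataset(
        pore_label=label, c_s=c, conductance=g, length=pore.length
    )


def gen_particle_snapshots(
    radius: float,
    l_z: float,
    n_snapshots: int = 5,
    densities: Optional[Dict[str, float]] = None,
    shells: Optional[Dict[str, Sequence[Tuple[float, float, float]]]] = None,
    exclusion_radius: Optional[float] = None,
    seed: int = 0,
) -> List[pd.DataFrame]:
    """Poisson-placed particle snapshots with radial shell structure.

    Units are nm. Per species, points are placed in the cylinder
    r < exclusion_radius (default: the pore radius) with intensity
    lambda(r) = rho0 [1 + sum_j A_j exp(-(r - r0_j)^2 / (2 w_j^2))]
    via thinning of a uniform Poisson process; ``densities`` maps species
    to the base density rho0 in nm^-3 (default: water 33.0, cation/anion
    0.06 -- liquid water plus ~0.1 M salt), ``shells`` maps species to
    (r0, width, amplitude) triples. Identical seeds give identical output.
    """
    if radius <= 0 or l_z <= 0:
        raise InvalidParameterError("radius and l_z must be > 0")
    if n_snapshots < 1:
        raise InvalidParameterError("need n_snapshots >= 1")
    r_acc = radius if exclusion_radius is None else float(exclusion_radius)
    if not 0 < r_acc <= radius:
        raise InvalidParameterError("exclusion_radius must lie in (0, radius]")
    dens = {"water": 33.0, "cation": 0.06, "anion": 0.06}
    if densities is not None:
        dens = dict(densities)
    if any(v < 0 for v in dens.values()):
        raise InvalidParameterError("densities must be >= 0")
    shells = shells or {}

    rng = np.random.default_rng(seed)
    out: List[pd.DataFrame] = []
    volume = math.pi * r_acc**2 * l_z
    for _ in range(n_snapshots):
        frames = []
        for sp, rho0 in dens.items():
            if rho0 == 0:
                continue
            sp_shells = shells.get(sp, ())
            amp_max = 1.0 + sum(max(a, 0.0) for _, _, a in sp_shells)
            lam_max = rho0 * amp_max
            n_cand = rng.poisson(lam_max * volume)
            # uniform points in the accessible cylinder
            rr = r_acc * np.sqrt(rng.random(n_cand))
            th = 2.0 * math.pi * rng.random(n_cand)
            zz = l_z * rng.random(n_cand)
            lam = np.ones(n_cand)
            for r0, w, a in sp_shells:
                lam += a * np.exp(-((rr - r0) ** 2) / (2.0 * w * w))
            keep = rng.random(n_cand) < lam / amp_max
            frames.append(
                pd.DataFrame(
                    {
                        "species": sp,
                        "x_nm": rr[keep] * np.cos(th[keep]),
                        "y_nm": rr[keep] * np.sin(th[keep]),
                        "z_nm": zz[keep],
                    }
                )
            )
        snap = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=list(SNAPSHOT_COLS))
        )
        out.append(snap)
    return out


SNAPSHOT_COLS = ("species", "x_nm", "y_nm", "z_nm")
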