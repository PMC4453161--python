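"""Bulk electrolyte properties: ions, mobilities, Bjerrum/Debye lengths, conductivity.

The model electrolyte is a fully dissociated 1:1 salt (NaCl by default) in
water. Ion transport coefficients are the dilute-limit bulk values; an
optional empirical correction factor chi(c_s) <= 1 can be supplied as a
table to account for the sub-linear growth of the bulk conductivity at
high concentration caused by ion-ion interactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .constants import (
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    VACUUM_PERMITTIVITY,
    number_density,
)
from .errors import ConfigurationError, InvalidParameterError

__all__ = [
    "IonSpecies",
    "Electrolyte",
    "LengthScales",
    "mobility",
    "bjerrum_length",
    "debye_length",
    "bulk_conductivity",
    "default_nacl",
    "SODIUM",
    "CHLORIDE",
]


@dataclass(frozen=True)
class IonSpecies:
    """A monovalent ion with its dilute-limit bulk diffusivity.

    Parameters
    ----------
    name : str
        Label, e.g. ``"Na+"``.
    valence : int
        Signed valence; only +1 / -1 are supported.
    diffusivity : float
        Bulk diffusion coefficient at the reference temperature, m^2 s^-1.
    """

    name: str
    valence: int
    diffusivity: float

    def __post_init__(self):
        if self.valence not in (-1, 1):
            raise InvalidParameterError(
                f"only monovalent ions are supported, got valence={self.valence}"
            )
        if not self.diffusivity >= 0:
            raise InvalidParameterError(
                f"diffusivity must be >= 0, got {self.diffusivity}"
            )


#: Dilute-limit NaCl ion species at 25 degC.
SODIUM = IonSpecies("Na+", +1, 1.334e-9)
CHLORIDE = IonSpecies("Cl-", -1, 2.032e-9)


@dataclass(frozen=True)
class Electrolyte:
    """A 1:1 electrolyte in water with solvent properties.

    ``correction_table`` is an optional sequence of (c_s mol l^-1, chi)
    pairs with strictly increasing concentrations and 0 < chi <= 1,
    interpolated monotonically in log-concentration by
    :func:`bulk_conductivity`.
    """

    cation: IonSpecies = SODIUM
    anion: IonSpecies = CHLORIDE
    temperature: float = 298.15  # K
    viscosity: float = 8.94e-4  # Pa s, bulk water at 25 degC
    relative_permittivity: float = 78.3
    correction_table: Optional[Tuple[Tuple[float, float], ...]] = field(default=None)

    def __post_init__(self):
        if not self.temperature > 0:
            raise InvalidParameterError("temperature must be > 0 K")
        if not self.viscosity > 0:
            raise InvalidParameterError("viscosity must be > 0 Pa s")
        if not self.relative_permittivity > 0:
            raise InvalidParameterError("relative_permittivity must be > 0")
        if self.cation.valence != 1 or self.anion.valence != -1:
            raise InvalidParameterError("cation must have valence +1, anion -1")
        if self.correction_table is not None:
            tab = tuple((float(c), float(x)) for c, x in self.correction_table)
            cs = np.array([c for c, _ in tab])
            chis = np.array([x for _, x in tab])
            if len(tab) < 1:
                raise InvalidParameterError("correction_table must be non-empty")
            if np.any(cs <= 0) or np.any(np.diff(cs) <= 0):
                raise InvalidParameterError(
                    "correction_table concentrations must be positive and strictly increasing"
                )
            if np.any(chis <= 0) or np.any(chis > 1):
                raise InvalidParameterError("correction factors must satisfy 0 < chi <= 1")
            object.__setattr__(self, "correction_table", tab)

    # -- convenience -------------------------------------------------------
    @property
    def thermal_energy(self) -> float:
        """k_B T in J."""
        return BOLTZMANN * self.temperature


@dataclass(frozen=True)
class LengthScales:
    """Electrostatic length scales of the electrolyte (m)."""

    bjerrum: float
    debye: float

    def __post_init__(self):
        if not (self.bjerrum > 0 and self.debye > 0):
            raise InvalidParameterError("length scales must be positive")


def default_nacl(**overrides) -> Electrolyte:
    """The default NaCl electrolyte at 25 degC; keyword overrides allowed."""
    return Electrolyte(**overrides)


def mobility(ion: IonSpecies, temperature: float) -> float:
    """Electrophoretic mobility mu = e D / (k_B T), in m^2 V^-1 s^-1.

    The Einstein relation connects the mobility to the (dilute-limit bulk)
    diffusion coefficient of the ion.
    """
    if not temperature > 0:
        raise InvalidParameterError("temperature must be > 0 K")
    if ion.diffusivity < 0:
        raise InvalidParameterError("diffusivity must be >= 0")
    return ELEMENTARY_CHARGE * ion.diffusivity / (BOLTZMANN * temperature)


def bjerrum_length(electrolyte: Electrolyte) -> float:
    """Bjerrum length l_B = e^2 / (4 pi eps0 eps_r k_B T), in m.

    Distance at which two elementary charges interact with energy k_B T
    (about 0.7 nm in water at room temperature).
    """
    e = ELEMENTARY_CHARGE
    return e * e / (
        4.0
        * math.pi
        * VACUUM_PERMITTIVITY
        * electrolyte.relative_permittivity
        * electrolyte.thermal_energy
    )


def debye_length(electrolyte: Electrolyte, c_s: float) -> float:
    """Debye-Hueckel screening length lambda_DH = (8 pi l_B n_s)^(-1/2), in m."""
    if not c_s > 0:
        raise InvalidParameterError(f"c_s must be > 0 mol/l, got {c_s}")
    n_s = number_density(c_s)
    return 1.0 / math.sqrt(8.0 * math.pi * bjerrum_length(electrolyte) * n_s)


def length_scales(electrolyte: Electrolyte, c_s: float) -> LengthScales:
    """Bundle Bjerrum and Debye lengths at molarity ``c_s``."""
    return LengthScales(bjerrum_length(electrolyte), debye_length(electrolyte, c_s))


def chi_factor(electrolyte: Electrolyte, c_s) -> np.ndarray:
    """Interpolated high-concentration correction factor chi(c_s).

    Piecewise-linear (hence monotone-preserving) in log10 c_s; chi = 1
    below the table's first concentration, clamped to the last chi above it.
    """
    if electrolyte.correction_table is None:
        raise ConfigurationError("no correction_table configured on this electrolyte")
    c_s = np.asarray(c_s, dtype=float)
    tab_c = np.log10([c for c, _ in electrolyte.correction_table])
    tab_chi = np.array([x for _, x in electrolyte.correction_table])
    with np.errstate(divide="ignore"):
        logc = np.log10(c_s)
    chi = np.interp(logc, tab_c, tab_chi, left=1.0, right=tab_chi[-1])
    return chi


def bulk_conductivity(
    electrolyte: Electrolyte, c_s, apply_correction: bool = False
):
    """Bulk conductivity kappa_b = e (mu+ + mu-) n_s, in S m^-1.

    With ``apply_correction`` the result is multiplied by the interpolated
    chi(c_s) <= 1 from the electrolyte's correction table (a configuration
    error if no table is present). Without it, kappa_b is strictly linear
    in c_s (ion-ion interactions neglected).
    """
    c_arr = np.asarray(c_s, dtype=float)
    if np.any(c_arr < 0):
        raise InvalidParameterError("c_s must be >= 0 mol/l")
    mu_sum = mobility(electrolyte.cation, electrolyte.temperature) + mobility(
        electrolyte.anion, electrolyte.temperature
    )
    kappa = ELEMENTARY_CHARGE * mu_sum * number_density(c_arr)
    if apply_correction:
        kappa = kappa * chi_factor(electrolyte, c_arr)
    if np.ndim(c_s) == 0:
        return float(kappa)
    return kappa
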