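"""Physical constants (CODATA, via scipy) and unit conversions.

Everything internal to the package is SI; molar salt concentrations
(mol l^-1) are converted to number densities (m^-3) exactly once, at
module boundaries, through :func:`number_density`.
"""

from scipy.constants import Avogadro as AVOGADRO
from scipy.constants import Boltzmann as BOLTZMANN
from scipy.constants import elementary_charge as ELEMENTARY_CHARGE
from scipy.constants import epsilon_0 as VACUUM_PERMITTIVITY

__all__ = [
    "AVOGADRO",
    "BOLTZMANN",
    "ELEMENTARY_CHARGE",
    "VACUUM_PERMITTIVITY",
    "number_density",
]


def number_density(c_mol_per_l: float) -> float:
    """Number density (m^-3) of each ion species of a 1:1 salt at molarity ``c_mol_per_l``."""
    return c_mol_per_l * 1e3 * AVOGADRO
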