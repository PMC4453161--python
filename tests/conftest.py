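import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import porecond as pc

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def nacl() -> pc.Electrolyte:
    """Default NaCl electrolyte at 25 degC."""
    return pc.default_nacl()


@pytest.fixture(scope="session")
def reference_pore() -> pc.PoreModel:
    """R = 5 nm, L = 6 um, sigma = -0.01 C/m^2 (the worked-example pore)."""
    return pc.PoreModel.from_nm(5.0, 6.0, surface_charge=-0.01)


def pore_with_sigma_star(electrolyte, target, radius_nm=5.0, length_um=6.0,
                         slip_nm=0.0) -> pc.PoreModel:
    """Build a pore whose dimensionless surface charge equals ``target``."""
    from porecond.constants import ELEMENTARY_CHARGE

    lb = pc.bjerrum_length(electrolyte)
    sigma = target * ELEMENTARY_CHARGE / (2 * np.pi * lb * radius_nm * 1e-9)
    return pc.PoreModel.from_nm(
        radius_nm, length_um, surface_charge=-sigma, slip_length_nm=slip_nm
    )
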