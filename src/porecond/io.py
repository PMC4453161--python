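"""File formats: CSV readers/writers and YAML run configuration.

CSV dialect: comma-separated, ``.`` decimal, ``#`` comment lines. Column
names carry their units (``c_mol_per_l``, ``G_S``, ``V_volt``, ``I_amp``,
``x_nm``...), one unit convention per key, so files are self-describing
and unit mistakes surface early.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .electrolyte import Electrolyte, IonSpecies
from .errors import ConfigurationError, InvalidParameterError
from .fitting import ConductanceDataset, FitResult
from .profiles import RadialProfile
from .synthetic import IVTrace

__all__ = [
    "read_conductance_csv",
    "write_conductance_csv",
    "read_chi_table",
    "read_iv_trace_csv",
    "write_iv_trace_csv",
    "read_snapshots_csv",
    "write_snapshots_csv",
    "write_profile_csv",
    "write_fit_report",
    "load_config",
    "electrolyte_from_config",
]


def _read_comment_meta(path) -> Dict[str, str]:
    """Parse ``# key=value ...`` comment lines preceding the CSV header."""
    meta: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    return meta


def read_conductance_csv(path) -> ConductanceDataset:
    """Read a per-pore conductance dataset.

    Format: ``# pore=<label> L_m=<value>`` comment, then columns
    ``c_mol_per_l,G_S``.
    """
    meta = _read_comment_meta(path)
    if "L_m" not in meta:
        raise ConfigurationError(f"{path}: missing '# pore=<label> L_m=<value>' header")
    df = pd.read_csv(path, comment="#")
    if not {"c_mol_per_l", "G_S"} <= set(df.columns):
        raise ConfigurationError(f"{path}: expected columns c_mol_per_l,G_S")
    return ConductanceDataset(
        pore_label=meta.get("pore", Path(path).stem),
        c_s=df["c_mol_per_l"].to_numpy(),
        conductance=df["G_S"].to_numpy(),
        length=float(meta["L_m"]),
    )


def write_conductance_csv(dataset: ConductanceDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pore={dataset.pore_label} L_m={dataset.length:.6e}\n")
        pd.DataFrame(
            {"c_mol_per_l": dataset.c_s, "G_S": dataset.conductance}
        ).to_csv(fh, index=False)


def read_chi_table(path) -> Tuple[Tuple[float, float], ...]:
    """Read a high-concentration correction table ``c_mol_per_l,chi``."""
    df = pd.read_csv(path, comment="#")
    if not {"c_mol_per_l", "chi"} <= set(df.columns):
        raise ConfigurationError(f"{path}: expected columns c_mol_per_l,chi")
    return tuple(zip(df["c_mol_per_l"].astype(float), df["chi"].astype(float)))


def read_iv_trace_csv(path) -> IVTrace:
    """Read a ``V_volt,I_amp`` voltage-clamp trace."""
    df = pd.read_csv(path, comment="#")
    if not {"V_volt", "I_amp"} <= set(df.columns):
        raise ConfigurationError(f"{path}: expected columns V_volt,I_amp")
    v = df["V_volt"].to_numpy(dtype=float)
    i = df["I_amp"].to_numpy(dtype=float)
    g_est = i[-1] / v[-1] if v[-1] != 0 else float("nan")
    return IVTrace(voltages=v, currents=i, g_true=g_est)


def write_iv_trace_csv(trace: IVTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_snapshots_csv(path) -> Tuple[List[pd.DataFrame], Dict[str, float]]:
    """Read particle snapshots: ``species,x_nm,y_nm,z_nm`` plus an optional
    ``snapshot`` column separating frames; metadata comment
    ``# l_z_nm=<..> r_nm=<..>``."""
    meta = {k: float(v) for k, v in _read_comment_meta(path).items()}
    df = pd.read_csv(path, comment="#")
    need = {"species", "x_nm", "y_nm", "z_nm"}
    if not need <= set(df.columns):
        raise ConfigurationError(f"{path}: expected columns species,x_nm,y_nm,z_nm")
    if len(df) == 0:
        raise InvalidParameterError(f"{path}: snapshot file contains no particles")
    if "snapshot" in df.columns:
        snaps = [g.drop(columns="snapshot") for _, g in df.groupby("snapshot")]
    else:
        snaps = [df]
    return snaps, meta


def write_snapshots_csv(snapshots: Sequence[pd.DataFrame], path, l_z: float,
                        radius: Optional[float] = None) -> None:
    parts = []
    for i, s in enumerate(snapshots):
        s = s.copy()
        s["snapshot"] = i
        parts.append(s)
    df = pd.concat(parts, ignore_index=True)
    with open(path, "w") as fh:
        extra = f" r_nm={radius:.6g}" if radius is not None else ""
        fh.write(f"# l_z_nm={l_z:.6g}{extra}\n")
        df.to_csv(fh, index=False)


def write_profile_csv(profile: RadialProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# l_z_nm={profile.l_z:.6g} n_snapshots={profile.n_snapshots} "
            f"mode={profile.mode}\n"
        )
        profile.to_frame().to_csv(fh, index=False)


def write_fit_report(fit: FitResult, path, extra: Optional[dict] = None) -> None:
    doc = fit.to_dict()
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# run configuration

DEFAULT_CONFIG: dict = {
    "electrolyte": {
        "d_plus_m2_per_s": 1.334e-9,
        "d_minus_m2_per_s": 2.032e-9,
        "temperature_K": 298.15,
        "viscosity_Pa_s": 8.94e-4,
        "relative_permittivity": 78.3,
        "chi_table_csv": None,
    },
    "pore": {"length_m": 6e-6},
    "fit": {"model_id": "hybrid", "b_m": 0.0, "n_starts": 10, "seed": 1},
}


def load_config(path=None) -> dict:
    """Load a YAML run configuration, merged over the defaults.

    Keys carry explicit units in their names (``L`` is always ``length_m``,
    slip is ``b_m``); no key accepts more than one unit convention.
    """
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigurationError(f"{path}: top level must be a mapping")
        for section, values in user.items():
            if section not in cfg:
                raise ConfigurationError(f"{path}: unknown config section {section!r}")
            if not isinstance(values, dict):
                raise ConfigurationError(f"{path}: section {section!r} must be a mapping")
            for key, val in values.items():
                if key not in cfg[section]:
                    raise ConfigurationError(
                        f"{path}: unknown key {section}.{key} (units are part of key names)"
                    )
                cfg[section][key] = val
    if cfg["fit"]["model_id"] not in ("phenomenological", "hybrid", "hybrid_slip",
                                      "homogeneous"):
        raise ConfigurationError(f"invalid model_id {cfg['fit']['model_id']!r}")
    if cfg["fit"].get("seed") is None:
        raise ConfigurationError("fit.seed must be set")
    return cfg


def electrolyte_from_config(cfg: dict) -> Electrolyte:
    ec = cfg["electrolyte"]
    table = None
    if ec.get("chi_table_csv"):
        table = read_chi_table(ec["chi_table_csv"])
    return Electrolyte(
        cation=IonSpecies("Na+", +1, float(ec["d_plus_m2_per_s"])),
        anion=IonSpecies("Cl-", -1, float(ec["d_minus_m2_per_s"])),
        temperature=float(ec["temperature_K"]),
        viscosity=float(ec["viscosity_Pa_s"]),
        relative_permittivity=float(ec["relative_permittivity"]),
        correction_table=table,
    )
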