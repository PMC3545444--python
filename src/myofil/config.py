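"""Run configuration: TOML sections over the model's literature defaults.

A run file has flat key-value sections ``[kinetics]``, ``[mechanics]``,
``[simulation]``, ``[sweep]``, ``[analysis]`` and ``[synth]``; any key not
listed in :data:`DEFAULTS` is rejected.  Every run writes its fully
resolved configuration beside its outputs so that a result is always
reproducible from the sidecar alone.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Any, Mapping

from .kinetics import InvalidParameterError, RateSet, make_rates
from .mechanics import ActinMechanics, MyofilamentParams
from .simulator import SimConfig

__all__ = ["DEFAULTS", "load_config", "resolve", "sim_config", "dump_toml"]

#: Default parameter table.  Physical constants are the printed literature
#: values the model is built on; simulation controls are package choices.
DEFAULTS: dict[str, dict[str, Any]] = {
    "kinetics": {
        "atp": 1.0,  # uM
        "k1": 100.0,  # s^-1, ATP hydrolysis
        "k2": 30.0,  # s^-1, actin binding
        "k3": 1.0e4,  # s^-1, powerstroke + Pi release
        "k4": 1.0e3,  # s^-1, ADP release
        "k6": 2.0e3,  # s^-1, detachment
        "kt": 4.0,  # uM^-1 s^-1, ATP binding
    },
    "mechanics": {
        "n_m": 30,
        "n_leading": 15,
        "n_trailing": 15,
        "p_st": 0.0,
        "d": 5.0,  # nm
        "kappa": 1.0,  # pN/nm
        "l_bz": 160.0,  # nm
        "lp_um": 15.0,  # um
        "kT": 4.0,  # pN nm
        "r_min_um": 0.18,  # um
    },
    "simulation": {
        "duration": 20.0,  # s
        "burn_in": 0.0,  # s
        "record_interval": 0.1,  # s
        "allow_bending": False,
        "seed": 0,
    },
    "sweep": {
        "atp": [0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 8.0, 12.0],  # uM
        "n_m": [30],
        "p_st": [0.0],
        "reps": 10,
        "duration": 100.0,  # s
        "burn_in": 5.0,  # s
    },
    "analysis": {
        "n": 20,  # radial-velocity span, frames
        "dt": 0.2,  # s
        "smooth_window": 2.0,  # s
        "min_dwell": 0.9,  # s
    },
    "synth": {
        "n_tracks": 20,
        "dt": 0.2,
        "base_speed": 0.05,
        "accel_rate": 0.05,
        "accel_magnitude": 3.0,
        "accel_duration": 1.0,
        "position_noise_sd": 0.02,
        "duration_mean": 8.0,
        "intensity_baseline": 100.0,
        "intensity_noise_sd": 4.0,
        "intensity_step_factor": 2.0,
        "length_median": 0.56,  # um
        "length_log_sd": 0.5,
        "length_n": 1000,
        "length_scale_factor": 0.5,
        "dwell_rate": 1.0,  # s^-1
        "dwell_n": 1000,
        "seed": 0,
    },
}


def resolve(user: Mapping[str, Mapping[str, Any]] | None = None) -> dict[str, dict[str, Any]]:
    """Merge a user configuration over the defaults, rejecting unknown keys."""
    cfg = {sec: dict(vals) for sec, vals in DEFAULTS.items()}
    if user is None:
        return cfg
    for sec, vals in user.items():
        if sec not in cfg:
            raise InvalidParameterError(f"unknown config section [{sec}]")
        if not isinstance(vals, Mapping):
            raise InvalidParameterError(f"[{sec}] must be a table of key = value pairs")
        for key, val in vals.items():
            if key not in cfg[sec]:
                raise InvalidParameterError(f"unknown key '{key}' in section [{sec}]")
            cfg[sec][key] = val
    return cfg


def load_config(path: str | Path | None) -> dict[str, dict[str, Any]]:
    """Read a TOML run file (or None for pure defaults) and resolve it."""
    if path is None:
        return resolve(None)
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    with open(p, "rb") as fh:
        user = tomllib.load(fh)
    return resolve(user)


def sim_config(cfg: Mapping[str, Mapping[str, Any]], **overrides: Any) -> SimConfig:
    """Build a :class:`SimConfig` from a resolved configuration."""
    kin = cfg["kinetics"]
    mech = cfg["mechanics"]
    sim = cfg["simulation"]
    rates = make_rates(
        kin["atp"],
        k1=kin["k1"],
        k2=kin["k2"],
        k3=kin["k3"],
        k4=kin["k4"],
        k6=kin["k6"],
        kt=kin["kt"],
    )
    params = MyofilamentParams(
        n_m=mech["n_m"],
        n_leading=mech["n_leading"],
        n_trailing=mech["n_trailing"],
        p_st=mech["p_st"],
        d=mech["d"],
        kappa=mech["kappa"],
        l_bz=mech["l_bz"],
    )
    actin = ActinMechanics(
        lp_um=mech["lp_um"], kT=mech["kT"], r_min_um=mech["r_min_um"], l_bz=mech["l_bz"]
    )
    kw: dict[str, Any] = dict(
        atp=kin["atp"],
        duration=sim["duration"],
        burn_in=sim["burn_in"],
        record_interval=sim["record_interval"],
        allow_bending=sim["allow_bending"],
        seed=sim["seed"],
        params=params,
        actin=actin,
        rates=rates,
    )
    kw.update(overrides)
    if "atp" in overrides and "rates" not in overrides:
        kw["rates"] = rates.with_atp(overrides["atp"])
    return SimConfig(**kw)


def _fmt(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_fmt(x) for x in v) + "]"
    return repr(v)


def dump_toml(cfg: Mapping[str, Mapping[str, Any]]) -> str:
    """Serialize a resolved configuration back to TOML text."""
    lines = []
    for sec, vals in cfg.items():
        lines.append(f"[{sec}]")
        for key, val in vals.items():
            lines.append(f"{key} = {_fmt(val)}")
        lines.append("")
    return "\n".join(lines)
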