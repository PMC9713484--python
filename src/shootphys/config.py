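"""Flat key–value configuration files (YAML) for leaf and stand parameters.

Keys use the tabulated units (e.g. ``K_O25`` in mmol mol⁻¹, ``d_L`` in cm);
conversion to internal units happens once when the :class:`LeafParams` is
built.  Unknown keys are rejected; omitted keys fall back to the defaults
and the substitution is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import yaml

from .budget import SimulationConfig
from .errors import ConfigurationError
from .params import LeafParams, TemperatureResponse

log = logging.getLogger(__name__)

#: leaf-level defaults in *tabulated* units
LEAF_DEFAULTS = {
    "pathway": "C4",
    "C_A": 402.9, "O_A": 209.46,          # μmol/mol, mmol/mol
    "d_L": 0.1,                           # cm
    "d": 0.05,                            # m
    "m": 4.53, "g_w0": 0.017, "V_pr": 80.0, "VPD_ref": 10.0,
    "theta": 0.7, "f": 0.15, "alpha": 0.85, "alpha_IR": 0.96,
    "beta": 2.1, "x": 0.4, "n1": 149.8, "n2": 24.5,
    "Gamma_star25": 38.6, "E_Gamma_star": 23400.0,
    "K_C25": 485.0, "E_K_C": 35600.0,
    "K_O25": 146.0, "E_K_O": 15100.0,     # mmol/mol
    "K_P25": 40.0, "E_K_P": 68100.0,
    "R_d25": 1.95, "E_R_d": 41850.0,
    "R_m25": 0.975, "R_s25": 0.975,
    "S_co25": 2862.0, "E_S_co": 27400.0,
    "V_cmax25": 49.0, "E_V_cmax": 53400.0,
    "J_max25": 299.6, "E_J_max": 37000.0, "D_J_max": 220000.0, "S_J_max": 710.0,
    "V_pmax25": 119.2, "E_V_pmax": 37000.0, "D_V_pmax": 214500.0,
    "S_V_pmax": 663.0,
    "g_s25": 0.00287, "E_g_s": 116700.0, "D_g_s": 264600.0, "S_g_s": 860.0,
    "bl_coeff": 10.97,
    "kair_intercept": 0.0243, "kair_slope": 0.00007,
    "nu_intercept": 1.415e-5, "nu_slope": 0.09e-5,
    "hvap_intercept": 45060.0, "hvap_slope": 425.0,
    "t_sky_offset": 40.0,
}

_SIM_KEYS = {f.name for f in fields(SimulationConfig)}


@dataclass
class FullConfig:
    leaf: LeafParams
    simulation: SimulationConfig
    raw: dict


def build_leaf_params(values: dict) -> LeafParams:
    """Construct :class:`LeafParams` from a complete tabulated-unit mapping."""
    v = values
    return LeafParams(
        pathway=v["pathway"],
        gamma_star=TemperatureResponse(v["Gamma_star25"], v["E_Gamma_star"]),
        K_C=TemperatureResponse(v["K_C25"], v["E_K_C"]),
        K_O=TemperatureResponse(v["K_O25"] * 1000.0, v["E_K_O"]),
        K_P=TemperatureResponse(v["K_P25"], v["E_K_P"]),
        R_d=TemperatureResponse(v["R_d25"], v["E_R_d"]),
        R_m=TemperatureResponse(v["R_m25"], v["E_R_d"]),
        R_s=TemperatureResponse(v["R_s25"], v["E_R_d"]),
        gamma_star_c4=TemperatureResponse(0.5 / v["S_co25"], v["E_S_co"]),
        V_cmax=TemperatureResponse(v["V_cmax25"], v["E_V_cmax"]),
        J_max=TemperatureResponse(v["J_max25"], v["E_J_max"],
                                  D=v["D_J_max"], S=v["S_J_max"]),
        V_pmax=TemperatureResponse(v["V_pmax25"], v["E_V_pmax"],
                                   D=v["D_V_pmax"], S=v["S_V_pmax"]),
        g_s=TemperatureResponse(v["g_s25"], v["E_g_s"],
                                D=v["D_g_s"], S=v["S_g_s"]),
        m=v["m"], g_w0=v["g_w0"], V_pr=v["V_pr"], VPD_ref=v["VPD_ref"],
        theta=v["theta"], f=v["f"], alpha=v["alpha"], alpha_IR=v["alpha_IR"],
        beta=v["beta"], x=v["x"],
        d_L=v["d_L"] / 100.0,  # cm -> m
        d=v["d"], C_A=v["C_A"],
        O_A=v["O_A"] * 1000.0,  # mmol/mol -> μmol/mol
        n1=v["n1"], n2=v["n2"],
        bl_coeff=v["bl_coeff"],
        kair_intercept=v["kair_intercept"], kair_slope=v["kair_slope"],
        nu_intercept=v["nu_intercept"], nu_slope=v["nu_slope"],
        hvap_intercept=v["hvap_intercept"], hvap_slope=v["hvap_slope"],
        t_sky_offset=v["t_sky_offset"],
    )


def parse_config(mapping: dict) -> FullConfig:
    """Validate a flat mapping and build leaf + simulation settings."""
    mapping = dict(mapping or {})
    unknown = sorted(set(mapping) - set(LEAF_DEFAULTS) - _SIM_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {', '.join(unknown)}")

    leaf_vals = dict(LEAF_DEFAULTS)
    sim_vals = {}
    for key, val in mapping.items():
        if key in LEAF_DEFAULTS:
            leaf_vals[key] = val
        else:
            sim_vals[key] = val
    for key in sorted(set(LEAF_DEFAULTS) - set(mapping)):
        log.debug("config key %s not given; using default %r",
                  key, LEAF_DEFAULTS[key])

    return FullConfig(leaf=build_leaf_params(leaf_vals),
                      simulation=SimulationConfig(**sim_vals),
                      raw=dict(LEAF_DEFAULTS, **mapping))


def read_config(path) -> FullConfig:
    """Read a YAML config file (flat key–value) into the full parameter set."""
    with open(path) as fh:
        try:
            mapping = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise ConfigurationError("config must be a flat key-value mapping")
    return parse_config(mapping)


def write_config(path, cfg: FullConfig) -> None:
    """Write the full (tabulated-unit) key set so configs round-trip."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.raw, fh, sort_keys=True)
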