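"""Physiological constants, temperature responses and the water-stress response.

All photosynthetic parameters are stored with their value at the reference
temperature ``T_REF`` = 298.15 K and, where temperature dependent, an
activation energy (simple Arrhenius) plus optionally a deactivation energy
and entropy factor (peaked Arrhenius).

Unit conventions
----------------
* gas concentrations: μmol mol⁻¹ internally.  Oxygen-side quantities
  (``O_A``, ``K_O``) are *entered* in mmol mol⁻¹, matching how they are
  usually tabulated, and converted once at construction.
* leaf thickness ``d_L`` is stored in metres (entered in cm in config files).
* collar water potential in hPa, negative under tension.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache
from math import exp
from typing import Optional

import numpy as np

from .errors import ConfigurationError, InvalidInputError

#: Universal gas constant, J K⁻¹ mol⁻¹.
R_GAS = 8.31446
#: Reference temperature for p25 parameter values, K.
T_REF = 298.15
#: Stefan-Boltzmann constant, W m⁻² K⁻⁴.
SIGMA = 5.67e-8


@dataclass(frozen=True)
class TemperatureResponse:
    """Arrhenius-type temperature response of a physiological parameter.

    Parameters
    ----------
    p25 : value of the parameter at 298.15 K, in the parameter's own units.
    E : activation energy, J mol⁻¹.
    D : deactivation energy, J mol⁻¹ (peaked form only).
    S : entropy factor, J K⁻¹ mol⁻¹ (peaked form only).

    Evaluating either form at 298.15 K returns exactly ``p25``.
    """

    p25: float
    E: float
    D: Optional[float] = None
    S: Optional[float] = None

    @property
    def peaked(self) -> bool:
        return self.D is not None or self.S is not None

    def __call__(self, t_leaf: float) -> float:
        if self.peaked:
            return peaked_arrhenius(self, t_leaf)
        return arrhenius(self, t_leaf)


def arrhenius(tr: TemperatureResponse, t_leaf: float) -> float:
    """Simple Arrhenius response p25·exp(E(T−T_ref)/(T_ref·R·T))."""
    if t_leaf <= 0.0:
        raise InvalidInputError(f"non-positive leaf temperature: {t_leaf} K")
    return tr.p25 * exp(tr.E * (t_leaf - T_REF) / (T_REF * R_GAS * t_leaf))


def peaked_arrhenius(tr: TemperatureResponse, t_leaf: float) -> float:
    """Peaked Arrhenius response with deactivation at high temperature.

    The simple Arrhenius factor is multiplied by
    ``(1 + exp((T_ref·S − D)/(T_ref·R))) / (1 + exp((T·S − D)/(R·T)))``
    which equals one at the reference temperature and decays once thermal
    deactivation (D, S) takes over.
    """
    if tr.D is None or tr.S is None:
        raise ConfigurationError(
            "peaked Arrhenius requires both deactivation energy D and entropy factor S"
        )
    if t_leaf <= 0.0:
        raise InvalidInputError(f"non-positive leaf temperature: {t_leaf} K")
    base = tr.p25 * exp(tr.E * (t_leaf - T_REF) / (T_REF * R_GAS * t_leaf))
    num = 1.0 + exp((T_REF * tr.S - tr.D) / (T_REF * R_GAS))
    den = 1.0 + exp((t_leaf * tr.S - tr.D) / (R_GAS * t_leaf))
    return base * num / den


@dataclass(frozen=True)
class WaterStressCurve:
    """Piecewise-linear map from collar water potential (hPa) to stress factor S_w.

    S_w is 1 when unstressed and 0 at maximal stress; values between
    breakpoints are linearly interpolated and clamped to [0, 1] outside the
    breakpoint range.  Breakpoints must be given with ascending potential.
    """

    psi: tuple = (-12000.0, -8000.0, -3000.0)
    s_w: tuple = (0.0, 0.4, 1.0)

    def __post_init__(self):
        psi = np.asarray(self.psi, dtype=float)
        s_w = np.asarray(self.s_w, dtype=float)
        if psi.shape != s_w.shape or psi.ndim != 1 or psi.size < 2:
            raise ConfigurationError("water-stress curve needs matching 1-d breakpoint arrays")
        if np.any(np.diff(psi) <= 0):
            raise ConfigurationError("water-stress breakpoints must be strictly ascending")
        if np.any(np.diff(s_w) < 0):
            raise ConfigurationError("S_w must be non-decreasing in collar potential")
        if np.any((s_w < 0) | (s_w > 1)):
            raise ConfigurationError("S_w breakpoints must lie in [0, 1]")

    def __call__(self, psi_c):
        return water_stress(self, psi_c)


def water_stress(curve: WaterStressCurve, psi_c) -> float:
    """Evaluate the drought response curve at collar potential ``psi_c`` (hPa).

    With the default breakpoints this reproduces the standard response:
    1 above −3000 hPa, 0.4 + 0.6(Ψc+8000)/5000 down to −8000 hPa,
    (Ψc+12000)/10000 down to −12000 hPa, and 0 below.
    """
    out = np.interp(psi_c, curve.psi, curve.s_w)
    out = np.clip(out, 0.0, 1.0)
    if np.ndim(psi_c) == 0:
        return float(out)
    return out


# default Table-3-style constant set; see docstrings for provenance of units
def _tr(p25, E, D=None, S=None):
    return TemperatureResponse(p25=p25, E=E, D=D, S=S)


@dataclass(frozen=True)
class LeafParams:
    """Full leaf-level constant set with temperature responses.

    Defaults are the maize (C4) parameterization; the ``pathway`` flag decides
    which assimilation/gas equations the coupled solver uses.  Oxygen-side
    values are stored internally in μmol mol⁻¹ (see module docstring).
    """

    pathway: str = "C4"

    # temperature-dependent kinetic parameters
    gamma_star: TemperatureResponse = field(default_factory=lambda: _tr(38.6, 23400.0))
    K_C: TemperatureResponse = field(default_factory=lambda: _tr(485.0, 35600.0))
    # entered as 146 mmol mol⁻¹ -> 146000 μmol mol⁻¹
    K_O: TemperatureResponse = field(default_factory=lambda: _tr(146000.0, 15100.0))
    K_P: TemperatureResponse = field(default_factory=lambda: _tr(40.0, 68100.0))
    R_d: TemperatureResponse = field(default_factory=lambda: _tr(1.95, 41850.0))
    R_m: TemperatureResponse = field(default_factory=lambda: _tr(0.975, 41850.0))
    R_s: TemperatureResponse = field(default_factory=lambda: _tr(0.975, 41850.0))
    # γ* of the C4 bundle sheath: half the inverse RuBisCo specificity, 1/(2·S_c/o)
    gamma_star_c4: TemperatureResponse = field(
        default_factory=lambda: _tr(0.5 / 2862.0, 27400.0)
    )
    V_cmax: TemperatureResponse = field(default_factory=lambda: _tr(49.0, 53400.0))
    J_max: TemperatureResponse = field(
        default_factory=lambda: _tr(299.6, 37000.0, D=220000.0, S=710.0)
    )
    V_pmax: TemperatureResponse = field(
        default_factory=lambda: _tr(119.2, 37000.0, D=214500.0, S=663.0)
    )
    g_s: TemperatureResponse = field(
        default_factory=lambda: _tr(0.00287, 116700.0, D=264600.0, S=860.0)
    )

    # scalar constants
    m: float = 4.53                  # Ball-Berry-Leuning slope, dimensionless
    g_w0: float = 0.017              # residual stomatal conductance, mol m⁻² s⁻¹
    V_pr: float = 80.0               # PEP regeneration rate, μmol m⁻² s⁻¹
    VPD_ref: float = 10.0            # reference vapor pressure deficit, kPa
    theta: float = 0.7               # electron-transport curvature factor
    f: float = 0.15                  # spectral light quality factor
    alpha: float = 0.85              # solar absorptance
    alpha_IR: float = 0.96           # infrared absorptance
    beta: float = 2.1                # light conversion factor, μmol J⁻¹
    x: float = 0.4                   # C4 electron-transport partitioning factor
    d_L: float = 0.001               # leaf thickness, m (0.1 cm)
    d: float = 0.05                  # characteristic leaf length, m
    C_A: float = 402.9               # atmospheric CO2, μmol mol⁻¹
    O_A: float = 209460.0            # atmospheric O2, μmol mol⁻¹ (209.46 mmol mol⁻¹)
    n1: float = 149.8                # J_max per unit leaf N concentration
    n2: float = 24.5                 # V_cmax per unit leaf N concentration

    # energy-balance coefficients (kept configurable; see methods note)
    bl_coeff: float = 10.97          # boundary-layer thickness coefficient
    kair_intercept: float = 0.0243   # W m⁻¹ K⁻¹ at 0 °C
    kair_slope: float = 0.00007      # W m⁻¹ K⁻² per °C
    nu_intercept: float = 1.415e-5   # m² s⁻¹ at 0 °C
    nu_slope: float = 0.09e-5        # m² s⁻¹ per °C
    hvap_intercept: float = 45060.0  # J mol⁻¹ at 0 °C
    hvap_slope: float = 425.0        # J mol⁻¹ per °C (subtracted)
    t_sky_offset: float = 40.0       # T_sky = T_a − offset, K

    def __post_init__(self):
        if self.pathway not in ("C3", "C4"):
            raise ConfigurationError(f"pathway must be 'C3' or 'C4', got {self.pathway!r}")
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigurationError("absorptance alpha must be in (0, 1]")
        if not 0.0 < self.theta < 1.0:
            raise ConfigurationError("curvature factor theta must be in (0, 1)")
        if self.g_w0 < 0.0:
            raise ConfigurationError("residual conductance g_w0 must be non-negative")
        if self.d_L <= 0.0 or self.d <= 0.0:
            raise ConfigurationError("leaf dimensions must be positive")

    def replace(self, **kw) -> "LeafParams":
        return dataclasses.replace(self, **kw)

    def at_leaf_temperature(self, t_leaf: float) -> "KineticRates":
        """Evaluate every temperature-dependent parameter at ``t_leaf`` (K)."""
        return _kinetics(self, float(t_leaf))


@dataclass(frozen=True)
class KineticRates:
    """Temperature-evaluated kinetic parameter bundle (units as in LeafParams)."""

    gamma_star: float
    K_C: float
    K_O: float
    K_P: float
    R_d: float
    R_m: float
    R_s: float
    gamma_star_c4: float
    V_cmax: float
    J_max: float
    V_pmax: float
    g_s: float


@lru_cache(maxsize=4096)
def _kinetics(params: LeafParams, t_leaf: float) -> KineticRates:
    return KineticRates(
        gamma_star=params.gamma_star(t_leaf),
        K_C=params.K_C(t_leaf),
        K_O=params.K_O(t_leaf),
        K_P=params.K_P(t_leaf),
        R_d=params.R_d(t_leaf),
        R_m=params.R_m(t_leaf),
        R_s=params.R_s(t_leaf),
        gamma_star_c4=params.gamma_star_c4(t_leaf),
        V_cmax=params.V_cmax(t_leaf),
        J_max=params.J_max(t_leaf),
        V_pmax=params.V_pmax(t_leaf),
        g_s=params.g_s(t_leaf),
    )
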