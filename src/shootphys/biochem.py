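"""Leaf biochemistry: FvCB assimilation, gas steady states, stomata, compensation points.

All functions here are pure scalar functions of their inputs.  Gas
concentrations are in μmol mol⁻¹ throughout (callers holding oxygen in
mmol mol⁻¹ must convert before calling; :class:`EnvironmentState` stores
``O_A`` in mmol mol⁻¹ to match the usual tabulation and the solver converts
once at entry).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Optional

import numpy as np

from .errors import ConfigurationError, InvalidInputError


@dataclass(frozen=True)
class EnvironmentState:
    """Instantaneous atmospheric forcing around a leaf.

    T_a air temperature K; P pressure Pa; I_s solar irradiance W m⁻²;
    VPD vapor pressure deficit kPa; v wind speed m s⁻¹; C_A atmospheric CO2
    μmol mol⁻¹; O_A atmospheric O2 mmol mol⁻¹; psi_c collar potential hPa.
    """

    T_a: float
    P: float = 101325.0
    I_s: float = 0.0
    VPD: float = 1.0
    v: float = 1.5
    C_A: float = 402.9
    O_A: float = 209.46
    psi_c: float = -1000.0

    def __post_init__(self):
        if self.P <= 0.0:
            raise InvalidInputError("atmospheric pressure must be positive")
        if self.I_s < 0.0:
            raise InvalidInputError("irradiance must be non-negative")
        if self.VPD < 0.0:
            raise InvalidInputError("VPD must be non-negative")
        if self.v <= 0.0:
            raise InvalidInputError("wind speed must be positive")
        if self.T_a <= 0.0:
            raise InvalidInputError("air temperature must be positive (kelvin)")


@dataclass
class LeafState:
    """Solved coupled leaf state.

    Rates in μmol m⁻² s⁻¹, conductances in mol m⁻² s⁻¹, concentrations in
    μmol mol⁻¹, temperatures in K, transpiration J_v in mol m⁻² s⁻¹.
    C4-only fields (C_s, O_s, V_p, Gamma_s) are None for C3 leaves.
    """

    A: float = 0.0
    A_c: float = 0.0
    A_j: float = 0.0
    R_d: float = 0.0
    J: float = 0.0
    g_w: float = 0.0
    C_m: float = 0.0
    O_m: float = 0.0
    Gamma: float = 0.0
    Gamma_star: float = 0.0
    T_L: float = 298.15
    J_v: float = 0.0
    C_s: Optional[float] = None
    O_s: Optional[float] = None
    V_p: Optional[float] = None
    Gamma_s: Optional[float] = None
    R_m: Optional[float] = None
    R_s: Optional[float] = None
    converged: bool = True
    iterations: int = 0
    residuals: dict = field(default_factory=dict)


def electron_transport(I_s: float, J_max: float, theta: float,
                       alpha: float, f: float, beta: float) -> float:
    """Potential electron transport rate J (μmol m⁻² s⁻¹).

    The light absorbed by photosystem II is I₂ = β·I_s·α(1−f)/2 and J is the
    smaller root of the non-rectangular hyperbola
    θJ² − (I₂+J_max)J + I₂·J_max = 0, so J ≤ min(I₂, J_max).
    """
    if not 0.0 < theta < 1.0:
        raise ConfigurationError("theta must be in (0, 1)")
    i2 = beta * I_s * alpha * (1.0 - f) / 2.0
    disc = (i2 + J_max) ** 2 - 4.0 * theta * i2 * J_max
    return (i2 + J_max - sqrt(max(disc, 0.0))) / (2.0 * theta)


def c3_assimilation(C_m: float, O_m: float, J: float, V_cmax: float,
                    K_C: float, K_O: float, gamma_star: float):
    """C3 gross assimilation: returns (A, A_c, A_j) with A = min(A_c, A_j).

    A_c = V_cmax(C_m−Γ*)/(C_m + K_C(1+O_m/K_O)) is the RuBisCo-limited rate,
    A_j = (C_m−Γ*)·J/(4C_m + 8Γ*) the electron-transport-limited rate.
    The phosphate-limited rate is assumed non-binding.
    """
    a_c = V_cmax * (C_m - gamma_star) / (C_m + K_C * (1.0 + O_m / K_O))
    a_j = (C_m - gamma_star) * J / (4.0 * C_m + 8.0 * gamma_star)
    return min(a_c, a_j), a_c, a_j


def pep_carboxylation(C_m: float, V_pmax: float, K_P: float, V_pr: float) -> float:
    """PEP carboxylation rate V_p = min(C_m·V_pmax/(C_m+K_P), V_pr)."""
    return min(C_m * V_pmax / (C_m + K_P), V_pr)


def c4_assimilation(C_s: float, O_s: float, J: float, V_cmax: float,
                    K_C: float, K_O: float, gamma_star_c4: float, x: float):
    """C4 gross assimilation in the bundle sheath: returns (A, A_c, A_j).

    ``gamma_star_c4`` is γ* = 1/(2·S_c/o).  The shared numerator
    (C_s − γ*·O_s) vanishes at the bundle-sheath compensation point.
    A_j uses the fraction (1−x) of electron transport allocated to the
    bundle sheath.
    """
    num = C_s - gamma_star_c4 * O_s
    a_c = num * V_cmax / (C_s + K_C * (1.0 + O_s / K_O))
    a_j = num * (1.0 - x) * J / (3.0 * C_s + 7.0 * gamma_star_c4 * O_s)
    return min(a_c, a_j), a_c, a_j


def c3_gas_steady_state(g_w: float, A: float, R_d: float,
                        C_A: float, O_A: float):
    """Quasi-steady-state mesophyll concentrations for a C3 leaf.

    C_m = C_A − 1.6(A−R_d)/g_w and O_m = O_A + 1.25(A−R_d)/g_w, i.e. the
    fixed point of the stomatal-diffusion/assimilation balance.  O_A must be
    in μmol mol⁻¹ here.
    """
    if g_w <= 0.0:
        raise InvalidInputError("stomatal conductance must be positive")
    net = A - R_d
    return C_A - 1.6 * net / g_w, O_A + 1.25 * net / g_w


def c4_gas_steady_state(g_w: float, g_s: float, A_r: float, V_p: float,
                        R_m: float, R_s: float, C_A: float, O_A: float):
    """Quasi-steady-state mesophyll and bundle-sheath concentrations (C4).

    Solves the coupled linear balances
        C_m = (g_w/1.6·C_A + g_s·C_s − V_p + R_m)/(g_w/1.6 + g_s)
        C_s = (V_p − A_r + R_s)/g_s + C_m
    and the analogous oxygen pair with interface conductance 0.047·g_s.
    Returns (C_m, C_s, O_m, O_s); O_A must be in μmol mol⁻¹.
    """
    if g_w <= 0.0 or g_s <= 0.0:
        raise InvalidInputError("conductances must be positive")
    a = g_w / 1.6
    mat = np.array([[a + g_s, -g_s], [-g_s, g_s]])
    rhs = np.array([a * C_A - V_p + R_m, V_p - A_r + R_s])
    c_m, c_s = np.linalg.solve(mat, rhs)

    b = g_w / 1.25
    gso = 0.047 * g_s
    mat_o = np.array([[b + gso, -gso], [-gso, gso]])
    rhs_o = np.array([b * O_A - R_m, A_r - R_s])
    o_m, o_s = np.linalg.solve(mat_o, rhs_o)
    return float(c_m), float(c_s), float(o_m), float(o_s)


def stomatal_conductance(A: float, R_d: float, Gamma: float, VPD: float,
                         S_w: float, C_A: float, m: float, g_w0: float,
                         VPD_ref: float) -> float:
    """Ball-Berry-Leuning stomatal conductance with a water-stress factor.

    g_w = m·S_w·(A−R_d)/(C_A−Γ)·(1+VPD/VPD_ref)⁻¹ + g_w0, floored at the
    residual conductance g_w0 (conductance below residual is unphysical).
    VPD and VPD_ref in kPa.
    """
    if C_A <= Gamma:
        raise InvalidInputError("ambient CO2 at or below the compensation point")
    g_w = m * S_w * (A - R_d) / (C_A - Gamma) / (1.0 + VPD / VPD_ref) + g_w0
    return max(g_w, g_w0)


def c3_compensation_point(R_d: float, V_cmax: float, K_C: float, K_O: float,
                          O_m: float, gamma_star: float) -> float:
    """C3 CO2 compensation point with dark respiration,
    Γ = (Γ* + K_C·(R_d/V_cmax)(1+O_m/K_O)) / (1 − R_d/V_cmax)."""
    ratio = R_d / V_cmax
    if ratio >= 1.0:
        raise InvalidInputError("dark respiration at or above V_cmax")
    return (gamma_star + K_C * ratio * (1.0 + O_m / K_O)) / (1.0 - ratio)


def c4_bundle_sheath_compensation(R_d: float, V_cmax: float, K_C: float,
                                  K_O: float, O_m: float,
                                  gamma_star_c4: float) -> float:
    """Bundle-sheath CO2 concentration at the compensation point,
    Γ_s = (γ*·O_m + K_C·(R_d/V_cmax)(1+O_m/K_O)) / (1 + R_d/V_cmax)."""
    ratio = R_d / V_cmax
    return (gamma_star_c4 * O_m + K_C * ratio * (1.0 + O_m / K_O)) / (1.0 + ratio)


def c4_compensation_point(Gamma_s: float, K_P: float, V_pmax: float,
                          g_s: float, R_m: float) -> float:
    """C4 leaf-level compensation point, Γ = (K_P/V_pmax)·(g_s·Γ_s − R_m).

    Implemented exactly in this printed form; isolated here so a corrected
    variant can be substituted if this rendering proves typographic.
    """
    return K_P / V_pmax * (g_s * Gamma_s - R_m)


def compensation_points(pathway: str, R_d: float, R_m: float, V_cmax: float,
                        V_pmax: float, K_C: float, K_O: float, K_P: float,
                        O_m: float, gamma_star: float, gamma_star_c4: float,
                        g_s: float):
    """Dispatch to the pathway-appropriate compensation point.

    Returns (Γ, Γ_s) where Γ_s is None for C3.
    """
    if pathway == "C3":
        return c3_compensation_point(R_d, V_cmax, K_C, K_O, O_m, gamma_star), None
    gamma_s = c4_bundle_sheath_compensation(R_d, V_cmax, K_C, K_O, O_m, gamma_star_c4)
    return c4_compensation_point(gamma_s, K_P, V_pmax, g_s, R_m), gamma_s
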