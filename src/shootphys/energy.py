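"""Leaf energy balance and temperature.

The steady-state balance of a leaf exchanging radiation, sensible heat and
latent heat with the air reads

    E(T_L) = α·I + α_IR·σ·(T_surr⁴ + T_sky⁴) − 2·α_IR·σ·T_L⁴
             − 2·K_air(T_a)·(T_L − T_a)/δ_bl − J_v·H_vap(T_a) = 0

with T_surr = T_a and T_sky = T_a − 40 by default, and the factors of two
accounting for both leaf faces.  The boundary-layer thickness is
δ_bl = 10.97·√(d·ν(T_a)/v).  E is a quartic in T_L solved with Newton's
method started at T_a, guarded by bisection on a ±50 K bracket.

Air-property approximations (K_air, ν, H_vap) are linear in temperature over
0–50 °C; their coefficients are configurable on :class:`~shootphys.params.LeafParams`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import exp, sqrt

from .biochem import EnvironmentState
from .errors import NoRootError
from .params import SIGMA, LeafParams


@dataclass(frozen=True)
class EnergyBalanceTerms:
    """Individual terms of the balance at a given leaf temperature, W m⁻²."""

    A_S: float
    A_IR: float
    e_IR: float
    H_c: float
    H_t: float
    E: float
    T_L: float
    delta_bl: float


def air_properties(T_a: float, params: LeafParams = None):
    """Thermal conductivity K_air (W m⁻¹ K⁻¹) and kinematic viscosity ν (m² s⁻¹).

    Linear fits valid for 273.15–323.15 K; outside that range the fit is
    extrapolated with a warning.
    """
    p = params or _DEFAULT
    if not 273.15 <= T_a <= 323.15:
        warnings.warn(
            f"air temperature {T_a:.2f} K outside the 273.15-323.15 K validity "
            "range of the air-property fits; extrapolating",
            stacklevel=2,
        )
    tc = T_a - 273.15
    k_air = p.kair_intercept + p.kair_slope * tc
    nu = p.nu_intercept + p.nu_slope * tc
    return k_air, nu


def latent_heat(T_a: float, params: LeafParams = None) -> float:
    """Molar heat of vaporization of water, H_vap(T_a) = 45060 − 425(T_a−273.15) J mol⁻¹."""
    p = params or _DEFAULT
    return p.hvap_intercept - p.hvap_slope * (T_a - 273.15)


def saturation_vapor_pressure(T: float) -> float:
    """Saturation vapor pressure over water (Tetens), Pa."""
    tc = T - 273.15
    return 610.78 * exp(17.27 * tc / (tc + 237.3))


def leaf_transpiration(g_w: float, T_L: float, T_a: float, VPD: float,
                       P: float) -> float:
    """Leaf transpiration J_v (mol m⁻² s⁻¹) from the leaf-air vapor gradient.

    J_v = g_w·(e_sat(T_L) − e_air)/P with e_air = e_sat(T_a) − VPD,
    floored at zero.  VPD in kPa; in a whole-plant model this flux would be
    supplied by the root hydraulic network instead.
    """
    e_air = saturation_vapor_pressure(T_a) - VPD * 1000.0
    j_v = g_w * (saturation_vapor_pressure(T_L) - e_air) / P
    return max(j_v, 0.0)


def boundary_layer_thickness(d: float, T_a: float, v: float,
                             params: LeafParams = None) -> float:
    """Laminar boundary-layer thickness δ_bl = c·√(d·ν(T_a)/v), m."""
    p = params or _DEFAULT
    _, nu = air_properties(T_a, p)
    return p.bl_coeff * sqrt(d * nu / v)


def energy_terms(T_L: float, env: EnvironmentState, J_v: float,
                 params: LeafParams = None, t_surr: float = None,
                 t_sky: float = None) -> EnergyBalanceTerms:
    """Evaluate every term of the balance at leaf temperature ``T_L``.

    ``t_surr``/``t_sky`` override the defaults T_a and T_a − offset, which is
    useful for constructing symmetric test equilibria.
    """
    p = params or _DEFAULT
    t_surr = env.T_a if t_surr is None else t_surr
    t_sky = env.T_a - p.t_sky_offset if t_sky is None else t_sky
    k_air, _ = air_properties(env.T_a, p)
    delta_bl = boundary_layer_thickness(p.d, env.T_a, env.v, p)

    a_s = p.alpha * env.I_s
    a_ir = p.alpha_IR * SIGMA * (t_surr ** 4 + t_sky ** 4)
    e_ir = 2.0 * p.alpha_IR * SIGMA * T_L ** 4
    h_c = 2.0 * k_air * (T_L - env.T_a) / delta_bl
    h_t = J_v * latent_heat(env.T_a, p)
    return EnergyBalanceTerms(
        A_S=a_s, A_IR=a_ir, e_IR=e_ir, H_c=h_c, H_t=h_t,
        E=a_s + a_ir - e_ir - h_c - h_t, T_L=T_L, delta_bl=delta_bl,
    )


def energy_residual(T_L: float, env: EnvironmentState, J_v: float,
                    params: LeafParams = None, t_surr: float = None,
                    t_sky: float = None) -> float:
    """Signed energy-balance residual E(T_L) in W m⁻² (zero at the solution)."""
    return energy_terms(T_L, env, J_v, params, t_surr, t_sky).E


def solve_leaf_temperature(env: EnvironmentState, J_v: float,
                           params: LeafParams = None, t_init: float = None,
                           tol: float = 1e-9, max_iter: int = 60,
                           bracket: float = 50.0, t_surr: float = None,
                           t_sky: float = None) -> float:
    """Leaf temperature solving E(T_L) = 0.

    Newton iteration with the analytic derivative
    dE/dT_L = −8·α_IR·σ·T_L³ − 2·K_air/δ_bl, started from T_a (or ``t_init``),
    falling back to bisection on [T_a−bracket, T_a+bracket] if Newton leaves
    the bracket or stalls.  Raises :class:`NoRootError` if the residual has no
    sign change in the bracket.
    """
    p = params or _DEFAULT
    k_air, _ = air_properties(env.T_a, p)
    delta_bl = boundary_layer_thickness(p.d, env.T_a, env.v, p)
    lo, hi = env.T_a - bracket, env.T_a + bracket

    def res(t):
        return energy_residual(t, env, J_v, p, t_surr, t_sky)

    t = env.T_a if t_init is None else float(t_init)
    t = min(max(t, lo), hi)
    for _ in range(max_iter):
        e = res(t)
        if abs(e) < tol:
            return t
        de = -8.0 * p.alpha_IR * SIGMA * t ** 3 - 2.0 * k_air / delta_bl
        t_new = t - e / de
        if not lo <= t_new <= hi:
            break
        if abs(t_new - t) < 1e-13:
            return t_new
        t = t_new
    else:
        if abs(res(t)) < tol:
            return t

    # bisection fallback; E is strictly decreasing in T_L
    e_lo, e_hi = res(lo), res(hi)
    if e_lo * e_hi > 0.0:
        raise NoRootError(
            f"energy balance has no root in [{lo:.2f}, {hi:.2f}] K "
            f"(E={e_lo:.3g}..{e_hi:.3g} W m^-2)"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        e_mid = res(mid)
        if abs(e_mid) < tol or hi - lo < 1e-13:
            return mid
        if e_lo * e_mid <= 0.0:
            hi, e_hi = mid, e_mid
        else:
            lo, e_lo = mid, e_mid
    return 0.5 * (lo + hi)


def solve_leaf_temperature_coupled(env: EnvironmentState, g_w: float,
                                   params: LeafParams = None,
                                   t_init: float = None, tol: float = 1e-9,
                                   max_iter: int = 60, bracket: float = 50.0,
                                   t_surr: float = None,
                                   t_sky: float = None) -> float:
    """Leaf temperature with transpiration evaluated at the trial temperature.

    Solves E(T_L) = 0 where J_v = J_v(g_w, T_L) follows the leaf-air vapor
    gradient, so the latent-heat term responds to T_L.  This removes the
    spurious no-root situations that arise when a large fixed J_v is paired
    with a cool trial temperature.  Newton with a finite-difference
    derivative, guarded by bisection on [T_a−bracket, T_a+bracket].
    """
    p = params or _DEFAULT
    lo, hi = env.T_a - bracket, env.T_a + bracket

    def res(t):
        j_v = leaf_transpiration(g_w, t, env.T_a, env.VPD, env.P)
        return energy_residual(t, env, j_v, p, t_surr, t_sky)

    t = env.T_a if t_init is None else float(t_init)
    t = min(max(t, lo), hi)
    for _ in range(max_iter):
        e = res(t)
        if abs(e) < tol:
            return t
        h = 1e-4
        de = (res(t + h) - e) / h
        if not de < 0.0:  # residual must be decreasing; fall through otherwise
            break
        t_new = t - e / de
        if not lo <= t_new <= hi:
            break
        if abs(t_new - t) < 1e-13:
            return t_new
        t = t_new
    else:
        if abs(res(t)) < tol:
            return t

    e_lo, e_hi = res(lo), res(hi)
    if e_lo * e_hi > 0.0:
        raise NoRootError(
            f"coupled energy balance has no root in [{lo:.2f}, {hi:.2f}] K"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        e_mid = res(mid)
        if abs(e_mid) < tol or hi - lo < 1e-13:
            return mid
        if e_lo * e_mid <= 0.0:
            hi, e_hi = mid, e_mid
        else:
            lo, e_lo = mid, e_mid
    return 0.5 * (lo + hi)


_DEFAULT = LeafParams()
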