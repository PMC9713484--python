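"""Nested Newton–Raphson fixed-point solver and the coupled leaf-state solve.

The leaf model is a fixed-point system x_i = F_i(x_1..x_n) coupling
assimilation, stomatal conductance, gas concentrations and leaf temperature.
Rather than a single multivariate Newton step, the solver nests univariate
Newton iterations: variable 1 (outermost) is updated by Newton while, before
each residual evaluation, variables 2..n are themselves re-solved the same
way.  At convergence every |F_i(x*) − x_i*| < ε_i simultaneously.  If the
outer sweeps do not converge within ``max_outer`` (default 40) steps the
supplied fallback values (normally the previous timestep) are returned with
``converged = False``.

For the leaf system the nesting order is T_L (outermost), then g_w, then A,
then the gas concentration (innermost): the slowest feedback sits outermost,
and with the gas balance innermost every univariate map is single-rooted
(with A innermost the C4 assimilation map has several fixed points in A at
frozen gas concentrations and Newton can lock onto an unphysical branch).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from . import biochem, energy
from .biochem import EnvironmentState, LeafState
from .errors import ShootPhysError
from .params import LeafParams


@dataclass
class FixedPointSystem:
    """A system of update maps x_i = F_i(x) with per-variable tolerances.

    ``updates[i]`` takes the full state vector and returns the new value of
    variable ``i``.  ``scales`` sets the magnitude used for relative
    finite-difference steps (defaults to max(|x0_i|, 1)).
    """

    updates: Sequence[Callable[[np.ndarray], float]]
    x0: np.ndarray
    tol: np.ndarray
    fallback: Optional[np.ndarray] = None
    max_outer: int = 40
    inner_max: int = 12
    scales: Optional[np.ndarray] = None
    names: Optional[Sequence[str]] = None
    lo: Optional[np.ndarray] = None
    hi: Optional[np.ndarray] = None

    def __post_init__(self):
        self.x0 = np.asarray(self.x0, dtype=float)
        self.tol = np.asarray(self.tol, dtype=float)
        n = len(self.updates)
        if self.x0.shape != (n,) or self.tol.shape != (n,):
            raise ShootPhysError("x0/tol length must match number of update maps")
        if np.any(self.tol <= 0):
            raise ShootPhysError("tolerances must be positive")
        if self.fallback is None:
            self.fallback = self.x0.copy()
        else:
            self.fallback = np.asarray(self.fallback, dtype=float)
        if self.scales is None:
            self.scales = np.maximum(np.abs(self.x0), 1.0)
        else:
            self.scales = np.asarray(self.scales, dtype=float)
        self.lo = (np.full(n, -np.inf) if self.lo is None
                   else np.asarray(self.lo, dtype=float))
        self.hi = (np.full(n, np.inf) if self.hi is None
                   else np.asarray(self.hi, dtype=float))


@dataclass
class RootFindResult:
    x: np.ndarray
    converged: bool
    iterations: int
    residuals: np.ndarray


def _eval_update(sys: FixedPointSystem, i: int, x: np.ndarray) -> float:
    try:
        return float(sys.updates[i](x))
    except ShootPhysError:
        raise
    except Exception as exc:  # annotate with the failing variable
        name = sys.names[i] if sys.names else str(i)
        raise ShootPhysError(f"update map for variable {name!r} failed: {exc}") from exc


def _solve_level(sys: FixedPointSystem, level: int, x: np.ndarray) -> None:
    """Solve variable ``level`` by 1-D Newton, re-solving deeper levels
    before every residual evaluation."""
    n = len(sys.updates)
    if level >= n:
        return

    def g(xi: float) -> float:
        x[level] = xi
        _solve_level(sys, level + 1, x)
        return _eval_update(sys, level, x) - xi

    lo, hi = sys.lo[level], sys.hi[level]

    def clamp(v):
        return min(max(v, lo), hi)

    xi = clamp(x[level])
    fx = g(xi)
    for _ in range(sys.inner_max):
        if abs(fx) < sys.tol[level]:
            break
        # forward difference with a coarse relative step: differences taken
        # across nested inner solves carry O(tol) noise, so a fine step would
        # be noise-dominated
        h = 1e-3 * max(abs(xi), sys.scales[level])
        if xi + h > hi:
            h = -h
        deriv = (g(xi + h) - fx) / h
        if not np.isfinite(deriv) or abs(deriv) < 1e-14:
            step = fx  # successive-substitution fallback
        else:
            step = -fx / deriv
        xi_new = clamp(xi + step)
        fx_new = g(xi_new)
        # damp the step while it fails to reduce the residual (min-kinks in
        # the assimilation law can make full Newton steps overshoot)
        shrink = 0
        while (not np.isfinite(fx_new) or abs(fx_new) > abs(fx)) and shrink < 5:
            step *= 0.5
            xi_new = clamp(xi + step)
            fx_new = g(xi_new)
            shrink += 1
        if not np.isfinite(fx_new):
            break
        if xi_new == xi:
            break
        xi, fx = xi_new, fx_new
    if abs(fx) >= sys.tol[level] and np.isfinite(lo) and np.isfinite(hi):
        xi = _bracketed_fallback(g, lo, hi, xi, fx, sys.tol[level])
    x[level] = xi
    _solve_level(sys, level + 1, x)


def _bracketed_fallback(g, lo: float, hi: float, best_x: float,
                        best_f: float, tol: float) -> float:
    """Scan [lo, hi] for a descending sign change of g and bisect it.

    Used when Newton stalls on a level whose map is locally expansive
    (|dF/dx| > 1 from one side) or has several crossings; the descending
    crossing (g going + to −) is the stable fixed point of the update map.
    Returns the best point found if no sign change exists in the bounds.
    """
    grid = np.linspace(lo, hi, 13)
    vals = []
    for t in grid:
        v = g(t)
        vals.append(v if np.isfinite(v) else np.nan)
        if abs(v) < tol:
            return t
    pair = None
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if np.isnan(a) or np.isnan(b):
            continue
        if a > 0.0 >= b:       # descending crossing preferred
            pair = (grid[i], grid[i + 1], a, b)
            break
    if pair is None:
        for i in range(len(grid) - 1):
            a, b = vals[i], vals[i + 1]
            if not (np.isnan(a) or np.isnan(b)) and a * b <= 0.0:
                pair = (grid[i], grid[i + 1], a, b)
                break
    if pair is None:
        # keep whichever point has the smallest residual
        finite = [(abs(v), t) for v, t in zip(vals, grid) if np.isfinite(v)]
        if finite and min(finite)[0] < abs(best_f):
            return min(finite)[1]
        return best_x
    a_x, b_x, a_f, b_f = pair
    for _ in range(80):
        mid = 0.5 * (a_x + b_x)
        m_f = g(mid)
        if abs(m_f) < tol or b_x - a_x < 1e-12 * max(1.0, abs(mid)):
            return mid
        if a_f * m_f <= 0.0:
            b_x, b_f = mid, m_f
        else:
            a_x, a_f = mid, m_f
    return 0.5 * (a_x + b_x)


def _damped_init(sys: FixedPointSystem, x: np.ndarray,
                 target: float = 0.05, max_sweeps: int = 60) -> None:
    """Cheap damped simultaneous-substitution sweeps to reach the Newton basin.

    Far from the solution the univariate maps can be steeper than one in
    their own variable, which sends nested Newton towards unphysical
    branches; a few damped sweeps x ← x + λ(F(x)−x) are enough to enter the
    locally contracting region.  Runs entirely before the first counted
    outer step and never moves x to a point with a larger scaled residual.
    """
    n = len(sys.updates)
    lam = 0.5
    f = np.empty(n)

    def evaluate(xv, out):
        for i in range(n):
            out[i] = _eval_update(sys, i, xv)
        return np.max(np.abs(out - xv) / sys.scales)

    try:
        r = evaluate(x, f)
    except ShootPhysError:
        return
    f_try = np.empty(n)
    for _ in range(max_sweeps):
        if r < target or lam < 1e-3:
            return
        x_try = x + lam * (f - x)
        try:
            r_try = evaluate(x_try, f_try)
        except ShootPhysError:
            lam *= 0.5
            continue
        if not np.isfinite(r_try) or r_try > r:
            lam *= 0.5
            continue
        x[:], f[:], r = x_try, f_try, r_try


def nested_root_find(sys: FixedPointSystem) -> RootFindResult:
    """Solve the fixed-point system with the nested Newton–Raphson scheme.

    Returns the simultaneous solution when every residual |F_i(x)−x_i| falls
    below its tolerance; otherwise, after ``max_outer`` outer sweeps, returns
    the fallback values with ``converged=False``.
    """
    x = sys.x0.copy()
    _damped_init(sys, x)
    resid = np.empty(len(sys.updates))
    for outer in range(1, sys.max_outer + 1):
        for i in range(len(sys.updates)):
            resid[i] = abs(_eval_update(sys, i, x) - x[i])
        if np.all(resid < sys.tol):
            return RootFindResult(x=x, converged=True, iterations=outer - 1,
                                  residuals=resid.copy())
        _solve_level(sys, 0, x)
    for i in range(len(sys.updates)):
        resid[i] = abs(_eval_update(sys, i, x) - x[i])
    if np.all(resid < sys.tol):
        return RootFindResult(x=x, converged=True, iterations=sys.max_outer,
                              residuals=resid.copy())
    return RootFindResult(x=sys.fallback.copy(), converged=False,
                          iterations=sys.max_outer, residuals=resid.copy())


# ---------------------------------------------------------------------------
# coupled leaf system
# ---------------------------------------------------------------------------

def night_state(env: EnvironmentState, params: LeafParams) -> LeafState:
    """Predetermined default leaf state (used as first-timestep fallback)."""
    kin = params.at_leaf_temperature(env.T_a)
    return LeafState(A=0.0, g_w=params.g_w0, C_m=env.C_A, O_m=env.O_A * 1000.0,
                     T_L=env.T_a, R_d=kin.R_d)


def leaf_update_maps(env: EnvironmentState, params: LeafParams, S_w: float):
    """Build the update maps F_i and variable names for the leaf system.

    The state vector is [T_L, g_w, A, C_m] for both pathways; for C4 the
    bundle-sheath concentrations C_s/O_s are explicit functions of
    (A, C_m, T_L) through the quasi-steady-state balances and are derived
    inside the maps (and recoverable via :func:`c4_derived`).
    Temperature-dependent parameters are re-evaluated at the current T_L
    inside every map.  Exposed publicly so independent solution schemes
    (e.g. damped simultaneous iteration) can run on the identical system.
    """
    o_a = env.O_A * 1000.0  # mmol/mol -> μmol/mol
    c_a = env.C_A

    if params.pathway == "C3":
        def o_m_of(x):
            kin = params.at_leaf_temperature(x[0])
            return o_a + 1.25 * (x[2] - kin.R_d) / max(x[1], params.g_w0)

        def f_tl(x):
            return energy.solve_leaf_temperature_coupled(env, x[1], params,
                                                         t_init=x[0])

        def f_gw(x):
            kin = params.at_leaf_temperature(x[0])
            gamma = biochem.c3_compensation_point(
                kin.R_d, kin.V_cmax, kin.K_C, kin.K_O, o_m_of(x), kin.gamma_star)
            return biochem.stomatal_conductance(
                x[2], kin.R_d, gamma, env.VPD, S_w, c_a,
                params.m, params.g_w0, params.VPD_ref)

        def f_a(x):
            kin = params.at_leaf_temperature(x[0])
            j = biochem.electron_transport(env.I_s, kin.J_max, params.theta,
                                           params.alpha, params.f, params.beta)
            a, _, _ = biochem.c3_assimilation(max(x[3], 1e-6), o_m_of(x), j,
                                              kin.V_cmax, kin.K_C, kin.K_O,
                                              kin.gamma_star)
            return a

        def f_cm(x):
            kin = params.at_leaf_temperature(x[0])
            return c_a - 1.6 * (x[2] - kin.R_d) / max(x[1], params.g_w0)

        return [f_tl, f_gw, f_a, f_cm], ["T_L", "g_w", "A", "C_m"]

    # C4: A_r (assimilation excluding respiration) is the gross rate A itself
    def derived(x):
        return c4_derived(x, env, params)

    def f_tl(x):
        return energy.solve_leaf_temperature_coupled(env, x[1], params,
                                                     t_init=x[0])

    def f_gw(x):
        kin = params.at_leaf_temperature(x[0])
        d = derived(x)
        gamma_s = biochem.c4_bundle_sheath_compensation(
            kin.R_d, kin.V_cmax, kin.K_C, kin.K_O, d["O_m"], kin.gamma_star_c4)
        gamma = biochem.c4_compensation_point(gamma_s, kin.K_P, kin.V_pmax,
                                              kin.g_s, kin.R_m)
        return biochem.stomatal_conductance(
            x[2], kin.R_d, gamma, env.VPD, S_w, c_a,
            params.m, params.g_w0, params.VPD_ref)

    def f_a(x):
        kin = params.at_leaf_temperature(x[0])
        j = biochem.electron_transport(env.I_s, kin.J_max, params.theta,
                                       params.alpha, params.f, params.beta)
        d = derived(x)
        a, _, _ = biochem.c4_assimilation(max(d["C_s"], 1e-6), d["O_s"], j,
                                          kin.V_cmax, kin.K_C, kin.K_O,
                                          kin.gamma_star_c4, params.x)
        return a

    def f_cm(x):
        kin = params.at_leaf_temperature(x[0])
        g_w = max(x[1], params.g_w0)
        d = derived(x)
        a = g_w / 1.6
        return (a * c_a + kin.g_s * d["C_s"] - d["V_p"] + kin.R_m) / (a + kin.g_s)

    return [f_tl, f_gw, f_a, f_cm], ["T_L", "g_w", "A", "C_m"]


def c4_derived(x: np.ndarray, env: EnvironmentState,
               params: LeafParams) -> dict:
    """Bundle-sheath quantities implied by the state vector [T_L, g_w, A, C_m].

    V_p from the PEP carboxylation law, C_s/O_s/O_m from the quasi-steady-state
    mesophyll/bundle-sheath balances with A_r = A.
    """
    kin = params.at_leaf_temperature(x[0])
    g_w = max(x[1], params.g_w0)
    a_r, c_m = x[2], x[3]
    v_p = biochem.pep_carboxylation(max(c_m, 0.0), kin.V_pmax, kin.K_P,
                                    params.V_pr)
    c_s = (v_p - a_r + kin.R_s) / kin.g_s + c_m
    o_m = env.O_A * 1000.0 + 1.25 * (a_r - kin.R_m - kin.R_s) / g_w
    o_s = o_m + (a_r - kin.R_s) / (0.047 * kin.g_s)
    return {"V_p": v_p, "C_s": c_s, "O_m": o_m, "O_s": o_s}


def _initial_vector(env: EnvironmentState, params: LeafParams) -> np.ndarray:
    a0 = (5.0 if params.pathway == "C3" else 10.0) if env.I_s > 0 else 0.0
    c0 = (0.8 if params.pathway == "C3" else 0.5) * env.C_A
    return np.array([env.T_a, max(0.05, params.g_w0), a0, c0])


def solve_leaf_state(env: EnvironmentState, params: LeafParams, S_w: float,
                     previous: Optional[LeafState] = None,
                     tol: float = 1e-6, max_outer: int = 40) -> LeafState:
    """Solve the coupled photosynthesis–conductance–gas–temperature system.

    The converged :class:`LeafState` simultaneously satisfies the
    assimilation equations, the quasi-steady-state gas balances, the
    stomatal-conductance relation and the leaf energy balance, each within
    ``tol`` in its native units.  On non-convergence the previous state (or
    the night default) is returned with ``converged=False``.
    """
    maps, names = leaf_update_maps(env, params, S_w)
    n = len(maps)

    if previous is not None:
        fb = np.array([previous.T_L, previous.g_w, previous.A, previous.C_m])
        x0 = fb.copy()
    else:
        ns = night_state(env, params)
        fb = np.array([ns.T_L, ns.g_w, ns.A, ns.C_m])
        x0 = _initial_vector(env, params)

    scales = np.array([300.0, 0.1, 10.0, 100.0])
    # physically admissible ranges; also enable the bracketed level fallback
    # C_m can far exceed C_A on hot leaves where respiration dominates and
    # stomata sit at the residual conductance
    lo = np.array([env.T_a - 50.0, params.g_w0, -20.0, -200.0])
    hi = np.array([env.T_a + 50.0, 3.0, 250.0, env.C_A + 4500.0])
    sys = FixedPointSystem(updates=maps, x0=x0, tol=np.full(n, tol),
                           fallback=fb, max_outer=max_outer, scales=scales,
                           names=names, lo=lo, hi=hi)
    result = nested_root_find(sys)
    return _assemble_state(result, env, params, S_w)


def _assemble_state(result: RootFindResult, env: EnvironmentState,
                    params: LeafParams, S_w: float) -> LeafState:
    x = result.x
    o_a = env.O_A * 1000.0
    t_l, g_w = x[0], max(x[1], params.g_w0)
    kin = params.at_leaf_temperature(t_l)
    j = biochem.electron_transport(env.I_s, kin.J_max, params.theta,
                                   params.alpha, params.f, params.beta)
    j_v = energy.leaf_transpiration(g_w, t_l, env.T_a, env.VPD, env.P)
    resid = dict(zip(["T_L", "g_w", "A", "C_m"], result.residuals))

    if params.pathway == "C3":
        a, c_m = x[2], x[3]
        o_m = o_a + 1.25 * (a - kin.R_d) / g_w
        _, a_c, a_j = biochem.c3_assimilation(c_m, o_m, j, kin.V_cmax,
                                              kin.K_C, kin.K_O, kin.gamma_star)
        gamma = biochem.c3_compensation_point(kin.R_d, kin.V_cmax, kin.K_C,
                                              kin.K_O, o_m, kin.gamma_star)
        return LeafState(A=a, A_c=a_c, A_j=a_j, R_d=kin.R_d, J=j, g_w=g_w,
                         C_m=c_m, O_m=o_m, Gamma=gamma,
                         Gamma_star=kin.gamma_star, T_L=t_l, J_v=j_v,
                         converged=result.converged,
                         iterations=result.iterations, residuals=resid)

    a, c_m = x[2], x[3]
    d = c4_derived(x, env, params)
    c_s, o_m, o_s, v_p = d["C_s"], d["O_m"], d["O_s"], d["V_p"]
    _, a_c, a_j = biochem.c4_assimilation(c_s, o_s, j, kin.V_cmax, kin.K_C,
                                          kin.K_O, kin.gamma_star_c4, params.x)
    gamma_s = biochem.c4_bundle_sheath_compensation(
        kin.R_d, kin.V_cmax, kin.K_C, kin.K_O, o_m, kin.gamma_star_c4)
    gamma = biochem.c4_compensation_point(gamma_s, kin.K_P, kin.V_pmax,
                                          kin.g_s, kin.R_m)
    return LeafState(A=a, A_c=a_c, A_j=a_j, R_d=kin.R_d, J=j, g_w=g_w,
                     C_m=c_m, O_m=o_m, C_s=c_s, O_s=o_s, V_p=v_p,
                     Gamma=gamma, Gamma_s=gamma_s, Gamma_star=kin.gamma_star,
                     R_m=kin.R_m, R_s=kin.R_s, T_L=t_l, J_v=j_v,
                     converged=result.converged, iterations=result.iterations,
                     residuals=resid)
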