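"""Whole-plant nitrogen limitation, diurnal carbon-reserve dynamics, simulation driver.

Carbon bookkeeping (all in g C per plant) follows a source/sink scheme:
available carbon ``C_a`` (photosynthesis; the seed is an initial reserve
endowment) first pays the carbon costs ``C_c`` (maintenance respiration and
exudation), then the growth sink ``C_g``; any surplus flows to the reserve
pool ``C_p`` at rate ``C_r`` (negative ``C_r`` = remobilization).  Reserve
remobilization is capped: at most 95 % of the reserves present at nightfall
may be consumed over the night, and no more than half of the current
reserves may be drawn per day.  During the day, if reserves are projected to
fall below 110 % of the night's carbon need by sunset, allocation to
reserves is prioritized over growth.  When carbon is short, realized growth
``C_h`` drops below its potential ``C_g``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .biochem import EnvironmentState
from .canopy import canopy_assimilation, solar_state
from .errors import ConfigurationError, InvalidInputError, StateCorruptionError
from .params import LeafParams, WaterStressCurve

#: grams of carbon per μmol CO2
G_C_PER_UMOL_CO2 = 12.011e-6
SECONDS_PER_DAY = 86400.0


# ---------------------------------------------------------------------------
# nitrogen limitation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NitrogenState:
    """Plant and leaf nitrogen bookkeeping for the nitrogen-limited rates.

    ``plant_n``/``plant_min``/``plant_opt`` are contents in g; ``leaf_min``/
    ``leaf_opt`` the corresponding leaf contents in g.  ``n_leaf_opt`` maps
    the optimal leaf content to a leaf nitrogen *concentration* (g m⁻²)
    used by the linear rate laws.
    """

    plant_n: float
    plant_min: float = 0.02
    plant_opt: float = 0.10
    leaf_min: float = 0.01
    leaf_opt: float = 0.05
    n_leaf_opt: float = 2.0   # leaf N concentration at optimal supply, g m⁻²


def leaf_nitrogen(plant_n: float, plant_min: float, plant_opt: float,
                  leaf_min: float, leaf_opt: float) -> float:
    """Leaf nitrogen content from total plant nitrogen (three-branch map).

    Below ``plant_min`` the leaf holds its minimum; between the bounds the
    leaf content interpolates linearly from minimum to optimum; above
    ``plant_opt`` leaf content scales proportionally with supply.
    """
    if not (plant_min < plant_opt and leaf_min < leaf_opt):
        raise ConfigurationError("nitrogen bounds must satisfy min < opt")
    if plant_n <= plant_min:
        return leaf_min
    if plant_n < plant_opt:
        frac = (plant_n - plant_min) / (plant_opt - plant_min)
        return (leaf_opt - leaf_min) * frac + leaf_min
    return plant_n * leaf_opt / plant_opt


def n_limited_rates(n_leaf: float, n1: float, n2: float):
    """Nitrogen-limited (J_max, V_cmax) = (n1·N_leaf, n2·N_leaf).

    ``n_leaf`` is the leaf nitrogen concentration (g m⁻²); the slopes are
    calibrated so the optimal concentration reproduces the reference rates.
    """
    if n1 <= 0.0 or n2 <= 0.0:
        raise ConfigurationError("nitrogen proportionality constants must be positive")
    return n1 * n_leaf, n2 * n_leaf


def apply_nitrogen_limitation(params: LeafParams,
                              nitrogen: NitrogenState) -> LeafParams:
    """Return params with J_max25/V_cmax25 replaced by nitrogen-limited values."""
    leaf_n = leaf_nitrogen(nitrogen.plant_n, nitrogen.plant_min,
                           nitrogen.plant_opt, nitrogen.leaf_min,
                           nitrogen.leaf_opt)
    n_conc = nitrogen.n_leaf_opt * leaf_n / nitrogen.leaf_opt
    j_max25, v_cmax25 = n_limited_rates(n_conc, params.n1, params.n2)
    return params.replace(
        J_max=params.J_max.__class__(p25=j_max25, E=params.J_max.E,
                                     D=params.J_max.D, S=params.J_max.S),
        V_cmax=params.V_cmax.__class__(p25=v_cmax25, E=params.V_cmax.E),
    )


# ---------------------------------------------------------------------------
# carbon reserves
# ---------------------------------------------------------------------------

@dataclass
class CarbonPool:
    """Instantaneous carbon fluxes (g d⁻¹) and the reserve pool (g)."""

    C_a: float                   # available carbon from photosynthesis
    C_c: float                   # carbon costs (maintenance, exudation)
    C_g: float                   # potential growth sink
    C_p: float                   # current reserves
    phase: str = "day"           # 'day' | 'night'
    t_s: float = 0.5             # time until sunset, d
    t_n: float = 0.5             # night duration, d
    C_cN: float = 0.0            # estimated carbon needed over the night, g
    C_p_night_start: float = 0.0  # reserves at nightfall, g


@dataclass(frozen=True)
class Allocation:
    C_r: float
    C_h: float
    growth_limited: bool


def reserve_allocation(pool: CarbonPool) -> Allocation:
    """Reserve allocation C_r and realized growth C_h under the reserve rules.

    Surplus: C_r = C_a − C_c − C_g with C_h = C_g.  Deficit: reserves are
    remobilized down to the binding cap — at night at most 95 % of the
    reserves present at nightfall spread over the night
    (C_r ≥ −0.95·C_p(nightfall)/t_n), during the day at most half the current
    reserves per day (C_r ≥ −C_p/2).  During the day, if reserves are
    projected below 110 % of the night's need by sunset
    (C_p + C_r·t_s ≤ 1.1·C_cN), C_r is raised to
    min(C_a − C_c, (1.1·C_cN − C_p)/t_s) and growth yields.  C_h is clipped
    to [0, C_g].
    """
    if pool.C_p < 0.0:
        raise StateCorruptionError(f"negative carbon reserves: {pool.C_p}")
    if min(pool.C_a, pool.C_c, pool.C_g) < 0.0:
        raise InvalidInputError("carbon rates must be non-negative")

    c_r = pool.C_a - pool.C_c - pool.C_g
    if pool.phase == "night":
        cap = -0.95 * pool.C_p_night_start / pool.t_n if pool.t_n > 0.0 else 0.0
    else:
        cap = -pool.C_p / 2.0
    c_r = max(c_r, cap)

    if pool.phase == "day" and pool.t_s > 0.0:
        if pool.C_p + c_r * pool.t_s <= 1.1 * pool.C_cN:
            hoard = min(pool.C_a - pool.C_c,
                        (1.1 * pool.C_cN - pool.C_p) / pool.t_s)
            c_r = max(c_r, hoard)

    c_h = min(max(pool.C_a - c_r - pool.C_c, 0.0), pool.C_g)
    return Allocation(C_r=c_r, C_h=c_h, growth_limited=c_h < pool.C_g - 1e-12)


# ---------------------------------------------------------------------------
# diurnal simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Stand- and plant-level settings for the diurnal simulation.

    Carbon state is tracked per plant in g C.  Leaf area follows structural
    shoot carbon through a fixed specific leaf area, so LAI grows with the
    plant: LAI = sla·(shoot C)·density.
    """

    latitude: float = 42.8
    doy_start: int = 150
    plant_density: float = 8.0        # plants m⁻²
    timestep: float = 0.1             # d
    seed_carbon: float = 0.25         # initial reserve endowment, g C
    initial_structural_c: float = 0.1  # g C
    shoot_fraction: float = 0.6       # share of growth allocated to shoot
    maint_coeff: float = 0.03         # maintenance + exudation, g C (g C)⁻¹ d⁻¹
    rgr: float = 0.25                 # potential relative growth rate, d⁻¹
    biomass_max: float = 40.0         # logistic ceiling for potential growth, g C
    sla: float = 0.05                 # leaf area per g shoot C, m² g⁻¹
    transmittance: float = 0.75
    diffuse_fraction: float = 0.15
    stress_growth_exponent: float = 0.0  # optional S_w transfer onto C_g
    well_watered_psi: float = -1000.0    # hPa, used when no schedule given


@dataclass
class SimulationResult:
    frame: pd.DataFrame
    summary: dict


def run_diurnal_simulation(params: LeafParams, config: SimulationConfig,
                           weather, psi_schedule=None, n_days: float = None,
                           stress_curve: WaterStressCurve = None,
                           nitrogen: Optional[NitrogenState] = None
                           ) -> SimulationResult:
    """Run the coupled shoot model over a weather series.

    Per timestep: solar state → canopy assimilation (day) or zero (night) →
    carbon accounting → reserve allocation → growth.  The carbon mass
    balance (seed + assimilation = costs + growth + reserves) closes
    identically each step; the per-step error is recorded in the output.

    ``weather`` is a :class:`~shootphys.weather.WeatherSeries`;
    ``psi_schedule`` maps time (d) to collar potential (hPa) — if omitted
    the well-watered potential is used throughout.
    """
    curve = stress_curve or WaterStressCurve()
    if nitrogen is not None:
        params = apply_nitrogen_limitation(params, nitrogen)

    frame = weather.frame
    dt = config.timestep
    if n_days is None:
        n_days = float(frame["time"].iloc[-1]) + dt
    n_steps = int(round(n_days / dt))
    if len(frame) < n_steps:
        raise InvalidInputError(
            f"weather series ends at t={frame['time'].iloc[-1]:.2f} d but "
            f"{n_days:.2f} d were requested"
        )

    shoot_c = config.shoot_fraction * config.initial_structural_c
    root_c = (1.0 - config.shoot_fraction) * config.initial_structural_c
    c_p = config.seed_carbon
    c_p_night_start = c_p
    phase_prev = "night"
    assim_cum = costs_cum = growth_cum = transp_cum = 0.0
    n_fail = 0
    prev_canopy = None
    rows = []

    for step in range(n_steps):
        row = frame.iloc[step]
        t = float(row["time"])
        doy = config.doy_start + int(t)
        hour = (t % 1.0) * 24.0
        sol = solar_state(config.latitude, doy, hour, config.transmittance)
        psi_c = float(psi_schedule(t)) if psi_schedule is not None \
            else config.well_watered_psi
        s_w = float(curve(psi_c))
        env = EnvironmentState(T_a=float(row["T_a"]), P=float(row["P"]),
                               I_s=float(row["I_s"]), VPD=float(row["VPD"]),
                               v=float(row["v"]), psi_c=psi_c)

        lai = config.sla * shoot_c * config.plant_density
        phase = "day" if (sol.is_day and env.I_s > 0.0) else "night"
        if phase == "night" and phase_prev == "day":
            c_p_night_start = c_p

        if phase == "day" and lai > 0.0:
            canopy = canopy_assimilation(env, lai, params, s_w,
                                         config.diffuse_fraction, sol.zenith,
                                         previous=prev_canopy)
            prev_canopy = canopy
            for leaf in (canopy.sun, canopy.shade):
                if leaf is not None and not leaf.converged:
                    n_fail += 1
            a_ground = canopy.A_ground
            j_v_ground = canopy.J_v_ground
            g_w_mean = canopy.g_w_mean
            t_l_sun = canopy.sun.T_L if canopy.sun else np.nan
            t_l_shade = canopy.shade.T_L if canopy.shade else np.nan
        else:
            canopy = None
            a_ground = j_v_ground = 0.0
            g_w_mean = params.g_w0
            t_l_sun = t_l_shade = np.nan

        # per-plant carbon source, g C d⁻¹
        c_a = a_ground * G_C_PER_UMOL_CO2 * SECONDS_PER_DAY / config.plant_density
        biomass = shoot_c + root_c
        c_c = config.maint_coeff * biomass
        c_g = config.rgr * biomass * max(1.0 - biomass / config.biomass_max, 0.0)
        if config.stress_growth_exponent > 0.0:
            c_g *= s_w ** config.stress_growth_exponent
        c_cn = c_c * sol.t_n

        pool = CarbonPool(C_a=c_a, C_c=c_c, C_g=c_g, C_p=c_p, phase=phase,
                          t_s=sol.t_s, t_n=sol.t_n, C_cN=c_cn,
                          C_p_night_start=c_p_night_start)
        alloc = reserve_allocation(pool)

        c_p = max(c_p + alloc.C_r * dt, 0.0)
        shoot_c += config.shoot_fraction * alloc.C_h * dt
        root_c += (1.0 - config.shoot_fraction) * alloc.C_h * dt

        costs_paid = c_a - alloc.C_r - alloc.C_h  # = C_c unless starving
        assim_cum += c_a * dt
        costs_cum += costs_paid * dt
        growth_cum += alloc.C_h * dt
        transp_cum += j_v_ground * SECONDS_PER_DAY * dt / config.plant_density
        balance_err = (config.seed_carbon + assim_cum - costs_cum
                       - growth_cum - c_p)

        rows.append({
            "time": t, "doy": doy, "hour": hour, "phase": phase,
            "I_s": env.I_s, "T_a": env.T_a, "VPD": env.VPD, "v": env.v,
            "psi_c": psi_c, "S_w": s_w, "LAI": lai,
            "A_ground": a_ground, "J_v_ground": j_v_ground,
            "g_w_mean": g_w_mean, "T_L_sun": t_l_sun, "T_L_shade": t_l_shade,
            "C_a": c_a, "C_c": c_c, "C_g": c_g, "C_r": alloc.C_r,
            "C_h": alloc.C_h, "C_p": c_p, "shoot_c": shoot_c,
            "root_c": root_c, "growth_limited": alloc.growth_limited,
            "mass_balance_error": balance_err,
        })
        phase_prev = phase

    out = pd.DataFrame(rows)
    summary = {
        "cumulative_assimilation_g": assim_cum,
        "cumulative_transpiration_mol": transp_cum,
        "cumulative_growth_g": growth_cum,
        "final_reserves_g": c_p,
        "final_shoot_c_g": shoot_c,
        "final_root_c_g": root_c,
        "n_steps": n_steps,
        "n_nonconverged": n_fail,
        "max_mass_balance_error": float(np.max(np.abs(out["mass_balance_error"])))
        if len(out) else 0.0,
    }
    return SimulationResult(frame=out, summary=summary)
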