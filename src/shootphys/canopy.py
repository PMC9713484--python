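"""Solar geometry, clear-sky irradiance and sun/shade canopy scaling.

The canopy is split each timestep into sunlit and shaded leaf-area
fractions (two-big-leaf scheme).  With a spherical leaf-angle distribution
the black-leaf beam extinction coefficient is k_b = 0.5/cos(θ_z) and the
sunlit leaf area index is LAI_sun = (1 − e^{−k_b·LAI})/k_b.  Sunlit leaves
receive the beam flux k_b·I_beam plus the mean intercepted diffuse flux;
shaded leaves receive the diffuse flux only.  The coupled leaf solver is
then run once per fraction and results are weighted by leaf area.

Solar position uses the standard declination/hour-angle construction with
Cooper's declination approximation (23.45° amplitude).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import acos, cos, exp, pi, radians, sin
from typing import Optional

from .biochem import EnvironmentState, LeafState
from .errors import InvalidInputError
from .params import LeafParams
from .solver import solve_leaf_state

#: Solar constant, W m⁻².
SOLAR_CONSTANT = 1361.0


@dataclass(frozen=True)
class SolarState:
    """Solar geometry and timing quantities for one instant."""

    latitude: float      # deg
    doy: int
    hour: float          # solar time, h
    declination: float   # rad
    zenith: float        # rad
    I_s: float           # clear-sky global irradiance, W m⁻²
    day_length: float    # h
    t_s: float           # time until sunset, d
    t_n: float           # night duration, d

    @property
    def is_day(self) -> bool:
        return self.zenith < pi / 2.0


@dataclass
class CanopyState:
    """Two-big-leaf canopy partition and per-fraction leaf solutions."""

    LAI: float
    LAI_sun: float
    LAI_shade: float
    I_sun: float            # per sunlit leaf area, W m⁻²
    I_shade: float          # per shaded leaf area, W m⁻²
    absorbed_sun: float     # per ground area, W m⁻²
    absorbed_shade: float   # per ground area, W m⁻²
    sun: Optional[LeafState] = None
    shade: Optional[LeafState] = None
    A_ground: float = 0.0       # gross assimilation, μmol m⁻²(ground) s⁻¹
    A_net_ground: float = 0.0   # net of dark respiration
    J_v_ground: float = 0.0     # transpiration, mol m⁻²(ground) s⁻¹
    g_w_mean: float = 0.0       # leaf-area-weighted conductance


def solar_declination(doy: int) -> float:
    """Solar declination in radians (Cooper's approximation)."""
    return radians(23.45) * sin(2.0 * pi * (284 + doy) / 365.0)


def solar_position(lat: float, doy: int, hour: float):
    """(declination, zenith) in radians for solar time ``hour``."""
    if abs(lat) > 90.0:
        raise InvalidInputError("latitude must be within ±90°")
    decl = solar_declination(doy)
    phi = radians(lat)
    h_angle = radians(15.0 * (hour - 12.0))
    cos_z = sin(phi) * sin(decl) + cos(phi) * cos(decl) * cos(h_angle)
    return decl, acos(min(max(cos_z, -1.0), 1.0))


def day_length(lat: float, doy: int) -> float:
    """Day length in hours, (2/15)·arccos(−tan φ tan δ) in degrees; clipped
    to 0/24 h in the polar cases."""
    if abs(lat) > 90.0:
        raise InvalidInputError("latitude must be within ±90°")
    decl = solar_declination(doy)
    phi = radians(lat)
    cos_h0 = -sin(phi) * sin(decl) / max(cos(phi) * cos(decl), 1e-12)
    cos_h0 = min(max(cos_h0, -1.0), 1.0)
    return 2.0 / 15.0 * (acos(cos_h0) * 180.0 / pi)


def solar_state(lat: float, doy: int, hour: float,
                transmittance: float = 0.75) -> SolarState:
    """Full solar state including timing (day length, time to sunset, night)."""
    decl, zen = solar_position(lat, doy, hour)
    dl = day_length(lat, doy)
    sunrise = 12.0 - dl / 2.0
    sunset = 12.0 + dl / 2.0
    t_s = max(sunset - hour, 0.0) / 24.0 if sunrise <= hour <= sunset else 0.0
    return SolarState(latitude=lat, doy=doy, hour=hour, declination=decl,
                      zenith=zen, I_s=clear_sky_irradiance(zen, doy, transmittance),
                      day_length=dl, t_s=t_s, t_n=(24.0 - dl) / 24.0)


def clear_sky_irradiance(zenith: float, doy: int,
                         transmittance: float = 0.75) -> float:
    """Clear-sky global irradiance on a horizontal plane, W m⁻².

    Solar constant × orbital eccentricity factor × τ^(1/cos θ_z) × cos θ_z,
    zero when the sun is below the horizon.
    """
    if not 0.0 < transmittance <= 1.0:
        raise InvalidInputError("transmittance must be in (0, 1]")
    cos_z = cos(zenith)
    if cos_z <= 0.0:
        return 0.0
    ecc = 1.0 + 0.033 * cos(2.0 * pi * doy / 365.0)
    return SOLAR_CONSTANT * ecc * transmittance ** (1.0 / cos_z) * cos_z


def sun_shade_partition(LAI: float, zenith: float, I_beam: float,
                        I_diffuse: float, k_d: float = 0.7) -> CanopyState:
    """Split the canopy into sunlit/shaded fractions and assign irradiances.

    LAI_sun = (1 − e^{−k_b·LAI})/k_b with k_b = 0.5/cos θ_z.  The beam is
    intercepted entirely by sunlit leaves (k_b·I_beam per sunlit leaf area);
    intercepted diffuse light, I_diffuse·(1 − e^{−k_d·LAI}), is shared
    uniformly per unit leaf area over both fractions.  Total absorbed light
    never exceeds the incident flux on the ground area.
    """
    if LAI < 0.0:
        raise InvalidInputError("LAI must be non-negative")
    if LAI == 0.0:
        return CanopyState(LAI=0.0, LAI_sun=0.0, LAI_shade=0.0, I_sun=0.0,
                           I_shade=0.0, absorbed_sun=0.0, absorbed_shade=0.0)
    cos_z = cos(zenith)
    if cos_z <= 1e-6:
        # sun at/below the horizon: everything is shaded
        diffuse_per_leaf = (I_diffuse * (1.0 - exp(-k_d * LAI)) / LAI
                            if I_diffuse > 0.0 else 0.0)
        return CanopyState(LAI=LAI, LAI_sun=0.0, LAI_shade=LAI,
                           I_sun=0.0, I_shade=diffuse_per_leaf,
                           absorbed_sun=0.0,
                           absorbed_shade=diffuse_per_leaf * LAI)
    k_b = 0.5 / cos_z
    lai_sun = (1.0 - exp(-min(k_b * LAI, 700.0))) / k_b
    lai_shade = LAI - lai_sun
    diffuse_per_leaf = I_diffuse * (1.0 - exp(-k_d * LAI)) / LAI
    i_sun = k_b * I_beam + diffuse_per_leaf
    i_shade = diffuse_per_leaf
    return CanopyState(LAI=LAI, LAI_sun=lai_sun, LAI_shade=lai_shade,
                       I_sun=i_sun, I_shade=i_shade,
                       absorbed_sun=lai_sun * i_sun,
                       absorbed_shade=lai_shade * i_shade)


def canopy_assimilation(env: EnvironmentState, LAI: float, params: LeafParams,
                        S_w: float, diffuse_fraction: float = 0.15,
                        zenith: float = 0.0,
                        previous: Optional[CanopyState] = None) -> CanopyState:
    """Canopy-scale assimilation and transpiration per unit ground area.

    The incident irradiance ``env.I_s`` is split into beam and diffuse parts,
    the two-big-leaf partition is formed, and the coupled leaf solver is run
    once for the sunlit and once for the shaded fraction; totals are leaf-area
    weighted.  ``previous`` supplies warm starts and the non-convergence
    fallback per fraction.
    """
    i_beam = env.I_s * (1.0 - diffuse_fraction)
    i_diff = env.I_s * diffuse_fraction
    state = sun_shade_partition(LAI, zenith, i_beam, i_diff)
    if LAI == 0.0:
        return state

    prev_sun = previous.sun if previous is not None else None
    prev_shade = previous.shade if previous is not None else None
    if state.LAI_sun > 0.0:
        env_sun = replace(env, I_s=state.I_sun)
        state.sun = solve_leaf_state(env_sun, params, S_w, previous=prev_sun)
    env_shade = replace(env, I_s=state.I_shade)
    state.shade = solve_leaf_state(env_shade, params, S_w, previous=prev_shade)

    a = a_net = j_v = g_sum = 0.0
    for leaf, lai in ((state.sun, state.LAI_sun), (state.shade, state.LAI_shade)):
        if leaf is None or lai == 0.0:
            continue
        a += leaf.A * lai
        a_net += (leaf.A - leaf.R_d) * lai
        j_v += leaf.J_v * lai
        g_sum += leaf.g_w * lai
    state.A_ground = a
    state.A_net_ground = a_net
    state.J_v_ground = j_v
    state.g_w_mean = g_sum / LAI
    return state
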