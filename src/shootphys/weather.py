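"""Weather forcing, drought schedules, and the synthetic generators.

The synthetic weather generator emulates a clear-sky field site: a
sinusoidal diurnal air-temperature cycle peaking mid-afternoon, clear-sky
irradiance from the solar-geometry model, and a vapor pressure deficit that
tracks temperature.  A terminal-drought schedule holds the collar water
potential at a well-watered value until an onset day and then declines
linearly, standing in for a root/soil hydraulic model.

All tabular I/O is plain CSV with a documented header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .canopy import solar_position, clear_sky_irradiance
from .errors import InvalidInputError, ParseError

WEATHER_COLUMNS = ("time", "T_a", "I_s", "VPD", "v", "P")
_RANGES = {
    "T_a": (230.0, 330.0),   # K
    "I_s": (0.0, 1500.0),    # W m⁻²
    "VPD": (0.0, 20.0),      # kPa
    "v": (0.0, 50.0),        # m s⁻¹ (exclusive lower bound)
    "P": (3.0e4, 1.2e5),     # Pa
}


@dataclass
class WeatherSeries:
    """Uniformly sampled weather forcing.

    Columns: time (d, fractional), T_a (K), I_s (W m⁻²), VPD (kPa),
    v (m s⁻¹), P (Pa).  Timestamps must be strictly increasing with a
    uniform step.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        f = self.frame
        missing = [c for c in WEATHER_COLUMNS if c not in f.columns]
        if missing:
            raise ParseError(f"weather series missing column(s): {', '.join(missing)}")
        t = f["time"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ParseError("weather series needs at least two rows")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ParseError("weather timestamps must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ParseError("weather timestamps must be uniformly spaced")
        for col, (lo, hi) in _RANGES.items():
            vals = f[col].to_numpy(dtype=float)
            bad = np.flatnonzero((vals < lo) | (vals > hi))
            if col == "v":
                bad = np.flatnonzero((vals <= lo) | (vals > hi))
            if bad.size:
                raise ParseError(
                    f"weather column {col!r} out of physical range "
                    f"[{lo}, {hi}] at row {int(bad[0])} "
                    f"(value {vals[bad[0]]!r})"
                )

    @property
    def timestep(self) -> float:
        t = self.frame["time"].to_numpy(dtype=float)
        return float(t[1] - t[0])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WeatherSeries":
        return read_weather(path)


@dataclass(frozen=True)
class DroughtSchedule:
    """Piecewise-linear collar-water-potential schedule (hPa, non-positive)."""

    times: tuple
    psi: tuple

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.psi, dtype=float)
        if t.shape != p.shape or t.ndim != 1 or t.size < 2:
            raise InvalidInputError("schedule needs matching 1-d time/psi arrays")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("schedule times must be strictly increasing")
        if np.any(p > 0):
            raise InvalidInputError("collar potential must be non-positive (hPa)")

    def __call__(self, t):
        out = np.interp(t, self.times, self.psi)
        return float(out) if np.ndim(t) == 0 else out


def synthetic_weather(lat: float, n_days: int, timestep: float = 0.1,
                      t_mean: float = 298.15, t_amplitude: float = 6.0,
                      transmittance: float = 0.75, vpd_max: float = 2.0,
                      wind: float = 1.5, pressure: float = 101325.0,
                      doy_start: int = 150, seed: int = 0,
                      noise_sd: float = 0.0) -> WeatherSeries:
    """Generate a sinusoidal clear-sky weather series.

    Air temperature follows T_a = T_mean + T_amp·cos(2π(h−15)/24), peaking
    at 15:00 solar time, so the range is exactly T_mean ± T_amp.  Irradiance
    comes from the clear-sky model at (lat, doy, hour).  VPD scales linearly
    with the temperature excursion up to ``vpd_max``.  Optional Gaussian
    noise (``noise_sd`` K on T_a, proportionally on VPD) is reproducible for
    a fixed ``seed``.
    """
    if timestep <= 0 or abs(round(1.0 / timestep) - 1.0 / timestep) > 1e-9:
        raise InvalidInputError("timestep must be positive and divide one day")
    rng = np.random.default_rng(seed)
    n = int(round(n_days / timestep))
    t = np.arange(n) * timestep
    hour = (t % 1.0) * 24.0
    doy = doy_start + t.astype(int)

    t_a = t_mean + t_amplitude * np.cos(2.0 * np.pi * (hour - 15.0) / 24.0)
    i_s = np.array([
        clear_sky_irradiance(solar_position(lat, int(d), float(h))[1], int(d),
                             transmittance)
        for d, h in zip(doy, hour)
    ])
    frac = (t_a - (t_mean - t_amplitude)) / (2.0 * t_amplitude)
    vpd = vpd_max * (0.15 + 0.85 * frac)
    if noise_sd > 0.0:
        t_a = t_a + rng.normal(0.0, noise_sd, n)
        vpd = np.maximum(vpd + rng.normal(0.0, noise_sd * 0.1, n), 0.0)

    frame = pd.DataFrame({
        "time": t, "T_a": t_a, "I_s": i_s, "VPD": vpd,
        "v": np.full(n, wind), "P": np.full(n, pressure),
    })
    return WeatherSeries(frame)


def terminal_drought_schedule(onset_day: float, end_psi: float, n_days: float,
                              well_watered_psi: float = -1000.0
                              ) -> DroughtSchedule:
    """Terminal drought: well-watered until onset, then linear decline.

    The collar potential holds at ``well_watered_psi`` before ``onset_day``
    and declines linearly to ``end_psi`` at ``n_days``.
    """
    if onset_day >= n_days:
        raise InvalidInputError("drought onset must precede the end of the run")
    return DroughtSchedule(times=(0.0, float(onset_day), float(n_days)),
                           psi=(well_watered_psi, well_watered_psi,
                                float(end_psi)))


def read_weather(path) -> WeatherSeries:
    """Read a weather CSV, reporting schema violations with row numbers."""
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse weather file {path}: {exc}") from exc
    return WeatherSeries(frame)


def write_timeseries(path, frame) -> None:
    """Write any tidy time-series DataFrame (weather or simulation output)."""
    if isinstance(frame, WeatherSeries):
        frame = frame.frame
    frame.to_csv(path, index=False)
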