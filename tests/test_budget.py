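"""Nitrogen limitation, reserve allocation rules, and the diurnal simulation."""

import numpy as np
import pytest

from shootphys.budget import (CarbonPool, NitrogenState, SimulationConfig,
                              apply_nitrogen_limitation, leaf_nitrogen,
                              n_limited_rates, reserve_allocation,
                              run_diurnal_simulation)
from shootphys.errors import (ConfigurationError, InvalidInputError,
                              StateCorruptionError)
from shootphys.params import LeafParams
from shootphys.weather import synthetic_weather, terminal_drought_schedule


class TestLeafNitrogen:
    BOUNDS = dict(plant_min=0.02, plant_opt=0.10, leaf_min=0.01, leaf_opt=0.05)

    def test_at_minimum_supply(self):
        assert leaf_nitrogen(0.02, **self.BOUNDS) == pytest.approx(0.01)

    def test_at_optimal_supply_both_branches_agree(self):
        below = leaf_nitrogen(0.10 - 1e-12, **self.BOUNDS)
        above = leaf_nitrogen(0.10, **self.BOUNDS)
        assert below == pytest.approx(0.05, abs=1e-9)
        assert above == pytest.approx(0.05, abs=1e-9)

    def test_midpoint_linearity(self):
        assert leaf_nitrogen(0.06, **self.BOUNDS) == pytest.approx(0.03)

    def test_luxury_supply_scales_proportionally(self):
        assert leaf_nitrogen(0.20, **self.BOUNDS) == pytest.approx(0.10)

    def test_continuity_at_both_breakpoints(self):
        for b in (0.02, 0.10):
            lo = leaf_nitrogen(b - 1e-9, **self.BOUNDS)
            hi = leaf_nitrogen(b + 1e-9, **self.BOUNDS)
            assert abs(hi - lo) < 1e-6

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            leaf_nitrogen(0.05, 0.1, 0.02, 0.01, 0.05)


class TestNitrogenLimitedRates:
    def test_zero_nitrogen_zero_rates(self):
        assert n_limited_rates(0.0, 149.8, 24.5) == (0.0, 0.0)

    def test_linearity(self):
        j1, v1 = n_limited_rates(1.0, 149.8, 24.5)
        j2, v2 = n_limited_rates(2.0, 149.8, 24.5)
        assert j2 == pytest.approx(2.0 * j1)
        assert v2 == pytest.approx(2.0 * v1)

    def test_calibration_identity_reproduces_reference_rates(self):
        # optimal leaf N concentration (2.0 g m^-2) must reproduce the
        # reference J_max25 and V_cmax25
        j_max, v_cmax = n_limited_rates(2.0, 149.8, 24.5)
        assert j_max == pytest.approx(299.6)
        assert v_cmax == pytest.approx(49.0)

    def test_applied_to_params_at_optimal_supply(self):
        params = LeafParams()
        limited = apply_nitrogen_limitation(
            params, NitrogenState(plant_n=0.10))
        assert limited.J_max.p25 == pytest.approx(299.6)
        assert limited.V_cmax.p25 == pytest.approx(49.0)
        deficient = apply_nitrogen_limitation(
            params, NitrogenState(plant_n=0.04))
        assert deficient.J_max.p25 < params.J_max.p25


class TestReserveAllocation:
    def test_surplus_day(self):
        alloc = reserve_allocation(CarbonPool(C_a=10.0, C_c=3.0, C_g=5.0,
                                              C_p=50.0, phase="day",
                                              t_s=0.3, C_cN=0.5))
        assert alloc.C_r == pytest.approx(2.0)
        assert alloc.C_h == pytest.approx(5.0)
        assert not alloc.growth_limited

    def test_exact_balance(self):
        alloc = reserve_allocation(CarbonPool(C_a=8.0, C_c=3.0, C_g=5.0,
                                              C_p=50.0, phase="day",
                                              t_s=0.3, C_cN=0.1))
        assert alloc.C_r == pytest.approx(0.0)
        assert alloc.C_h == pytest.approx(5.0)

    def test_night_cap_binds_at_95_percent(self):
        # huge deficit: remobilization capped at 0.95·C_p/t_n = 19 g/d
        pool = CarbonPool(C_a=0.0, C_c=4.0, C_g=30.0, C_p=10.0,
                          phase="night", t_n=0.5, C_p_night_start=10.0)
        alloc = reserve_allocation(pool)
        assert alloc.C_r == pytest.approx(-19.0)
        assert alloc.growth_limited

    def test_night_cap_leaves_five_percent_by_dawn(self):
        c_p = 10.0
        t_n, dt = 0.5, 0.05
        c_p_start = c_p
        for _ in range(int(t_n / dt)):
            pool = CarbonPool(C_a=0.0, C_c=4.0, C_g=30.0, C_p=c_p,
                              phase="night", t_n=t_n,
                              C_p_night_start=c_p_start)
            c_p += reserve_allocation(pool).C_r * dt
        assert c_p == pytest.approx(0.05 * c_p_start, abs=1e-12)

    def test_day_half_reserve_cap(self):
        pool = CarbonPool(C_a=0.0, C_c=1.0, C_g=30.0, C_p=10.0, phase="day",
                          t_s=0.4, C_cN=0.0)
        alloc = reserve_allocation(pool)
        assert alloc.C_r == pytest.approx(-5.0)

    def test_daytime_hoarding_rule_preserves_night_need(self):
        # projected reserves at sunset fall below 110% of the night need,
        # so allocation to reserves pre-empts growth
        pool = CarbonPool(C_a=6.0, C_c=2.0, C_g=5.0, C_p=0.5, phase="day",
                          t_s=0.25, C_cN=1.0)
        alloc = reserve_allocation(pool)
        expected_cr = min(6.0 - 2.0, (1.1 * 1.0 - 0.5) / 0.25)
        assert alloc.C_r == pytest.approx(expected_cr)
        assert alloc.C_h < 5.0
        # the raised C_r indeed secures 110% of the night need by sunset
        assert pool.C_p + alloc.C_r * pool.t_s >= 1.1 * pool.C_cN - 1e-12

    def test_growth_reduction_when_short(self):
        pool = CarbonPool(C_a=2.0, C_c=1.0, C_g=5.0, C_p=4.0, phase="day",
                          t_s=0.3, C_cN=0.0)
        alloc = reserve_allocation(pool)
        # remobilize down to the half-per-day cap, growth takes the rest
        assert alloc.C_r == pytest.approx(-2.0)
        assert alloc.C_h == pytest.approx(2.0 - alloc.C_r - 1.0)
        assert alloc.growth_limited

    def test_negative_reserves_rejected(self):
        with pytest.raises(StateCorruptionError):
            reserve_allocation(CarbonPool(C_a=1.0, C_c=1.0, C_g=1.0,
                                          C_p=-0.1))

    def test_negative_rates_rejected(self):
        with pytest.raises(InvalidInputError):
            reserve_allocation(CarbonPool(C_a=-1.0, C_c=1.0, C_g=1.0,
                                          C_p=1.0))


@pytest.fixture(scope="module")
def short_run():
    params = LeafParams()
    config = SimulationConfig()
    weather = synthetic_weather(config.latitude, 4, config.timestep, seed=7)
    return run_diurnal_simulation(params, config, weather, n_days=4)


class TestDiurnalSimulation:
    def test_mass_balance_closes_each_step(self, short_run):
        assert short_run.summary["max_mass_balance_error"] < 1e-8

    def test_day_night_structure(self, short_run):
        frame = short_run.frame
        night = frame[frame["phase"] == "night"]
        day = frame[frame["phase"] == "day"]
        assert len(night) and len(day)
        assert (night["A_ground"] == 0.0).all()
        assert (day["I_s"] > 0.0).all()

    def test_ample_conditions_growth_unlimited_at_night(self, short_run):
        night = short_run.frame[short_run.frame["phase"] == "night"]
        assert (np.isclose(night["C_h"], night["C_g"])).all()

    def test_reserves_deplete_without_light(self):
        params = LeafParams()
        config = SimulationConfig()
        weather = synthetic_weather(config.latitude, 3, config.timestep,
                                    seed=3)
        dark = weather.frame.assign(I_s=0.0)
        result = run_diurnal_simulation(params, config,
                                        type(weather)(dark), n_days=3)
        c_p = result.frame["C_p"].to_numpy()
        assert np.all(np.diff(c_p) <= 1e-12)
        assert c_p[-1] < config.seed_carbon

    def test_drought_reduces_cumulative_assimilation(self):
        params = LeafParams()
        config = SimulationConfig()
        weather = synthetic_weather(config.latitude, 6, config.timestep,
                                    seed=11)
        wet = run_diurnal_simulation(params, config, weather, n_days=6)
        schedule = terminal_drought_schedule(1.0, -12000.0, 6.0)
        dry = run_diurnal_simulation(params, config, weather,
                                     psi_schedule=schedule, n_days=6)
        assert dry.summary["cumulative_assimilation_g"] < \
            wet.summary["cumulative_assimilation_g"]
        assert (dry.frame["S_w"] < 1.0).any()

    def test_missing_weather_rows_reported(self):
        params = LeafParams()
        config = SimulationConfig()
        weather = synthetic_weather(config.latitude, 2, config.timestep,
                                    seed=1)
        with pytest.raises(InvalidInputError, match="weather"):
            run_diurnal_simulation(params, config, weather, n_days=10)

    def test_growth_reduced_when_photosynthesis_cannot_cover_demand(self):
        # darkness with a small reserve: growth must fall below potential
        params = LeafParams()
        config = SimulationConfig(seed_carbon=0.05, initial_structural_c=1.0)
        weather = synthetic_weather(config.latitude, 2, config.timestep,
                                    seed=5)
        dark = weather.frame.assign(I_s=0.0)
        result = run_diurnal_simulation(params, config,
                                        type(weather)(dark), n_days=2)
        assert result.frame["growth_limited"].any()
        limited = result.frame[result.frame["growth_limited"]]
        assert (limited["C_h"] < limited["C_g"] - 1e-12).all()
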