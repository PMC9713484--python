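"""Assimilation laws, gas steady states, stomatal conductance, compensation points."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from shootphys.biochem import (c3_assimilation, c3_compensation_point,
                               c3_gas_steady_state, c4_assimilation,
                               c4_bundle_sheath_compensation,
                               c4_compensation_point, c4_gas_steady_state,
                               compensation_points, electron_transport,
                               pep_carboxylation, stomatal_conductance)
from shootphys.errors import ConfigurationError, InvalidInputError

# representative 25 °C kinetics (tabulated values, O-side in μmol/mol)
KC, KO, GSTAR = 485.0, 146000.0, 38.6
VCMAX, JMAX = 49.0, 299.6
OA = 209460.0


class TestElectronTransport:
    def test_dark_gives_zero(self):
        assert electron_transport(0.0, JMAX, 0.7, 0.85, 0.15, 2.1) == 0.0

    def test_saturates_at_jmax(self):
        j = electron_transport(1e7, JMAX, 0.7, 0.85, 0.15, 2.1)
        assert j == pytest.approx(JMAX, rel=1e-3)
        assert j <= JMAX

    def test_quadratic_root_when_i2_equals_jmax(self):
        # choose I_s so that I2 = β·I_s·α(1−f)/2 equals J_max exactly
        theta = 0.7
        i_s = JMAX * 2.0 / (2.1 * 0.85 * (1.0 - 0.15))
        expected = JMAX * (2.0 - math.sqrt(4.0 - 4.0 * theta)) / (2.0 * theta)
        assert electron_transport(i_s, JMAX, theta, 0.85, 0.15, 2.1) == \
            pytest.approx(expected, rel=1e-12)

    def test_bounded_by_light_and_capacity(self):
        for i_s in np.linspace(0.0, 1500.0, 31):
            i2 = 2.1 * i_s * 0.85 * (1.0 - 0.15) / 2.0
            j = electron_transport(i_s, JMAX, 0.7, 0.85, 0.15, 2.1)
            assert j <= min(i2, JMAX) + 1e-9

    def test_invalid_curvature_rejected(self):
        with pytest.raises(ConfigurationError):
            electron_transport(100.0, JMAX, 1.2, 0.85, 0.15, 2.1)


class TestC3Assimilation:
    def test_compensation_point_zeroes_both_rates(self):
        a, a_c, a_j = c3_assimilation(GSTAR, OA, 150.0, VCMAX, KC, KO, GSTAR)
        assert a == a_c == a_j == 0.0

    def test_rubisco_limited_value_at_saturating_light(self):
        c_m = 242.9
        expected_ac = VCMAX * (c_m - GSTAR) / (c_m + KC * (1.0 + OA / KO))
        a, a_c, _ = c3_assimilation(c_m, OA, 1e4, VCMAX, KC, KO, GSTAR)
        assert a_c == pytest.approx(expected_ac, rel=1e-12)
        assert a == a_c  # saturating J makes the carbon-limited rate bind

    def test_no_light_no_assimilation(self):
        a, _, a_j = c3_assimilation(300.0, OA, 0.0, VCMAX, KC, KO, GSTAR)
        assert a_j == 0.0
        assert a == 0.0

    def test_min_law(self):
        for c_m in np.linspace(50.0, 600.0, 12):
            for j in (20.0, 100.0, 250.0):
                a, a_c, a_j = c3_assimilation(c_m, OA, j, VCMAX, KC, KO, GSTAR)
                assert a <= a_c + 1e-12 and a <= a_j + 1e-12

    def test_limiting_state_flips_once_along_light_transect(self):
        c_m = 250.0
        flags = []
        for i_s in np.linspace(1.0, 1200.0, 200):
            j = electron_transport(i_s, JMAX, 0.7, 0.85, 0.15, 2.1)
            _, a_c, a_j = c3_assimilation(c_m, OA, j, VCMAX, KC, KO, GSTAR)
            flags.append(a_c < a_j)  # carbon-limited?
        transitions = sum(f1 != f0 for f0, f1 in zip(flags, flags[1:]))
        assert transitions == 1
        assert not flags[0] and flags[-1]


class TestPEPCarboxylation:
    def test_zero_co2_gives_zero(self):
        assert pep_carboxylation(0.0, 119.2, 40.0, 80.0) == 0.0

    def test_half_saturation(self):
        assert pep_carboxylation(40.0, 119.2, 40.0, 80.0) == pytest.approx(59.6)

    def test_regeneration_cap_in_the_limit(self):
        assert pep_carboxylation(1e9, 119.2, 40.0, 80.0) == pytest.approx(80.0)


class TestC4Assimilation:
    GSTAR_C4 = 0.5 / 2862.0

    def test_shared_numerator_vanishes(self):
        o_s = 210000.0
        c_s = self.GSTAR_C4 * o_s
        a, a_c, a_j = c4_assimilation(c_s, o_s, 200.0, VCMAX, KC, KO,
                                      self.GSTAR_C4, 0.4)
        assert a == a_c == a_j == 0.0

    def test_full_partitioning_kills_light_limited_rate(self):
        a, _, a_j = c4_assimilation(1000.0, 210000.0, 200.0, VCMAX, KC, KO,
                                    self.GSTAR_C4, 1.0)
        assert a_j == 0.0

    def test_value_against_independent_evaluation(self):
        c_s, o_s, j, x = 1500.0, 210000.0, 200.0, 0.4
        num = c_s - self.GSTAR_C4 * o_s
        ac = num * VCMAX / (c_s + KC * (1.0 + o_s / KO))
        aj = num * (1.0 - x) * j / (3.0 * c_s + 7.0 * self.GSTAR_C4 * o_s)
        a, a_c, a_j = c4_assimilation(c_s, o_s, j, VCMAX, KC, KO,
                                      self.GSTAR_C4, x)
        assert a_c == pytest.approx(ac, rel=1e-12)
        assert a_j == pytest.approx(aj, rel=1e-12)
        assert a == min(ac, aj)


PREF = 8.31446 * 298.15 / (101325.0 * 0.001)  # ODE prefactor R·T_a/(P·d_L)


class TestC3GasSteadyState:
    def test_no_net_flux_recovers_ambient(self):
        c_m, o_m = c3_gas_steady_state(0.2, 1.95, 1.95, 402.9, OA)
        assert c_m == pytest.approx(402.9)
        assert o_m == pytest.approx(OA)

    def test_hand_evaluated_drawdown(self):
        c_m, _ = c3_gas_steady_state(0.2, 21.95, 1.95, 402.9, OA)
        assert c_m == pytest.approx(242.9, rel=1e-12)

    def test_zero_conductance_rejected(self):
        with pytest.raises(InvalidInputError):
            c3_gas_steady_state(0.0, 10.0, 1.0, 402.9, OA)

    def test_output_zeroes_the_gas_odes(self):
        g_w, a, r_d, c_a = 0.17, 18.0, 1.95, 402.9
        c_m, o_m = c3_gas_steady_state(g_w, a, r_d, c_a, OA)
        dcm = PREF * (g_w / 1.6 * (c_a - c_m) - a + r_d)
        dom = PREF * (g_w / 1.25 * (OA - o_m) + a - r_d)
        assert abs(dcm) < 1e-9 and abs(dom) < 1e-9

    def test_ode_integration_reaches_the_same_fixed_point(self):
        g_w, a, r_d, c_a = 0.23, 15.0, 1.95, 402.9

        def rhs(_, y):
            c_m, o_m = y
            return [PREF * (g_w / 1.6 * (c_a - c_m) - a + r_d),
                    PREF * (g_w / 1.25 * (OA - o_m) + a - r_d)]

        sol = solve_ivp(rhs, (0.0, 120.0), [c_a, OA], rtol=1e-12, atol=1e-10)
        c_m, o_m = c3_gas_steady_state(g_w, a, r_d, c_a, OA)
        assert sol.y[0, -1] == pytest.approx(c_m, rel=1e-6)
        assert sol.y[1, -1] == pytest.approx(o_m, rel=1e-6)


class TestC4GasSteadyState:
    def test_all_fluxes_zero_recovers_ambient_everywhere(self):
        c_m, c_s, o_m, o_s = c4_gas_steady_state(0.2, 0.003, 0.0, 0.0, 0.0,
                                                 0.0, 402.9, OA)
        assert c_m == pytest.approx(402.9)
        assert c_s == pytest.approx(c_m)
        assert o_m == pytest.approx(OA)
        assert o_s == pytest.approx(o_m)

    def test_solution_zeroes_all_four_odes(self):
        g_w, g_s = 0.25, 0.00287
        a_r, v_p, r_m, r_s = 30.0, 45.0, 0.975, 0.975
        c_m, c_s, o_m, o_s = c4_gas_steady_state(g_w, g_s, a_r, v_p, r_m,
                                                 r_s, 402.9, OA)
        d = [
            g_w / 1.6 * (402.9 - c_m) + g_s * (c_s - c_m) - v_p + r_m,
            v_p - a_r - g_s * (c_s - c_m) + r_s,
            g_w / 1.25 * (OA - o_m) + 0.047 * g_s * (o_s - o_m) - r_m,
            a_r - r_s - 0.047 * g_s * (o_s - o_m),
        ]
        for resid in d:
            assert abs(PREF * resid) < 1e-9

    def test_ode_integration_oracle(self):
        g_w, g_s = 0.18, 0.004
        a_r, v_p, r_m, r_s = 22.0, 35.0, 1.2, 0.8

        def rhs(_, y):
            c_m, c_s, o_m, o_s = y
            return [
                PREF * (g_w / 1.6 * (402.9 - c_m) + g_s * (c_s - c_m)
                        - v_p + r_m),
                PREF * (v_p - a_r - g_s * (c_s - c_m) + r_s),
                PREF * (g_w / 1.25 * (OA - o_m)
                        + 0.047 * g_s * (o_s - o_m) - r_m),
                PREF * (a_r - r_s - 0.047 * g_s * (o_s - o_m)),
            ]

        sol = solve_ivp(rhs, (0.0, 2.0e4), [402.9, 402.9, OA, OA],
                        rtol=1e-12, atol=1e-8, method="LSODA")
        got = c4_gas_steady_state(g_w, g_s, a_r, v_p, r_m, r_s, 402.9, OA)
        for ode_val, lin_val in zip(sol.y[:, -1], got):
            assert ode_val == pytest.approx(lin_val, rel=1e-6)

    def test_nonpositive_conductances_rejected(self):
        with pytest.raises(InvalidInputError):
            c4_gas_steady_state(0.0, 0.003, 1.0, 1.0, 0.5, 0.5, 402.9, OA)


class TestStomatalConductance:
    def test_compensation_flux_returns_residual(self):
        g = stomatal_conductance(1.95, 1.95, 50.0, 1.0, 1.0, 402.9, 4.53,
                                 0.017, 10.0)
        assert g == pytest.approx(0.017)

    def test_full_stress_closes_to_residual(self):
        g = stomatal_conductance(25.0, 1.95, 50.0, 1.0, 0.0, 402.9, 4.53,
                                 0.017, 10.0)
        assert g == pytest.approx(0.017)

    def test_hand_arithmetic(self):
        # m=4.53, S_w=1, A−R_d=20, C_A−Γ=350, VPD=1 kPa, VPD_ref=10 kPa
        g = stomatal_conductance(21.95, 1.95, 52.9, 1.0, 1.0, 402.9, 4.53,
                                 0.017, 10.0)
        expected = 4.53 * 20.0 / 350.0 / 1.1 + 0.017
        assert g == pytest.approx(expected, rel=1e-12)
        assert g == pytest.approx(0.2523, abs=2e-4)

    def test_nonincreasing_in_vpd(self):
        vals = [stomatal_conductance(20.0, 1.95, 50.0, v, 1.0, 402.9, 4.53,
                                     0.017, 10.0)
                for v in np.linspace(0.0, 6.0, 20)]
        assert all(b <= a + 1e-15 for a, b in zip(vals, vals[1:]))

    def test_subcompensation_ambient_rejected(self):
        with pytest.raises(InvalidInputError):
            stomatal_conductance(20.0, 1.95, 500.0, 1.0, 1.0, 400.0, 4.53,
                                 0.017, 10.0)


class TestCompensationPoints:
    def test_c3_without_respiration_collapses_to_gamma_star(self):
        assert c3_compensation_point(0.0, VCMAX, KC, KO, OA, GSTAR) == \
            pytest.approx(GSTAR)

    def test_c3_respiration_raises_compensation_point(self):
        gamma = c3_compensation_point(1.95, VCMAX, KC, KO, OA, GSTAR)
        assert gamma > GSTAR

    def test_c3_excess_respiration_rejected(self):
        with pytest.raises(InvalidInputError):
            c3_compensation_point(VCMAX, VCMAX, KC, KO, OA, GSTAR)

    def test_c4_bundle_sheath_collapses_without_respiration(self):
        g4 = 0.5 / 2862.0
        gamma_s = c4_bundle_sheath_compensation(0.0, VCMAX, KC, KO, OA, g4)
        assert gamma_s == pytest.approx(g4 * OA)

    def test_c4_leaf_level_form(self):
        # Γ = (K_P/V_pmax)·(g_s·Γ_s − R_m), evaluated as printed
        gamma = c4_compensation_point(40.0, 40.0, 119.2, 0.00287, 0.975)
        assert gamma == pytest.approx(40.0 / 119.2 * (0.00287 * 40.0 - 0.975))

    def test_dispatch_matches_pathway_functions(self):
        g4 = 0.5 / 2862.0
        gamma_c3, none = compensation_points("C3", 1.95, 0.975, VCMAX, 119.2,
                                             KC, KO, 40.0, OA, GSTAR, g4,
                                             0.00287)
        assert none is None
        assert gamma_c3 == pytest.approx(
            c3_compensation_point(1.95, VCMAX, KC, KO, OA, GSTAR))
        gamma_c4, gamma_s = compensation_points("C4", 1.95, 0.975, VCMAX,
                                                119.2, KC, KO, 40.0, OA,
                                                GSTAR, g4, 0.00287)
        assert gamma_s == pytest.approx(
            c4_bundle_sheath_compensation(1.95, VCMAX, KC, KO, OA, g4))
        assert gamma_c4 == pytest.approx(
            c4_compensation_point(gamma_s, 40.0, 119.2, 0.00287, 0.975))
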