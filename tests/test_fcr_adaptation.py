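"""Flux-controlled-regulation simulator: regulation functions, steady
states, depletion dynamics and death-rate prediction."""

import math

import numpy as np
import pytest
from scipy import optimize

from starvekit.fcr_adaptation import (FCRParams, FCRState, NutrientPool,
                                      adaptation_state, below_affinity_share,
                                      death_from_adaptation,
                                      depletion_scenario, init_steady_state,
                                      mass_balance_error,
                                      regulation_functions,
                                      scenario_death_rates,
                                      sequential_uptake_rates,
                                      simulate_depletion, steady_state_sigma,
                                      uptake_rate)

P = FCRParams()


class TestUptakeRate:
    def test_half_saturation(self):
        assert uptake_rate(2.0, 3.0, 2.0) == pytest.approx(1.5)

    def test_zero_concentration(self):
        assert uptake_rate(0.0, 3.0, 2.0) == 0.0

    def test_nine_km(self):
        assert uptake_rate(9.0, 1.0, 1.0) == pytest.approx(0.9)


class TestRegulationFunctions:
    def test_zero_activity(self):
        chi_R, chi_Cat = regulation_functions(0.0, P)
        assert chi_R == pytest.approx(P.phi_Rb0)
        assert chi_Cat == pytest.approx(1.0)

    def test_chi_R_monotone_increasing(self):
        sigmas = np.linspace(0, 0.9 * P.gamma_t, 20)
        vals = [regulation_functions(s, P)[0] for s in sigmas]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_chi_cat_vanishes_at_c_line(self):
        # root of sigma*chi_R(sigma) = lambda_C
        f = lambda s: s * regulation_functions(s, P)[0] - P.lambda_C
        s_star = optimize.brentq(f, 0.0, 0.999 * P.gamma_t)
        assert regulation_functions(s_star, P)[1] == pytest.approx(0.0,
                                                                   abs=1e-12)

    def test_capacity_exceeded(self):
        with pytest.raises(ValueError, match="translation capacity"):
            regulation_functions(P.gamma_t, P)


class TestInitSteadyState:
    def test_adaptation_equals_mu0(self):
        for mu0 in (0.2, 0.6, 0.9, 1.1):
            st = init_steady_state(mu0, P)
            assert adaptation_state(st.M_Rb / st.M, P) == pytest.approx(
                mu0, abs=1e-9)

    def test_slow_growth_limit_phi_rb0(self):
        st = init_steady_state(1e-6, P)
        assert st.M_Rb / st.M == pytest.approx(P.phi_Rb0, rel=1e-3)

    def test_sigma_matches_bisection_oracle(self):
        mu0 = 0.7
        f = lambda s: s * P.phi_Rb0 / (1 - s / P.gamma_t) - mu0
        s_oracle = optimize.bisect(f, 0.0, 0.999 * P.gamma_t, xtol=1e-12)
        assert steady_state_sigma(mu0, P) == pytest.approx(s_oracle,
                                                           abs=1e-9)

    def test_infeasible_mu0(self):
        with pytest.raises(ValueError, match="infeasible"):
            init_steady_state(1.5, P)

    def test_steady_state_holds_under_saturating_nutrient(self):
        # ten generations with c >> K_M: fractions stay constant
        mu0 = 0.9
        s0, pool, params = depletion_scenario(1, K_M_uM=1e-4, mu0=mu0,
                                              n_doublings=10.5)
        t_tengen = 10 * math.log(2) / mu0
        traj = simulate_depletion(s0, pool, params, t_end=t_tengen)
        assert traj.t[-1] == pytest.approx(t_tengen)
        assert np.max(np.abs(traj.phi_Rb - traj.phi_Rb[0])) < 1e-6 * \
            traj.phi_Rb[0]
        assert np.max(np.abs(traj.mu_inst - mu0)) < 1e-4 * mu0


class TestSimulateDepletion:
    def test_mass_conservation(self):
        s0, pool, params = depletion_scenario(2, 100.0)
        traj = simulate_depletion(s0, pool, params, t_end=100.0)
        assert mass_balance_error(traj) < 1e-6

    def test_below_affinity_share_is_km_over_c0(self):
        s0, pool, params = depletion_scenario(1, K_M_uM=1000.0,
                                              c0_total_uM=5000.0)
        traj = simulate_depletion(s0, pool, params, t_end=100.0)
        assert below_affinity_share(traj, pool) == pytest.approx(0.2,
                                                                 abs=1e-3)

    def test_high_affinity_limit_no_adaptation(self):
        # K_M -> 0: abrupt stop, final adaptation stays at mu0
        s0, pool, params = depletion_scenario(1, K_M_uM=0.05)
        traj = simulate_depletion(s0, pool, params, t_end=100.0)
        assert traj.final_adaptation == pytest.approx(0.9, rel=0.02)
        assert traj.final_gamma == pytest.approx(
            params.tradeoff.gamma_per_day(0.9), rel=0.03)

    def test_trajectory_invariants(self):
        s0, pool, params = depletion_scenario(2, 100.0)
        traj = simulate_depletion(s0, pool, params, t_end=100.0)
        assert np.all(np.diff(traj.M) >= -1e-12)
        assert np.all(np.diff(traj.c, axis=1) <= 1e-12)
        assert np.all(traj.mu_inst >= -1e-12)

    def test_adaptation_monotone_once_flux_falls(self):
        s0, pool, params = depletion_scenario(1, 1000.0)
        traj = simulate_depletion(s0, pool, params, t_end=100.0)
        peak = int(np.argmax(traj.J))
        assert np.all(np.diff(traj.adaptation[peak:]) <= 1e-9)


class TestAdaptationAndDeath:
    def test_phi_rb0_maps_to_zero(self):
        assert adaptation_state(P.phi_Rb0, P) == 0.0

    def test_death_at_zero_state(self):
        assert death_from_adaptation(0.0, P) == pytest.approx(0.21)

    def test_death_near_half_per_day_at_fast_growth_state(self):
        assert death_from_adaptation(0.865, P) == pytest.approx(0.50,
                                                                abs=5e-3)

    def test_log_linearity(self):
        d = math.log(death_from_adaptation(0.8, P)) - \
            math.log(death_from_adaptation(0.3, P))
        assert d == pytest.approx(0.5 * P.death_b_h, rel=1e-12)

    def test_downshift_final_composition_matches_slower_steady_state(self):
        # a proteome that adapted from 0.9 to 0.6 looks like steady growth
        # at 0.6
        st_06 = init_steady_state(0.6, P)
        assert adaptation_state(st_06.M_Rb / st_06.M, P) == pytest.approx(
            0.6, abs=1e-9)


class TestSequentialUptakeRates:
    def test_single_nutrient_closed_form(self):
        lam = 0.9
        k = sequential_uptake_rates(1, lam, P)
        assert k[0] == pytest.approx(lam / (1 - lam / P.lambda_C), rel=1e-12)

    def test_two_nutrient_hand_recursion(self):
        # lambda ladder 1.0, 0.5 with lambda_C = 1.17:
        #   K1 = 1.0/(1 - 1/1.17),  K2 = 0.5/(1 - 0.5/1.17)
        k = sequential_uptake_rates(2, 1.0, P)
        K1 = 1.0 / (1 - 1.0 / 1.17)
        K2 = 0.5 / (1 - 0.5 / 1.17)
        assert k[1] == pytest.approx(K2, rel=1e-12)
        assert k[0] == pytest.approx(K1 - K2, rel=1e-12)

    def test_rates_positive_with_corrected_indexing(self):
        k = sequential_uptake_rates(10, 0.9, P)
        assert np.all(k > 0)

    def test_printed_indexing_breaks_last_nutrient(self):
        k = sequential_uptake_rates(3, 0.9, P, printed_indexing=True)
        assert k[-1] <= 0

    def test_c_line_violation(self):
        with pytest.raises(ValueError, match="C-line"):
            sequential_uptake_rates(2, 1.3, P)

    def test_simulated_plateaus_strictly_decrease(self):
        s0, pool, params = depletion_scenario(3, 20.0)
        traj = simulate_depletion(s0, pool, params, t_end=200.0)
        # sample instantaneous growth right before each nutrient exhausts
        plateaus = []
        for j in range(3):
            cj = traj.c[j]
            alive = cj > pool.K_M[j]
            if np.any(alive):
                plateaus.append(traj.mu_inst[np.nonzero(alive)[0][-1]])
        assert len(plateaus) == 3
        assert all(a > b for a, b in zip(plateaus, plateaus[1:]))


@pytest.fixture(scope="module")
def table():
    return scenario_death_rates()


class TestScenarioDeathRates:
    def test_lower_affinity_lowers_death_rate(self, table):
        single = {r["K_M_uM"]: r["gamma_pred_per_day"]
                  for r in table if r["scenario"] == "single"}
        assert single[1000.0] < single[10.0]

    def test_more_nutrients_lower_death_rate(self, table):
        multi = {r["N"]: r["gamma_pred_per_day"]
                 for r in table if r["scenario"] == "multi"}
        assert multi[10] < multi[2] < multi[1]

    def test_predictions_bounded_by_trade_off(self, table):
        lo = P.death_a_per_day
        hi = P.death_a_per_day * math.exp(P.death_b_h * 0.9)
        for r in table:
            assert lo <= r["gamma_pred_per_day"] <= hi

    def test_single_and_multi_coincide_at_n1(self, table):
        single100 = next(r for r in table
                         if r["scenario"] == "single" and r["K_M_uM"] == 100.0)
        multi1 = next(r for r in table
                      if r["scenario"] == "multi" and r["N"] == 1)
        assert single100["gamma_pred_per_day"] == pytest.approx(
            multi1["gamma_pred_per_day"], rel=1e-9)
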