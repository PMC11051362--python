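"""Post-therapy evolution, regrowth times, simulation, classification."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from sfrtsim import (
    COMPLETE_RECOVERY,
    IMMEDIATE_REGROWTH,
    TRANSIENT_REGROWTH,
    GompertzParameters,
    ImmuneActivation,
    ImmunotherapyEffect,
    ModelDomainError,
    NoRegrowthError,
    OutcomeReport,
    gompertz_volume,
    post_therapy_log_ratio,
    recovery_condition,
    regrowth_time_closed_form,
    regrowth_time_implicit,
    simulate,
)

G = GompertzParameters(k_per_day=0.01, v_inf_cm3=1000.0)
NO_B = ImmunotherapyEffect()


class TestPostTherapyLogRatio:
    def test_zero_at_onset_without_immune_terms(self):
        L = post_therapy_log_ratio(10.0, 0.009, G, ImmuneActivation(0.0), NO_B, 10.0)
        assert L == 0.0

    def test_long_time_limit(self):
        """L -> ln(V_inf/V) - A as t -> infinity under constant A."""
        v_end = G.v_inf_cm3 * math.exp(-12.0)  # ln ratio exactly 12
        L = post_therapy_log_ratio(1e6, v_end, G, ImmuneActivation(0.4), NO_B, 0.0)
        assert L == pytest.approx(11.6, rel=1e-9)

    def test_small_time_linearization(self):
        """L ~ k m ln(V_inf/V) - A(0) to first order, error O((km)^2)."""
        v_end = G.v_inf_cm3 * math.exp(-12.0)
        a = ImmuneActivation(0.4)
        for m in (0.1, 0.5, 1.0):
            L = post_therapy_log_ratio(m, v_end, G, a, NO_B, 0.0)
            linear = G.k_per_day * m * 12.0 - 0.4
            assert abs(L - linear) <= 0.5 * 12.0 * (G.k_per_day * m) ** 2 + 1e-12

    def test_linearization_error_is_second_order(self):
        """Halving the step shrinks the linearization error ~4x."""
        v_end = G.v_inf_cm3 * math.exp(-12.0)
        a = ImmuneActivation(0.0)

        def err(m):
            L = post_therapy_log_ratio(m, v_end, G, a, NO_B, 0.0)
            return abs(L - G.k_per_day * m * 12.0)

        ratio = err(1.0) / err(0.5)
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_time_before_therapy_end_rejected(self):
        with pytest.raises(ModelDomainError):
            post_therapy_log_ratio(5.0, 0.009, G, ImmuneActivation(0.4), NO_B, 10.0)


class TestRecoveryCondition:
    def test_case_report_margin(self):
        """ln(1000/0.006) - 0.4 ~ +11.6: activation alone is not enough."""
        recovered, margin = recovery_condition(0.006, G, ImmuneActivation(0.4))
        assert not recovered
        assert margin == pytest.approx(math.log(1000 / 0.006) - 0.4, rel=1e-12)
        assert margin == pytest.approx(11.6, abs=0.05)

    def test_large_activation_recovers(self):
        recovered, margin = recovery_condition(0.006, G, ImmuneActivation(13.0))
        assert recovered and margin < 0

    def test_boundary_is_not_recovery(self):
        ratio = math.log(1000 / 0.006)
        recovered, margin = recovery_condition(0.006, G, ImmuneActivation(ratio))
        assert not recovered
        assert margin == pytest.approx(0.0, abs=1e-12)


class TestRegrowthTimeClosedForm:
    def test_case_report_value(self):
        """a0=0.4, ln ratio 12, k=0.01 -> -100 ln(1 - 1/30) ~ 3.390 days."""
        v_end = G.v_inf_cm3 * math.exp(-12.0)
        t = regrowth_time_closed_form(v_end, G, 0.4)
        assert t == pytest.approx(3.3902, abs=1e-4)

    def test_zero_activation_is_immediate(self):
        assert regrowth_time_closed_form(0.009, G, 0.0) == 0.0

    def test_recovery_regime_signalled(self):
        with pytest.raises(NoRegrowthError, match="recovery regime"):
            regrowth_time_closed_form(0.006, G, 20.0)

    def test_matches_independent_root_over_random_draws(self):
        """Closed form vs Brent root of the explicit L(t), 200 draws, 1e-6."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 200:
            k = rng.uniform(0.001, 0.1)
            ratio = rng.uniform(1.0, 20.0)
            a0 = rng.uniform(0.01, 0.99) * ratio
            g = GompertzParameters(k_per_day=k, v_inf_cm3=1000.0)
            v_end = 1000.0 * math.exp(-ratio)
            t_closed = regrowth_time_closed_form(v_end, g, a0)

            def L(m):  # independent oracle: the defining condition itself
                return ratio * (1.0 - math.exp(-k * m)) - a0

            hi = 10 * t_closed + 1.0
            if L(hi) <= 0:
                continue
            t_root = brentq(L, 0.0, hi, xtol=1e-12)
            assert t_closed == pytest.approx(t_root, abs=1e-6)
            checked += 1


class TestRegrowthTimeImplicit:
    def test_matches_closed_form_under_constant_activation(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            k = rng.uniform(0.005, 0.05)
            ratio = rng.uniform(2.0, 15.0)
            a0 = rng.uniform(0.05, 0.9) * ratio
            g = GompertzParameters(k_per_day=k, v_inf_cm3=1000.0)
            v_end = 1000.0 * math.exp(-ratio)
            t_closed = regrowth_time_closed_form(v_end, g, a0)
            t_impl = regrowth_time_implicit(
                v_end, g, ImmuneActivation(a0), NO_B, n_end_day=10.0, horizon_days=3000.0
            )
            assert t_impl == pytest.approx(t_closed, abs=1e-6)

    def test_strong_linear_immunotherapy_prevents_regrowth(self):
        """B growing faster than L's supremum slope keeps L negative forever."""
        v_end = 0.006
        b = ImmunotherapyEffect(form="linear", coefficient=5.0, start_day=10.0)
        t = regrowth_time_implicit(
            v_end, G, ImmuneActivation(0.4), b, n_end_day=10.0, horizon_days=730.0
        )
        assert t is None

    def test_logarithmic_immunotherapy_delays_regrowth(self):
        v_end = 0.006
        b_log = ImmunotherapyEffect(form="logarithmic", coefficient=0.05, start_day=11.0)
        t_none = regrowth_time_implicit(
            v_end, G, ImmuneActivation(0.4), NO_B, n_end_day=10.0, horizon_days=730.0
        )
        t_log = regrowth_time_implicit(
            v_end, G, ImmuneActivation(0.4), b_log, n_end_day=10.0, horizon_days=730.0
        )
        assert t_none is not None and t_log is not None
        assert t_log > t_none

    def test_horizon_must_exceed_end(self):
        with pytest.raises(ModelDomainError):
            regrowth_time_implicit(0.006, G, ImmuneActivation(0.4), NO_B, 10.0, 5.0)


class TestSimulate:
    def test_fixture_end_of_therapy_normoxic_volume(self, fixture_scenario):
        """Normoxic end volume is 71.5 cm^3 x the cumulative LQ factor."""
        result = simulate(fixture_scenario, horizon_days=30.0)
        assert result.v_end_theoretical_normoxic_cm3 == pytest.approx(
            71.5 * 1.19e-4, rel=1e-6
        )
        # the paper-scale rounding of that product
        assert result.v_end_theoretical_normoxic_cm3 == pytest.approx(0.009, abs=5e-4)

    def test_pure_gompertz_trajectory_matches_analytic(self, fixture_scenario):
        """Zero-dose, no-immune evolution is exactly the Gompertz solution."""
        scenario = fixture_scenario.with_(
            schedule=(), immune=None, assumed_end_volume_cm3=None, immunotherapy=NO_B
        )
        result = simulate(scenario, horizon_days=365.0)
        frame = result.frame
        v0 = 71.5
        for day, v in zip(frame["day"], frame["normoxic_viable"]):
            assert v == pytest.approx(gompertz_volume(v0, day, scenario.gompertz), rel=1e-8)

    def test_pure_growth_matches_ode_oracle(self, fixture_scenario):
        """Same trajectory cross-checked against direct ODE integration."""
        scenario = fixture_scenario.with_(
            schedule=(), immune=None, assumed_end_volume_cm3=None, immunotherapy=NO_B
        )
        g = scenario.gompertz
        result = simulate(scenario, horizon_days=365.0)
        sol = solve_ivp(
            lambda t, v: g.k_per_day * v * np.log(g.v_inf_cm3 / v),
            (0, 365), [71.5], t_eval=[100.0, 365.0], rtol=1e-11, atol=1e-12,
        )
        frame = result.frame.set_index("day")
        for t, v_num in zip(sol.t, sol.y[0]):
            assert frame.loc[t, "normoxic_viable"] == pytest.approx(v_num, rel=1e-8)

    def test_untreated_growth_monotone_and_bounded(self, fixture_scenario):
        scenario = fixture_scenario.with_(
            schedule=(), immune=None, assumed_end_volume_cm3=None, immunotherapy=NO_B
        )
        v = simulate(scenario, horizon_days=2000.0).frame["normoxic_viable"].to_numpy()
        assert np.all(np.diff(v) >= 0)
        assert np.all(v <= scenario.gompertz.v_inf_cm3)

    def test_figure_regimes_classification(self, fixture_scenario):
        """Constant-I immunotherapy recovers; none regrows; log B delays it."""
        base = fixture_scenario.with_(immune=ImmuneActivation(0.4))
        linear = simulate(
            base.with_(immunotherapy=ImmunotherapyEffect("linear", 0.05, 11.0)), 730.0
        )
        none = simulate(base, 730.0)
        logb = simulate(
            base.with_(immunotherapy=ImmunotherapyEffect("logarithmic", 0.05, 11.0)), 730.0
        )
        assert linear.outcome.classification == COMPLETE_RECOVERY
        assert none.outcome.classification == TRANSIENT_REGROWTH
        assert logb.outcome.classification == TRANSIENT_REGROWTH
        assert logb.outcome.regrowth_day > none.outcome.regrowth_day

    def test_zero_activation_regrows_immediately(self, fixture_scenario):
        scenario = fixture_scenario.with_(immune=ImmuneActivation(0.0))
        result = simulate(scenario, horizon_days=100.0)
        assert result.outcome.classification == IMMEDIATE_REGROWTH
        assert result.outcome.regrowth_day is None

    def test_recovery_monotone_in_immunotherapy_strength(self, fixture_scenario):
        """A pointwise larger B never moves the outcome toward regrowth."""
        rank = {IMMEDIATE_REGROWTH: 0, TRANSIENT_REGROWTH: 1, COMPLETE_RECOVERY: 2}
        base = fixture_scenario.with_(immune=ImmuneActivation(0.4))
        ranks = []
        for coeff in (0.0, 0.01, 0.05, 0.2, 1.0):
            it = (
                ImmunotherapyEffect("linear", coeff, 11.0)
                if coeff > 0
                else ImmunotherapyEffect()
            )
            out = simulate(base.with_(immunotherapy=it), 730.0).outcome
            ranks.append(rank[out.classification])
        assert ranks == sorted(ranks)

    def test_interfraction_growth_increases_end_volume(self, fixture_scenario):
        off = simulate(fixture_scenario, horizon_days=30.0)
        on = simulate(
            fixture_scenario.with_(include_interfraction_growth=True), horizon_days=30.0
        )
        assert (
            on.v_end_theoretical_normoxic_cm3 > off.v_end_theoretical_normoxic_cm3
        )

    def test_trajectory_conserves_necrotic_bookkeeping(self, fixture_scenario):
        frame = simulate(fixture_scenario, horizon_days=30.0).frame
        assert (frame["necrotic"] == 86.8).all()


class TestOutcomeReport:
    def test_regrowth_day_presence_tied_to_classification(self):
        with pytest.raises(ModelDomainError):
            OutcomeReport(classification=COMPLETE_RECOVERY, regrowth_day=12.0)
        with pytest.raises(ModelDomainError):
            OutcomeReport(classification=TRANSIENT_REGROWTH, regrowth_day=None)
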