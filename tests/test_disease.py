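"""Annual-loop dynamics: dose-response, rate extrapolation, state machine."""

import numpy as np
import pandas as pd
import pytest

from saltsim.disease import (
    DiseaseConfig,
    Simulation,
    advance_year,
    extrapolate_rate,
    relative_risk,
    simulate,
)
from saltsim.interventions import ScenarioSpec
from saltsim.population import SHARE_COLS, Population
from saltsim.testing import flat_rates, uniform_cohort

NONE = ScenarioSpec(kind="none")


class TestRelativeRisk:
    @pytest.mark.parametrize("intake,tmrel,slope,expected", [
        (1.5, 1.5, 0.2, 1.0),     # at threshold
        (3.5, 1.5, 0.2, 1.4),     # linear form
        (9.0, 1.5, 0.0, 1.0),     # zero slope
        (0.5, 1.5, 0.2, 1.0),     # below threshold never protective
    ])
    def test_linear_form(self, intake, tmrel, slope, expected):
        assert relative_risk(intake, tmrel, slope) == pytest.approx(expected)

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            relative_risk(3.0, 1.5, -0.1)


class TestExtrapolateRate:
    def test_closed_form(self):
        assert extrapolate_rate(0.01, -2.0, 10) == pytest.approx(0.008171, abs=5e-7)

    def test_zero_apc_unchanged(self):
        assert extrapolate_rate(0.37, 0.0, 25) == 0.37

    def test_clamped_to_probability(self):
        assert extrapolate_rate(0.9, 5.0, 10) <= 1.0
        assert extrapolate_rate(0.9, 5.0, 10) == 1.0


class TestAnnualLoop:
    def test_certain_mortality_kills_everyone(self):
        pop = uniform_cohort(200, age=50)
        rates = flat_rates(all_cause=1.0)
        sim = Simulation(pop, rates, NONE, DiseaseConfig(), seed=0)
        rows = advance_year(sim, 2010)
        assert rows["died"].all()
        log = sim.run()
        assert len(log) == 200  # no rows after death

    def test_no_incidence_without_risk(self):
        pop = uniform_cohort(500, age=40)
        rates = flat_rates(gca_incidence=0.0, rr_per_gram=0.0)
        log = simulate(pop, rates, NONE, DiseaseConfig(), seed=1)
        assert not log["incident_gca"].any()

    def test_zero_rates_freeze_everything_but_age(self):
        pop = uniform_cohort(300, age=(20, 60), intake_log_sd=0.3, seed=4)
        rates = flat_rates()
        log = simulate(pop, rates, NONE, DiseaseConfig(), seed=2)
        final = log[log["year"] == 2030]
        assert len(final) == 300
        assert not log["died"].any() and not log["incident_gca"].any()
        start = log[log["year"] == 2010].set_index("person_id")
        end = final.set_index("person_id")
        assert (end["state"] == start["state"]).all()
        assert (end["age"] - start["age"] == 20).all()

    def test_binomial_incidence_oracle(self):
        """One-stratum, one-year incident count matches n * p * RR."""
        n, p, slope = 5000, 0.01, 0.2
        pop = uniform_cohort(n, usual_sodium_g=4.0, tmrel_g=1.5, age=50)
        rates = flat_rates(gca_incidence=p, rr_per_gram=slope)
        sim = Simulation(pop, rates, NONE, DiseaseConfig(), seed=11)
        rows = sim.step(2010)
        rr = 1 + slope * (4.0 - 1.5)
        expected = n * p * rr
        se = np.sqrt(n * p * rr * (1 - p * rr))
        assert abs(rows["incident_gca"].sum() - expected) < 3 * se

    def test_lagged_exposure_gates_intervention_effect(self):
        """An exposure change at 2010 first moves incidence at 2018."""
        pop = uniform_cohort(3000, usual_sodium_g=5.0, age=40)
        rates = flat_rates(gca_incidence=0.01, rr_per_gram=1.0)
        cfg = DiseaseConfig()
        sub = ScenarioSpec(kind="substitute", substitute_fraction=0.95)
        log0 = simulate(pop, rates, NONE, cfg, seed=3)
        log1 = simulate(pop, rates, sub, cfg, seed=3)
        pre0 = log0[log0["year"] < 2018]
        pre1 = log1[log1["year"] < 2018]
        pd.testing.assert_frame_equal(
            pre0[["person_id", "year", "incident_gca"]],
            pre1[["person_id", "year", "incident_gca"]])
        assert log1["incident_gca"].sum() < log0["incident_gca"].sum()

    def test_conservation_and_absorbing_death(self, baseline_comparison):
        log = baseline_comparison.baseline.log
        alive = log.groupby("year")["person_id"].count()
        deaths = log.groupby("year")["died"].sum()
        for y in range(2010, 2030):
            assert alive[y + 1] == alive[y] - deaths[y]
        last = log.groupby("person_id").last()
        died_ids = set(log.loc[log["died"], "person_id"])
        assert died_ids == set(last.index[last["died"]])

    def test_state_machine_transitions(self, baseline_comparison):
        log = baseline_comparison.baseline.log.sort_values(["person_id", "year"])
        allowed = {("healthy", "sodium_excess"), ("sodium_excess", "healthy"),
                   ("healthy", "gca"), ("sodium_excess", "gca"),
                   ("healthy", "dead"), ("sodium_excess", "dead"),
                   ("gca", "dead"), ("gca", "gca"),
                   ("healthy", "healthy"), ("sodium_excess", "sodium_excess")}
        prev = log.groupby("person_id")["state"].shift()
        pairs = set(zip(prev.dropna(), log.loc[prev.notna(), "state"]))
        assert pairs <= allowed
        assert log.groupby("person_id")["incident_gca"].sum().max() <= 1

    def test_deterministic_under_seed(self):
        pop = uniform_cohort(400, intake_log_sd=0.2, age=(30, 70), seed=8)
        rates = flat_rates(all_cause=0.02, gca_incidence=0.005, case_fatality=0.2)
        a = simulate(pop, rates, NONE, DiseaseConfig(), seed=5)
        b = simulate(pop, rates, NONE, DiseaseConfig(), seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_population_gives_empty_log(self):
        empty = Population(df=uniform_cohort(1).df.iloc[:0].copy())
        log = simulate(empty, flat_rates(), NONE, DiseaseConfig(), seed=0)
        assert log.empty

    def test_spoon_never_adds_cases_under_crn(self):
        pop = uniform_cohort(2000, usual_sodium_g=4.5, intake_log_sd=0.25,
                             age=(30, 70), seed=12)
        rates = flat_rates(gca_incidence=0.005, rr_per_gram=0.3)
        spoon = ScenarioSpec(kind="spoon", spoon_sodium_mg=394.0)
        for seed in range(5):
            log0 = simulate(pop, rates, NONE, DiseaseConfig(), seed=seed)
            log1 = simulate(pop, rates, spoon, DiseaseConfig(), seed=seed)
            assert log1["incident_gca"].sum() <= log0["incident_gca"].sum()

    def test_poisson_lag_reproducible(self):
        pop = uniform_cohort(300, age=40)
        rates = flat_rates(gca_incidence=0.01)
        cfg = DiseaseConfig(lag_distribution="poisson")
        a = simulate(pop, rates, NONE, cfg, seed=6)
        b = simulate(pop, rates, NONE, cfg, seed=6)
        pd.testing.assert_frame_equal(a, b)
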