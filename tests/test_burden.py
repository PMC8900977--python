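"""Discounted DALY accounting and attributable-burden contrasts."""

import numpy as np
import pandas as pd
import pytest

from saltsim.burden import (
    BurdenConfig,
    attributable_burden,
    compute_burden,
    compute_yld,
    compute_yll,
    discount_factor,
)
from saltsim.disease import DiseaseConfig, simulate
from saltsim.interventions import ScenarioSpec
from saltsim.testing import flat_rates, uniform_cohort

FLAT_LE_10 = np.full((2, 19), 10.0)


def make_config(r=0.03, w=0.288, le=None):
    return BurdenConfig(disability_weight=w, discount_rate=r,
                        life_expectancy=FLAT_LE_10 if le is None else le)


def make_log(rows):
    """rows: (person_id, year, age, sex, state, died, cause)."""
    df = pd.DataFrame(rows, columns=["person_id", "year", "age", "sex",
                                     "state", "died", "cause"])
    df["province"] = "Hunan"
    df["region"] = "south"
    df["intake_g"] = 4.0
    df["excess"] = True
    df["incident_gca"] = False
    return df


class TestDiscounting:
    def test_base_year_is_one(self):
        assert discount_factor(2010, make_config()) == 1.0

    def test_closed_form_2030(self):
        assert discount_factor(2030, make_config()) == pytest.approx(
            1.03 ** -20, abs=1e-9)
        assert discount_factor(2030, make_config()) == pytest.approx(0.55368,
                                                                     abs=5e-6)

    def test_zero_rate_never_discounts(self):
        cfg = make_config(r=0.0)
        assert discount_factor(2029, cfg) == 1.0

    def test_pre_base_year_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(2009, make_config())


class TestYll:
    def test_no_deaths_is_zero(self):
        log = make_log([("p", 2010, 50, "male", "gca", False, "")])
        assert compute_yll(log, make_config()) == 0.0

    def test_undiscounted_equals_residual_life_expectancy(self):
        log = make_log([("p", 2010, 50, "male", "dead", True, "gca")])
        assert compute_yll(log, make_config(r=0.0)) == pytest.approx(10.0)

    def test_discounted_stream_geometric_series(self):
        log = make_log([("p", 2010, 50, "male", "dead", True, "gca")])
        expected = sum(1.03 ** -k for k in range(10))
        assert compute_yll(log, make_config()) == pytest.approx(expected)
        assert compute_yll(log, make_config()) == pytest.approx(8.7861, abs=5e-5)

    def test_non_gca_deaths_not_counted(self):
        log = make_log([("p", 2010, 50, "male", "dead", True, "other")])
        assert compute_yll(log, make_config()) == 0.0


class TestYld:
    def test_zero_weight_is_zero(self):
        log = make_log([("p", y, 50, "male", "gca", False, "") for y in
                        (2010, 2011, 2012)])
        assert compute_yld(log, make_config(w=0.0)) == 0.0

    def test_undiscounted_person_years(self):
        log = make_log([("p", y, 50, "male", "gca", False, "") for y in
                        (2010, 2011, 2012)])
        assert compute_yld(log, make_config(r=0.0, w=0.5)) == pytest.approx(1.5)

    def test_discounted_closed_form(self):
        log = make_log([("p", y, 50, "male", "gca", False, "") for y in
                        (2010, 2011, 2012)])
        expected = 0.5 * (1 + 1.03 ** -1 + 1.03 ** -2)
        got = compute_yld(log, make_config(w=0.5))
        assert got == pytest.approx(expected)
        assert got == pytest.approx(1.4567, abs=5e-5)


class TestAttributable:
    def test_identical_logs_give_zero(self):
        log = make_log([("p", 2010, 50, "male", "gca", False, "")])
        assert attributable_burden(log, log.copy(), make_config()) == 0.0

    def test_mismatched_populations_rejected(self):
        a = make_log([("p1", 2010, 50, "male", "healthy", False, "")])
        b = make_log([("p2", 2010, 50, "male", "healthy", False, "")])
        with pytest.raises(ValueError):
            attributable_burden(a, b, make_config())

    def test_extra_case_years_valued_at_discounted_weight(self):
        factual = make_log(
            [("p", y, 50, "male", "gca", False, "") for y in (2010, 2011, 2012)])
        counterfactual = make_log(
            [("p", y, 50, "male", "healthy", False, "") for y in
             (2010, 2011, 2012)])
        got = attributable_burden(factual, counterfactual, make_config(w=0.288))
        expected = 0.288 * (1 + 1.03 ** -1 + 1.03 ** -2)
        assert got == pytest.approx(expected)

    def test_factual_at_least_counterfactual_under_crn(self):
        pop = uniform_cohort(1500, usual_sodium_g=4.5, intake_log_sd=0.3,
                             age=(30, 70), seed=2)
        rates = flat_rates(all_cause=0.01, gca_incidence=0.004,
                           case_fatality=0.2, rr_per_gram=0.3)
        cfg = BurdenConfig.from_rates(rates)
        for seed in range(5):
            log_f = simulate(pop, rates, ScenarioSpec(), DiseaseConfig(), seed)
            log_c = simulate(pop, rates, ScenarioSpec(), DiseaseConfig(), seed,
                             force_tmrel=True)
            assert attributable_burden(log_f, log_c, cfg) >= 0.0


class TestAggregation:
    def test_discounting_never_inflates(self, baseline_comparison, inputs):
        log = baseline_comparison.baseline.log
        disc = make_config(r=0.03, le=inputs.burden_config.life_expectancy)
        undisc = make_config(r=0.0, le=inputs.burden_config.life_expectancy)
        assert (compute_yll(log, disc) + compute_yld(log, disc)
                <= compute_yll(log, undisc) + compute_yld(log, undisc))

    def test_strata_sum_to_total(self, baseline_comparison):
        res = baseline_comparison.baseline.burden
        for by, table in res.strata.items():
            assert table["daly"].sum() == pytest.approx(res.daly, rel=1e-9)
            assert table["yll"].sum() == pytest.approx(res.yll, rel=1e-9)

    def test_per_1000_scaling(self):
        log = make_log([("p", 2010, 50, "male", "dead", True, "gca")])
        res = compute_burden(log, make_config(r=0.0), population_size=500)
        assert res.daly_per_1000 == pytest.approx(1000 * res.daly / 500)
        assert res.daly == res.yll + res.yld
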