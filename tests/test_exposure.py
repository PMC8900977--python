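"""Usual-intake estimation, trend fitting, TMREL draws and excess status."""

import numpy as np
import pandas as pd
import pytest

from saltsim.exposure import (
    TmrelSpec,
    TrendParams,
    classify_excess,
    draw_tmrel,
    estimate_usual_intake,
    fit_log_decline,
    person_day_sodium,
    project_intake,
    trend_value,
)
from saltsim.synthetic_data import GeneratorConfig, ProvinceParams, \
    generate_census, generate_fct, generate_recalls


def _recalls(rows):
    return pd.DataFrame(rows, columns=[
        "person_id", "survey_year", "day_index", "food_code", "amount_g"])


PURE_SALT = pd.DataFrame({
    "food_code": ["SALT"], "sodium_mg_per_100g": [39340.0],
    "source_category": ["added_salt"]})


class TestPersonDaySodium:
    def test_composition_arithmetic(self):
        # 10 g of pure salt at 39.34 % sodium -> 3.934 g sodium
        days = person_day_sodium(_recalls([("p1", 2011, 1, "SALT", 10.0)]),
                                 PURE_SALT)
        assert days["sodium_g"].iloc[0] == pytest.approx(3.934, abs=1e-9)

    def test_unresolvable_food_code_named(self):
        with pytest.raises(ValueError, match="NOPE"):
            person_day_sodium(_recalls([("p1", 2011, 1, "NOPE", 10.0)]), PURE_SALT)


class TestUsualIntake:
    def test_no_within_variance_returns_person_mean(self):
        rows = [(p, 2011, d, "SALT", amt) for p, amt in
                [("p1", 5.0), ("p2", 10.0), ("p3", 20.0)] for d in (1, 2, 3)]
        usual = estimate_usual_intake(_recalls(rows), PURE_SALT)
        expected = {"p1": 5.0, "p2": 10.0, "p3": 20.0}
        for _, row in usual.iterrows():
            assert row["usual_sodium_g"] == pytest.approx(
                expected[row["person_id"]] * 0.3934, rel=1e-9)

    def test_shrinkage_contracts_toward_stratum_mean(self, recalls, fct):
        merged = estimate_usual_intake(recalls, fct)
        sm = merged.groupby(["province", "sex", "age_band", "survey_year"])[
            "person_mean"].transform("mean")
        lo = np.minimum(merged["person_mean"], sm)
        hi = np.maximum(merged["person_mean"], sm)
        assert ((merged["usual_sodium_g"] >= lo - 1e-9)
                & (merged["usual_sodium_g"] <= hi + 1e-9)).all()
        assert merged["usual_sodium_g"].var() <= merged["person_mean"].var()

    def test_recovers_known_stratum_mean(self, fct):
        config = GeneratorConfig(
            provinces={"Shandong": ProvinceParams(region="central",
                                                  base_mean_g=4.0, decline_b=0.0)},
            sex_multiplier={"male": 1.0, "female": 1.0},
            n_recall_persons=1200, seed=99)
        recalls = generate_recalls(generate_census(config), fct, config)
        usual = estimate_usual_intake(recalls, fct)
        adults = usual[~usual["age_band"].isin(["0-1", "1-4", "5-9", "10-14"])]
        est = adults["usual_sodium_g"]
        se = est.std() / np.sqrt(len(est))
        assert abs(est.mean() - 4.0) < 2 * se + 0.05


class TestLogDeclineTrend:
    def test_noiseless_recovery(self):
        a, b, t0 = 5.0, 0.4, 2004
        means = {y: a - b * np.log(y - t0 + 1) for y in (2004, 2006, 2009, 2011)}
        fit = fit_log_decline(means, t0=t0, province="Hunan")
        assert round(fit.a, 6) == 5.0
        assert round(fit.b, 6) == 0.4

    def test_flat_series_gives_zero_slope(self):
        fit = fit_log_decline({y: 4.2 for y in (2004, 2006, 2009)}, province="Hunan")
        assert fit.b == pytest.approx(0.0, abs=1e-12)

    def test_megacity_constant_at_latest_level(self):
        fit = fit_log_decline({2011: 4.4}, province="Shanghai")
        assert fit.constant_flag and fit.b == 0.0
        assert trend_value(fit, 2030) == trend_value(fit, 2011) == 4.4

    def test_single_year_non_megacity_rejected(self):
        with pytest.raises(ValueError):
            fit_log_decline({2011: 4.4}, province="Hunan", megacity=False)

    def test_nonpositive_means_rejected(self):
        with pytest.raises(ValueError):
            fit_log_decline({2004: 5.0, 2011: -1.0}, province="Hunan")


class TestProjection:
    trend = TrendParams(province="Hunan", a=5.0, b=0.4)

    def test_zero_slope_is_constant(self):
        flat = TrendParams(province="Hunan", a=5.0, b=0.0)
        vals = [project_intake(4.0, y, flat) for y in (2010, 2020, 2030)]
        assert vals == [4.0, 4.0, 4.0]

    def test_monotone_non_increasing_under_decline(self):
        years = np.arange(2010, 2031)
        vals = project_intake(4.0, years, self.trend)
        assert (np.diff(vals) <= 0).all()
        assert vals[-1] <= vals[0]

    def test_clamped_at_floor(self):
        steep = TrendParams(province="Hunan", a=5.0, b=6.0)
        assert project_intake(1.0, 2030, steep) == 0.6

    def test_year_outside_horizon_rejected(self):
        with pytest.raises(ValueError):
            project_intake(4.0, 2031, self.trend)
        with pytest.raises(ValueError):
            project_intake(4.0, 2005, self.trend)
        # back-fill years are allowed when explicitly requested
        assert project_intake(4.0, 2005, self.trend, allow_backfill=True) > 0


class TestTmrel:
    def test_draws_stay_in_risk_free_range(self):
        rng = np.random.default_rng(1)
        draws = draw_tmrel(TmrelSpec(), rng, size=10_000)
        assert draws.min() >= 0.6 and draws.max() <= 2.0

    def test_mean_matches_pert_closed_form(self):
        rng = np.random.default_rng(2)
        draws = draw_tmrel(TmrelSpec(), rng, size=100_000)
        assert draws.mean() == pytest.approx((0.6 + 4 * 1.5 + 2.0) / 6, abs=0.005)

    def test_degenerate_spec_rejected(self):
        with pytest.raises(ValueError):
            TmrelSpec(min_g=1.5, mode_g=1.5, max_g=1.5)


class TestClassifyExcess:
    @pytest.mark.parametrize("intake,tmrel,expected", [
        (3.0, 1.5, True),
        (1.5, 1.5, False),  # boundary is not excess
        (0.9, 1.2, False),
    ])
    def test_threshold_rule(self, intake, tmrel, expected):
        assert classify_excess(intake, tmrel) is expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_excess(-1.0, 1.5)
        with pytest.raises(ValueError):
            classify_excess(3.0, 0.0)

    def test_exceedance_monotone_in_intake(self):
        rng = np.random.default_rng(3)
        tmrels = draw_tmrel(TmrelSpec(), rng, size=20_000)
        probs = [np.mean(i > tmrels) for i in (0.8, 1.2, 1.6, 2.1)]
        assert probs == sorted(probs)
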