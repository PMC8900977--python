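"""Generator structure: census margins, recall statistics, rate-table shape."""

import numpy as np
import pandas as pd
import pytest

from saltsim._demography import AGE_BANDS, MEGACITIES, PROVINCES, SEXES
from saltsim.exposure import person_day_sodium
from saltsim.ratetables import RateTables, extrapolate_rate
from saltsim.synthetic_data import (
    GeneratorConfig,
    ProvinceParams,
    generate_census,
    generate_fct,
    generate_recalls,
    generate_rate_tables,
    write_inputs,
)


def small_config(**kw):
    provinces = {
        "Beijing": ProvinceParams(region="north", megacity=True, base_mean_g=4.6,
                                  decline_b=0.0),
        "Shandong": ProvinceParams(region="central", base_mean_g=6.1, decline_b=0.35),
        "Hunan": ProvinceParams(region="south", base_mean_g=5.0, decline_b=0.35),
    }
    kw.setdefault("provinces", provinces)
    kw.setdefault("n_recall_persons", 300)
    kw.setdefault("persons_per_province", 3000)
    kw.setdefault("seed", 5)
    return GeneratorConfig(**kw)


class TestCensus:
    def test_full_cross_of_strata(self, census):
        assert len(census) == len(PROVINCES) * len(SEXES) * len(AGE_BANDS) == 456
        cells = census.set_index(["province", "sex", "age_band"])
        assert not cells.index.duplicated().any()
        assert (census["count"] >= 0).all()
        assert set(census["region"]) == {"north", "central", "south"}

    def test_deterministic_under_seed(self, gen_config, census):
        again = generate_census(GeneratorConfig(seed=gen_config.seed))
        pd.testing.assert_frame_equal(census, again)

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="Atlantis"):
            GeneratorConfig(provinces={
                "Atlantis": ProvinceParams(region="west")})


class TestRecalls:
    def test_zero_within_day_sd_gives_identical_days(self, fct):
        config = small_config(sigma_within=0.0, n_recall_persons=40)
        recalls = generate_recalls(generate_census(config), fct, config)
        days = person_day_sodium(recalls, fct)
        spread = days.groupby(["person_id", "survey_year"])["sodium_g"].agg(
            lambda s: s.max() - s.min())
        assert np.allclose(spread, 0.0, atol=1e-9)

    def test_added_salt_share_near_target(self, recalls, fct):
        days = person_day_sodium(recalls, fct)
        share = days["sodium_added_salt_g"].sum() / days["sodium_g"].sum()
        assert abs(share - 0.67) < 0.02

    def test_megacity_flat_but_others_decline(self, recalls, fct):
        days = person_day_sodium(recalls, fct)
        adults = days[~days["age_band"].isin(["0-1", "1-4", "5-9", "10-14"])]
        means = adults.groupby(["province", "survey_year"])["sodium_g"].mean()
        for megacity in MEGACITIES:
            assert abs(means[megacity, 2011] - means[megacity, 2004]) < 0.25
        # the survey-covered provinces decline by b*ln(8) ~ 0.7 g/day
        assert means["Shandong", 2004] - means["Shandong", 2011] > 0.3

    def test_missing_stratum_config_rejected(self, census, fct):
        config = small_config()  # covers 3 of the 12 census provinces
        with pytest.raises(ValueError, match="missing"):
            generate_recalls(census, fct, config)

    def test_source_shares_sum_to_one_per_person_day(self, recalls, fct):
        days = person_day_sodium(recalls, fct)
        cats = [c for c in days.columns if c.startswith("sodium_") and c != "sodium_g"]
        assert np.allclose(days[cats].sum(axis=1), days["sodium_g"], rtol=1e-9)


class TestRateTables:
    def test_invariants(self, rates):
        for arr in (rates.all_cause_mortality, rates.gca_mortality,
                    rates.gca_prevalence):
            assert ((arr >= 0) & (arr <= 1)).all()
        assert (np.diff(rates.life_expectancy, axis=1) < 0).all()
        # GCa rates sit strictly below all-cause mortality in every stratum
        assert (rates.gca_mortality < rates.all_cause_mortality).all()
        assert (rates.gca_prevalence[rates.gca_prevalence > 0]
                < rates.all_cause_mortality[rates.gca_prevalence > 0]).all()

    def test_mortality_increases_with_age(self, rates):
        i80 = AGE_BANDS.index("80-84")
        i30 = AGE_BANDS.index("30-34")
        assert (rates.all_cause_mortality[:, i80]
                > rates.all_cause_mortality[:, i30]).all()

    def test_zero_apc_means_constant_rates(self, rates):
        out = extrapolate_rate(rates.all_cause_mortality, 0.0, 15)
        assert np.array_equal(out, rates.all_cause_mortality)

    def test_csv_roundtrip(self, rates, tmp_path):
        path = tmp_path / "rates.csv"
        rates.write_csv(path)
        back = RateTables.read_csv(path)
        np.testing.assert_allclose(back.all_cause_mortality,
                                   rates.all_cause_mortality)
        np.testing.assert_allclose(back.life_expectancy, rates.life_expectancy)
        assert back.disability_weight == rates.disability_weight
        assert back.base_year == rates.base_year


def test_fixed_seed_gives_byte_identical_files(tmp_path, fct):
    config = small_config(n_recall_persons=60)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    p1 = write_inputs(config, d1)
    p2 = write_inputs(config, d2)
    for name in ("census", "fct", "recalls", "rates"):
        assert open(p1[name], "rb").read() == open(p2[name], "rb").read()


def test_fct_covers_all_categories():
    fct = generate_fct()
    assert len(fct) == 30
    assert set(fct["source_category"]) == {
        "added_salt", "soy_sauce", "msg", "fermented", "pickled", "other"}
    assert (fct["sodium_mg_per_100g"] >= 0).all()
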