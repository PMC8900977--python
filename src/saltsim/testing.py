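"""Controlled synthetic cohorts and flat rate tables for verification runs.

These builders bypass the survey-emulating generator and construct worlds
whose expected outcomes have closed forms (flat incidence, known excess,
no secular trend), so simulation output can be checked against binomial
and linearity oracles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._demography import AGE_BANDS, REGION_OF, SEXES, SOURCE_CATEGORIES, age_to_band
from .population import Population
from .ratetables import RateTables

__all__ = ["uniform_cohort", "flat_rates", "scale_excess"]

_BAND_MIDS = np.array([(lo + hi) / 2 for lo, hi in
                       ((0, 1), (1, 5), *(((b, b + 5)) for b in range(5, 85, 5)),
                        (85, 100))])


def uniform_cohort(n: int, usual_sodium_g: float = 4.0, intake_log_sd: float = 0.0,
                   tmrel_g: float = 1.5, age: int | tuple[int, int] = 45,
                   sex: str = "male", province: str = "Shandong",
                   shares: dict[str, float] | None = None, seed: int = 0,
                   base_year: int = 2010) -> Population:
    """A one-stratum cohort with controlled intake.

    ``intake_log_sd`` > 0 spreads usual intake lognormally around
    ``usual_sodium_g`` (arithmetic mean preserved); ``age`` may be a single
    integer or an inclusive (lo, hi) range sampled uniformly.
    """
    rng = np.random.default_rng(seed)
    if shares is None:
        shares = {"added_salt": 0.67, "soy_sauce": 0.15, "msg": 0.05,
                  "fermented": 0.04, "pickled": 0.04, "other": 0.05}
    if intake_log_sd > 0:
        usual = usual_sodium_g * np.exp(
            rng.normal(-intake_log_sd**2 / 2, intake_log_sd, size=n))
    else:
        usual = np.full(n, float(usual_sodium_g))
    ages = (np.full(n, age, dtype=int) if np.isscalar(age)
            else rng.integers(age[0], age[1] + 1, size=n))
    df = pd.DataFrame({
        "id": np.arange(n),
        "province": province,
        "region": REGION_OF.get(province, "central"),
        "sex": sex,
        "age": ages,
        "age_band": [age_to_band(a) for a in ages],
        "usual_sodium_g": usual,
    })
    for c in SOURCE_CATEGORIES:
        df[f"share_{c}"] = shares[c]
    df["tmrel_g"] = float(tmrel_g)
    df["state"] = np.where(usual > tmrel_g, "sodium_excess", "healthy")
    df["year_of_gca"] = np.nan
    return Population(df=df, base_year=base_year)


def flat_rates(all_cause: float = 0.0, gca_incidence: float = 0.0,
               case_fatality: float = 0.0, prevalence: float = 0.0,
               disability_weight: float = 0.288, rr_per_gram: float = 0.2,
               apc_mortality: float = 0.0, apc_prevalence: float = 0.0,
               apc_all_cause: float = 0.0) -> RateTables:
    """Rate tables flat in sex, age and (by default) time.

    The GCa incidence is an explicit table, decoupled from the prevalence
    balance; when ``case_fatality`` > 0 a small prevalence floor keeps the
    implied case fatality exact.
    """
    shape = (len(SEXES), len(AGE_BANDS))
    if case_fatality > 0 and prevalence == 0:
        prevalence = 1e-3
    le = np.maximum(1.0, 80.0 - 0.8 * _BAND_MIDS)
    return RateTables(
        all_cause_mortality=np.full(shape, all_cause),
        gca_mortality=np.full(shape, case_fatality * prevalence),
        gca_prevalence=np.full(shape, prevalence),
        gca_incidence=np.full(shape, gca_incidence),
        life_expectancy=np.vstack([le, le + 1e-6]),
        disability_weight=disability_weight,
        rr_per_gram=rr_per_gram,
        apc_mortality=apc_mortality,
        apc_prevalence=apc_prevalence,
        apc_all_cause=apc_all_cause,
    )


def scale_excess(population: Population, fraction: float) -> Population:
    """Copy of a cohort with every person's excess intake above their TMREL
    multiplied by (1 - fraction) -- the idealised linear intervention."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    df = population.df.copy()
    tmrel = df["tmrel_g"].to_numpy(float)
    usual = df["usual_sodium_g"].to_numpy(float)
    excess = np.maximum(usual - tmrel, 0.0)
    df["usual_sodium_g"] = np.where(usual > tmrel,
                                    tmrel + (1.0 - fraction) * excess, usual)
    df["state"] = np.where(df["usual_sodium_g"] > tmrel, "sodium_excess",
                           np.where(df["state"] == "gca", "gca", "healthy"))
    return Population(df=df, base_year=population.base_year)
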