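"""Usual sodium intake from 24-h recalls, trend projection, and excess classification.

Short-term recalls overstate between-person spread because day-to-day
variation is mixed into each person's observed mean.  Usual intake is
estimated by shrinking each person's observed mean toward the stratum mean
with the classical reliability factor

    usual = stratum_mean + (person_mean - stratum_mean) * B / (B + W / k)

where B and W are between- and within-person variance components from a
one-way ANOVA with person as the factor and k is the number of observed
days.  Province-level means are projected over the horizon with a
logarithmic decline S(t) = a - b * ln(t - t0 + 1) fitted to the survey
waves; megacity provinces are held constant at the 2011 level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._demography import MEGACITIES, SOURCE_CATEGORIES, SURVEY_YEARS

__all__ = [
    "TrendParams",
    "TmrelSpec",
    "estimate_usual_intake",
    "person_day_sodium",
    "province_year_means",
    "fit_log_decline",
    "trend_value",
    "project_intake",
    "draw_tmrel",
    "classify_excess",
]

#: Intake projections never fall below the lower end of the risk-free range.
INTAKE_FLOOR_G = 0.6


@dataclass(frozen=True)
class TrendParams:
    """Province intake trajectory S(t) = a - b*ln(t - t0 + 1), g/day."""

    province: str
    a: float
    b: float
    t0: int = SURVEY_YEARS[0]
    constant_flag: bool = False

    def __post_init__(self) -> None:
        if self.constant_flag and self.b != 0.0:
            raise ValueError("constant (megacity) trend requires b = 0")


@dataclass(frozen=True)
class TmrelSpec:
    """PERT-distributed risk-free sodium intake (g/day): min 0.6, mode 1.5, max 2."""

    min_g: float = 0.6
    mode_g: float = 1.5
    max_g: float = 2.0
    shape: float = 4.0

    def __post_init__(self) -> None:
        if not self.min_g < self.mode_g < self.max_g:
            raise ValueError("TMREL spec requires min < mode < max")
        if self.shape <= 0:
            raise ValueError("PERT shape must be positive")

    @property
    def mean(self) -> float:
        return (self.min_g + self.shape * self.mode_g + self.max_g) / (self.shape + 2)


def person_day_sodium(recalls: pd.DataFrame, fct: pd.DataFrame) -> pd.DataFrame:
    """Total sodium (g) per person-day, plus sodium by source category.

    Per-record sodium = amount_g * sodium_mg_per_100g / 100 / 1000.
    Raises on any food code absent from the composition table.
    """
    unresolved = set(recalls["food_code"]) - set(fct["food_code"])
    if unresolved:
        raise ValueError(f"unresolvable food codes: {sorted(unresolved)}")
    merged = recalls.merge(fct, on="food_code", how="left")
    merged["sodium_g"] = merged["amount_g"] * merged["sodium_mg_per_100g"] / 1e5
    keys = ["person_id", "survey_year", "day_index"]
    meta_cols = [c for c in ("province", "sex", "age_band") if c in recalls.columns]
    days = (merged.groupby(keys + meta_cols, as_index=False)
            .agg(sodium_g=("sodium_g", "sum")))
    by_cat = (merged.pivot_table(index=keys, columns="source_category",
                                 values="sodium_g", aggfunc="sum", fill_value=0.0)
              .reindex(columns=list(SOURCE_CATEGORIES), fill_value=0.0))
    by_cat.columns = [f"sodium_{c}_g" for c in by_cat.columns]
    return days.merge(by_cat.reset_index(), on=keys)


def _variance_components(day_totals: pd.DataFrame) -> tuple[float, float]:
    """Between/within variance components via one-way ANOVA (person-wave as
    the factor) on stratum-centred day totals, method of moments."""
    d = day_totals.copy()
    strat_cols = [c for c in ("province", "sex", "age_band") if c in d.columns]
    d["_dev"] = d["sodium_g"] - d.groupby(strat_cols + ["survey_year"]) \
        ["sodium_g"].transform("mean") if strat_cols else \
        d["sodium_g"] - d["sodium_g"].mean()
    g = d.groupby(["person_id", "survey_year"])["_dev"]
    counts = g.count()
    means = g.mean()
    if (counts < 1).any() or len(counts) == 0:
        raise ValueError("every person needs at least one recall day")
    n_groups = len(counts)
    n_total = counts.sum()
    ssw = float(((d["_dev"] - g.transform("mean")) ** 2).sum())
    ssb = float((counts * (means - 0.0) ** 2).sum())
    df_w = max(n_total - n_groups, 1)
    df_b = max(n_groups - 1, 1)
    msw = ssw / df_w
    msb = ssb / df_b
    # harmonic-style average group size (unbalanced one-way ANOVA)
    k0 = (n_total - (counts ** 2).sum() / n_total) / df_b if n_groups > 1 else counts.iloc[0]
    var_within = msw
    var_between = max((msb - msw) / max(k0, 1.0), 0.0)
    return var_between, var_within


def estimate_usual_intake(recalls: pd.DataFrame, fct: pd.DataFrame) -> pd.DataFrame:
    """Usual daily sodium intake and source shares per person and survey wave.

    Returns one row per (person_id, survey_year) with columns
    ``usual_sodium_g`` and ``share_<category>``; strata for the shrinkage
    target are (province, sex, age_band, survey_year) when the recall table
    carries demographics, else the pooled wave mean.
    """
    days = person_day_sodium(recalls, fct)
    strat_cols = [c for c in ("province", "sex", "age_band") if c in days.columns]
    var_b, var_w = _variance_components(days)

    g = days.groupby(["person_id", "survey_year"] + strat_cols, as_index=False)
    person = g.agg(person_mean=("sodium_g", "mean"), k=("sodium_g", "count"))
    person["stratum_mean"] = person.groupby(strat_cols + ["survey_year"]) \
        ["person_mean"].transform("mean") if strat_cols else \
        person.groupby("survey_year")["person_mean"].transform("mean")
    shrink = var_b / (var_b + var_w / person["k"]) if var_w > 0 else 1.0
    person["usual_sodium_g"] = (person["stratum_mean"]
                                + (person["person_mean"] - person["stratum_mean"]) * shrink)

    cat_cols = [f"sodium_{c}_g" for c in SOURCE_CATEGORIES]
    sums = days.groupby(["person_id", "survey_year"])[cat_cols].sum()
    shares = sums.div(sums.sum(axis=1), axis=0).fillna(0.0)
    shares.columns = [f"share_{c}" for c in SOURCE_CATEGORIES]
    out = person.merge(shares.reset_index(), on=["person_id", "survey_year"])
    return out.drop(columns=["stratum_mean"])


def province_year_means(usual: pd.DataFrame) -> pd.DataFrame:
    """Province x survey-year mean usual intake (adults 15+ when age bands
    are present), the series the log-decline trend is fitted to."""
    d = usual
    if "age_band" in d.columns:
        d = d[~d["age_band"].isin(["0-1", "1-4", "5-9", "10-14"])]
    return (d.groupby(["province", "survey_year"], as_index=False)
            .agg(mean_g=("usual_sodium_g", "mean")))


def fit_log_decline(yearly_means: Mapping[int, float], t0: int = SURVEY_YEARS[0],
                    province: str = "", megacity: bool | None = None) -> TrendParams:
    """Least-squares fit of S(t) = a - b*ln(t - t0 + 1) to yearly means.

    Megacity provinces get a constant trend pinned at their latest observed
    level (b = 0); ``megacity`` defaults from the known megacity list.
    """
    if megacity is None:
        megacity = province in MEGACITIES
    years = np.array(sorted(yearly_means))
    vals = np.array([yearly_means[y] for y in years], dtype=float)
    if np.any(vals <= 0):
        raise ValueError("yearly means must be positive")
    if megacity:
        return TrendParams(province=province, a=float(vals[-1]), b=0.0, t0=t0,
                           constant_flag=True)
    if len(years) < 2:
        raise ValueError(
            f"need >= 2 distinct years to fit a decline for {province or 'province'}")
    x = np.log(years - t0 + 1)
    slope, intercept = np.polyfit(x, vals, 1)
    return TrendParams(province=province, a=float(intercept), b=float(-slope), t0=t0)


def trend_value(trend: TrendParams, year) -> np.ndarray | float:
    """Evaluate S(year); constant trends return a for every year."""
    year = np.asarray(year, dtype=float)
    if trend.constant_flag:
        out = np.full_like(year, trend.a, dtype=float)
    else:
        # years before t0 (back-fill beyond the first survey wave) are held
        # at the t0 level rather than extrapolating the log upwards
        out = trend.a - trend.b * np.log(np.maximum(year - trend.t0 + 1, 1.0))
    return out if out.ndim else float(out)


def project_intake(usual_g, year, trend: TrendParams, base_year: int = 2010,
                   floor_g: float = INTAKE_FLOOR_G,
                   allow_backfill: bool = False) -> np.ndarray | float:
    """Project a person's intake to ``year``: the province trend plus the
    person's constant offset anchored at ``base_year``, floored at
    ``floor_g``.  Years must lie in [2010, 2030] unless ``allow_backfill``
    extends the range to 2002 for lagged-exposure lookups."""
    lo = 2002 if allow_backfill else 2010
    years = np.asarray(year)
    if np.any(years < lo) or np.any(years > 2030):
        raise ValueError(f"year must lie in [{lo}, 2030]")
    offset = np.asarray(usual_g, dtype=float) - trend_value(trend, base_year)
    out = np.maximum(floor_g, offset + trend_value(trend, year))
    return out if out.ndim else float(out)


def draw_tmrel(spec: TmrelSpec, rng: np.random.Generator, size=None):
    """Sample the risk-free intake threshold from the PERT distribution:
    a Beta(1 + s*(m-a)/(b-a), 1 + s*(b-m)/(b-a)) rescaled to [a, b]."""
    a, m, b, s = spec.min_g, spec.mode_g, spec.max_g, spec.shape
    alpha = 1.0 + s * (m - a) / (b - a)
    beta = 1.0 + s * (b - m) / (b - a)
    draw = stats.beta.rvs(alpha, beta, size=size, random_state=rng)
    return a + (b - a) * draw


def classify_excess(intake_g, tmrel_g):
    """True where intake strictly exceeds the risk-free threshold."""
    intake = np.asarray(intake_g, dtype=float)
    tmrel = np.asarray(tmrel_g, dtype=float)
    if np.any(intake <= 0) or np.any(tmrel <= 0):
        raise ValueError("intake and TMREL must be positive")
    out = intake > tmrel
    return out if out.ndim else bool(out)
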