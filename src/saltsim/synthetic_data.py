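"""Synthetic model inputs: census margins, food-composition table, 24-h recalls, rate tables.

The generator emulates the statistical structure of the study inputs so the
whole pipeline is testable without any restricted survey or census file:

* right-skewed (lognormal) province/sex/age-specific sodium intake with
  within-person day-to-day variation around each person's long-run mean;
* a food-source decomposition in which direct addition of cooking salt
  dominates (about two thirds of total sodium by default);
* province-level intake declining logarithmically across the 2004-2011
  survey waves, except in the three megacities where exposure is held at
  the 2011 level;
* age-increasing all-cause mortality with gastric-cancer rates well below
  all-cause mortality in every stratum.

All randomness flows from one root seed through named independent streams
(census / recalls / rates), so each output file is reproducible on its own.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._demography import (
    AGE_BANDS,
    MEGACITIES,
    PROVINCES,
    REGIONS,
    REGION_OF,
    SEXES,
    SOURCE_CATEGORIES,
    SURVEY_YEARS,
)
from .ratetables import RateTables

__all__ = [
    "ProvinceParams",
    "GeneratorConfig",
    "generate_census",
    "generate_fct",
    "generate_recalls",
    "generate_rate_tables",
    "write_inputs",
]

# Named sub-streams of the root seed.
_STREAM_CENSUS, _STREAM_RECALLS, _STREAM_RATES = 0, 1, 2


def _stream(seed: int, stream_id: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream_id,)))


@dataclass(frozen=True)
class ProvinceParams:
    """Per-province exposure parameters.

    ``base_mean_g`` is the adult mean usual sodium intake (g/day) at the
    first survey wave (2004); for megacities it is the constant 2011 level.
    ``decline_b`` is the log-decline slope in g/day per log-year.
    """

    region: str
    megacity: bool = False
    base_mean_g: float = 5.0
    decline_b: float = 0.35
    population_weight: float = 1.0


def _default_provinces() -> dict[str, ProvinceParams]:
    # Central provinces eat saltiest (heavy use of added salt and soy sauce);
    # megacities somewhat less.  Values are stylised adult means in g/day.
    base = {
        "Beijing": 4.6, "Heilongjiang": 5.3, "Liaoning": 5.2,
        "Henan": 5.9, "Jiangsu": 5.5, "Shandong": 6.1,
        "Chongqing": 4.8, "Hunan": 5.0, "Hubei": 5.1,
        "Guizhou": 4.7, "Guangxi": 4.6, "Shanghai": 4.4,
    }
    return {
        p: ProvinceParams(
            region=REGION_OF[p],
            megacity=p in MEGACITIES,
            base_mean_g=base[p],
            decline_b=0.0 if p in MEGACITIES else 0.35,
        )
        for p in PROVINCES
    }


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-input generator.

    ``sigma_between`` / ``sigma_within`` are log-scale SDs of the person
    long-run mean around the stratum mean and of day-to-day intake around
    the person mean.  ``source_shares`` are expected shares of total sodium
    by source category; direct addition defaults to 0.67.
    """

    provinces: dict[str, ProvinceParams] = field(default_factory=_default_provinces)
    sigma_between: float = 0.25
    sigma_within: float = 0.40
    source_shares: dict[str, float] = field(default_factory=lambda: {
        "added_salt": 0.67, "soy_sauce": 0.15, "msg": 0.05,
        "fermented": 0.04, "pickled": 0.04, "other": 0.05,
    })
    share_concentration: float = 80.0
    sex_multiplier: dict[str, float] = field(default_factory=lambda: {
        "male": 1.08, "female": 0.92})
    n_recall_persons: int = 2000
    persons_per_province: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.provinces:
            raise ValueError("config must list at least one province")
        for name, pp in self.provinces.items():
            if pp.region not in REGIONS:
                raise ValueError(
                    f"province {name!r} mapped to unknown region {pp.region!r}; "
                    f"regions are {REGIONS}")
        if abs(sum(self.source_shares.values()) - 1.0) > 1e-9:
            raise ValueError("source_shares must sum to 1")
        if set(self.source_shares) != set(SOURCE_CATEGORIES):
            raise ValueError(f"source_shares must cover exactly {SOURCE_CATEGORIES}")
        if self.sigma_between <= 0:
            raise ValueError("sigma_between must be > 0")
        if self.sigma_within < 0:
            raise ValueError("sigma_within must be >= 0")

    # -- stratum mean model -------------------------------------------------

    def age_multiplier(self, age_band: str) -> float:
        """Children eat less sodium than adults; flat from 15 upwards."""
        if age_band in ("0-1",):
            return 0.25
        if age_band in ("1-4",):
            return 0.50
        if age_band in ("5-9", "10-14"):
            return 0.75
        return 1.0

    def province_mean(self, province: str, year: int) -> float:
        """Province-level adult mean intake trajectory S(t), g/day."""
        pp = self.provinces[province]
        if pp.megacity:
            return pp.base_mean_g
        return pp.base_mean_g - pp.decline_b * np.log(year - SURVEY_YEARS[0] + 1)

    def stratum_mean(self, province: str, sex: str, age_band: str, year: int) -> float:
        return (self.province_mean(province, year)
                * self.sex_multiplier[sex]
                * self.age_multiplier(age_band))

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        payload["provinces"] = {
            name: ProvinceParams(**pp) for name, pp in payload["provinces"].items()}
        return cls(**payload)


# Stylised 2010-like age pyramid: weight per census band (normalised later).
_PYRAMID = np.array([
    1.1, 4.4, 5.5, 6.4, 8.2, 9.4, 8.6, 8.2, 8.8,
    9.2, 7.6, 6.0, 5.0, 3.8, 2.9, 2.3, 1.7, 0.9, 0.6,
])


def generate_census(config: GeneratorConfig) -> pd.DataFrame:
    """Full province x sex x age-band cross of person counts.

    Counts are multinomial around a shared stylised age pyramid and a
    51.2/48.8 male/female split, scaled by each province's population
    weight.  Deterministic under ``config.seed``.
    """
    rng = _stream(config.seed, _STREAM_CENSUS)
    band_p = _PYRAMID / _PYRAMID.sum()
    sex_p = np.array([0.512, 0.488])
    cell_p = np.outer(sex_p, band_p).ravel()
    rows = []
    for province, pp in config.provinces.items():
        total = int(round(config.persons_per_province * pp.population_weight))
        counts = rng.multinomial(total, cell_p).reshape(len(SEXES), len(AGE_BANDS))
        for i, sex in enumerate(SEXES):
            for j, band in enumerate(AGE_BANDS):
                rows.append((province, pp.region, sex, band, int(counts[i, j])))
    return pd.DataFrame(rows, columns=["province", "region", "sex", "age_band", "count"])


# Fixed 30-item toy food-composition table spanning all six source categories.
# sodium_mg_per_100g: SALT-001 is pure NaCl at 39.34 % sodium by mass.
_FCT_ITEMS = [
    ("SALT-001", 39340.0, "added_salt"),
    ("SOY-001", 6900.0, "soy_sauce"),
    ("SOY-002", 5800.0, "soy_sauce"),
    ("MSG-001", 12300.0, "msg"),
    ("MSG-002", 8160.0, "msg"),
    ("FERM-001", 5100.0, "fermented"),
    ("FERM-002", 3200.0, "fermented"),
    ("FERM-003", 2400.0, "fermented"),
    ("PICK-001", 3900.0, "pickled"),
    ("PICK-002", 2600.0, "pickled"),
    ("PICK-003", 1900.0, "pickled"),
    ("OTH-001", 610.0, "other"),
    ("OTH-002", 420.0, "other"),
    ("OTH-003", 330.0, "other"),
    ("OTH-004", 260.0, "other"),
    ("OTH-005", 190.0, "other"),
    ("OTH-006", 150.0, "other"),
    ("OTH-007", 120.0, "other"),
    ("OTH-008", 95.0, "other"),
    ("OTH-009", 80.0, "other"),
    ("OTH-010", 65.0, "other"),
    ("OTH-011", 52.0, "other"),
    ("OTH-012", 40.0, "other"),
    ("OTH-013", 31.0, "other"),
    ("OTH-014", 24.0, "other"),
    ("OTH-015", 18.0, "other"),
    ("OTH-016", 12.0, "other"),
    ("OTH-017", 8.0, "other"),
    ("OTH-018", 5.0, "other"),
    ("OTH-019", 2.0, "other"),
]


def generate_fct(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Toy food-composition table: food code, sodium mg/100 g, source category."""
    return pd.DataFrame(
        _FCT_ITEMS, columns=["food_code", "sodium_mg_per_100g", "source_category"])


def generate_recalls(census: pd.DataFrame, fct: pd.DataFrame,
                     config: GeneratorConfig) -> pd.DataFrame:
    """Three-day 24-h recall records for all four survey waves.

    Persons are sampled proportional to census counts.  Each person carries a
    lognormal person effect (constant across waves), each person-day a
    lognormal within-person deviation; daily sodium is decomposed into the
    six source categories with Dirichlet shares around the config targets and
    converted to food amounts through the composition table.
    """
    if fct.empty:
        raise ValueError("food-composition table must be non-empty")
    missing = set(census["province"]) - set(config.provinces)
    if missing:
        raise ValueError(f"census strata missing from config: {sorted(missing)}")

    rng = _stream(config.seed, _STREAM_RECALLS)
    cells = census[census["count"] > 0].reset_index(drop=True)
    probs = cells["count"].to_numpy(float)
    probs /= probs.sum()
    n = config.n_recall_persons
    cell_idx = rng.choice(len(cells), size=n, p=probs)

    cats = list(SOURCE_CATEGORIES)
    target = np.array([config.source_shares[c] for c in cats])
    by_cat = {c: fct[fct["source_category"] == c] for c in cats}
    for c in cats:
        if by_cat[c].empty:
            raise ValueError(f"food-composition table has no item in category {c!r}")

    person_eff = rng.normal(0.0, config.sigma_between, size=n)
    shares = rng.dirichlet(target * config.share_concentration, size=n)
    # one food per category per person, reused across days/waves
    food_idx = {c: rng.integers(len(by_cat[c]), size=n) for c in cats}

    n_waves, n_days, n_cats = len(SURVEY_YEARS), 3, len(cats)
    sw = config.sigma_within
    day_dev = (rng.normal(0.0, sw, size=(n, n_waves, n_days)) if sw > 0
               else np.zeros((n, n_waves, n_days)))

    # stratum means per person x wave, filled per unique census cell
    mu = np.empty((n, n_waves))
    for i in np.unique(cell_idx):
        cell = cells.iloc[i]
        mask = cell_idx == i
        for w, year in enumerate(SURVEY_YEARS):
            mu[mask, w] = config.stratum_mean(
                cell["province"], cell["sex"], cell["age_band"], year)

    person_mean = mu * np.exp(person_eff - config.sigma_between**2 / 2)[:, None]
    day_total = person_mean[:, :, None] * np.exp(day_dev - sw**2 / 2)
    sodium = day_total[:, :, :, None] * shares[:, None, None, :]  # (n,W,D,C)

    codes = np.empty((n, n_cats), dtype=object)
    mg = np.empty((n, n_cats))
    for ci, c in enumerate(cats):
        sub = by_cat[c].reset_index(drop=True)
        codes[:, ci] = sub["food_code"].to_numpy()[food_idx[c]]
        mg[:, ci] = sub["sodium_mg_per_100g"].to_numpy()[food_idx[c]]
    amounts = sodium * 1e5 / mg[:, None, None, :]

    rep = n_waves * n_days * n_cats
    person_ids = np.array([f"P{p:05d}" for p in range(n)])
    out = pd.DataFrame({
        "person_id": np.repeat(person_ids, rep),
        "province": np.repeat(cells["province"].to_numpy()[cell_idx], rep),
        "sex": np.repeat(cells["sex"].to_numpy()[cell_idx], rep),
        "age_band": np.repeat(cells["age_band"].to_numpy()[cell_idx], rep),
        "survey_year": np.tile(np.repeat(SURVEY_YEARS, n_days * n_cats), n),
        "day_index": np.tile(np.repeat([1, 2, 3], n_cats), n * n_waves),
        "food_code": np.tile(codes, (1, n_waves * n_days)).ravel(),
        "amount_g": amounts.ravel(),
    })
    return out


def generate_rate_tables(config: GeneratorConfig) -> RateTables:
    """Stylised GBD/WHO-like rate tables.

    All-cause mortality follows a Gompertz curve with an infant bump; GCa
    prevalence rises with age from 20 and its population-level mortality is
    a fixed fraction of prevalence, keeping both strictly below all-cause
    mortality everywhere.  Residual life expectancy declines linearly in age.
    """
    rng = _stream(config.seed, _STREAM_RATES)
    mids = np.array([(lo + hi) / 2 for lo, hi in
                     ((0, 1), (1, 5), *(((b, b + 5)) for b in range(5, 85, 5)), (85, 100))])
    sex_scale = np.array([1.0, 0.85]) * np.exp(rng.normal(0.0, 0.03, size=2))

    gompertz = 2.0e-4 * np.exp(0.085 * mids)
    gompertz[0] += 8.0e-3   # infant mortality bump
    gompertz[1] += 8.0e-4
    all_cause = np.clip(np.outer(sex_scale, gompertz), 0.0, 0.7)
    # bump breaks age monotonicity at the very young end only; enforce it
    all_cause = np.maximum.accumulate(all_cause, axis=1)
    all_cause += np.arange(len(mids)) * 1e-9  # strict increase

    prev = np.where(mids >= 20, 8.0e-4 * np.exp(0.06 * (mids - 40.0)), 0.0)
    prev = np.clip(np.outer(np.array([1.15, 0.85]), prev), 0.0, 0.05)
    gca_mort = 0.25 * prev  # case fatality ~25 %/yr

    le = np.maximum(2.0, 77.0 - 0.82 * mids)
    life_exp = np.vstack([le - 1.5, le + 1.5])
    life_exp = np.maximum(life_exp, 1.0)

    return RateTables(
        all_cause_mortality=all_cause,
        gca_mortality=gca_mort,
        gca_prevalence=prev,
        life_expectancy=life_exp,
        disability_weight=0.288,
        rr_per_gram=0.20,
        apc_mortality=-2.0,
        apc_prevalence=-1.0,
        apc_all_cause=-1.0,
        base_year=2010,
    )


def write_inputs(config: GeneratorConfig, outdir) -> dict[str, str]:
    """Generate and write census.csv, fct.csv, recalls.csv, rates.csv and the
    generator config YAML into ``outdir``; returns the path map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    census = generate_census(config)
    fct = generate_fct(config)
    recalls = generate_recalls(census, fct, config)
    rates = generate_rate_tables(config)
    paths = {name: os.path.join(outdir, f"{name}.csv")
             for name in ("census", "fct", "recalls", "rates")}
    census.to_csv(paths["census"], index=False)
    fct.to_csv(paths["fct"], index=False)
    recalls.to_csv(paths["recalls"], index=False)
    rates.write_csv(paths["rates"])
    cfg_path = os.path.join(outdir, "generator_config.yaml")
    config.to_yaml(cfg_path)
    paths["config"] = cfg_path
    return paths
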