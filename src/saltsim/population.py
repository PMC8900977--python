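"""Synthetic individuals matching census margins.

Individuals are allocated to (province, sex, age-band) cells by multinomial
sampling of the census proportions, given an exact integer age uniform
within their band, a usual sodium intake and source-share profile drawn
from their stratum's estimated usual intakes, and an initial health state:
prevalent gastric cancer with the stratum's base-year prevalence, otherwise
sodium-excess or healthy according to intake versus the TMREL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._demography import (
    AGE_BAND_BOUNDS,
    REGION_OF,
    SEXES,
    SOURCE_CATEGORIES,
    band_index,
)
from .ratetables import RateTables

__all__ = ["Population", "build_population"]

STATES = ("healthy", "sodium_excess", "gca", "dead")

SHARE_COLS = [f"share_{c}" for c in SOURCE_CATEGORIES]


@dataclass
class Population:
    """Columnar individual table plus the base (start) year.

    Columns: id, province, region, sex, age (integer years at base year),
    age_band, state, usual_sodium_g, share_<category> x6, tmrel_g,
    year_of_gca (NaN when never diseased).
    """

    df: pd.DataFrame
    base_year: int = 2010

    def __post_init__(self) -> None:
        if self.df["id"].duplicated().any():
            raise ValueError("individual ids must be unique")
        bad = set(self.df["state"]) - set(STATES)
        if bad:
            raise ValueError(f"unknown states: {sorted(bad)}")
        shares = self.df[SHARE_COLS].to_numpy(float)
        if not np.allclose(shares.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("source shares must sum to 1 per person")

    def __len__(self) -> int:
        return len(self.df)

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _intake_sampler(usual: pd.DataFrame):
    """Stratum-matched donor sampling with pooled fallbacks.

    ``usual`` is the per-person usual-intake table (latest wave per person);
    donors are matched on (province, sex, age_band), falling back to
    (province, sex), province, then the full pool when a stratum is empty.
    """
    cols = ["usual_sodium_g"] + SHARE_COLS
    pools = {
        3: usual.groupby(["province", "sex", "age_band"]),
        2: usual.groupby(["province", "sex"]),
        1: usual.groupby(["province"]),
    }
    groups = {level: {k: v[cols].to_numpy(float) for k, v in g} for level, g in pools.items()}
    full = usual[cols].to_numpy(float)

    def sample(province: str, sex: str, age_band: str, size: int,
               rng: np.random.Generator) -> np.ndarray:
        for key, level in (((province, sex, age_band), 3), ((province, sex), 2),
                           (province, 1)):
            pool = groups[level].get(key)
            if pool is not None and len(pool):
                return pool[rng.integers(len(pool), size=size)]
        return full[rng.integers(len(full), size=size)]

    return sample


def build_population(census: pd.DataFrame, usual_intakes: pd.DataFrame, n: int,
                     seed: int, tmrel_g: float = 1.5,
                     rates: RateTables | None = None,
                     base_year: int = 2010) -> Population:
    """Build ``n`` individuals resembling the census margins.

    Cell allocation is a single multinomial draw over census proportions, so
    realised margins converge to the census as n grows.  ``usual_intakes``
    is the table from :func:`saltsim.exposure.estimate_usual_intake` (one
    row per person; pass the latest wave).  When ``rates`` is given,
    base-year gastric-cancer prevalence seeds initial disease states.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    cells = census[census["count"] > 0].reset_index(drop=True)
    if cells.empty:
        raise ValueError("census has no nonzero cells")
    if tmrel_g <= 0:
        raise ValueError("tmrel_g must be positive")

    rng = np.random.default_rng(seed)
    p = cells["count"].to_numpy(float)
    counts = rng.multinomial(n, p / p.sum())
    sampler = _intake_sampler(usual_intakes)

    frames = []
    offset = 0
    for i, n_cell in enumerate(counts):
        if n_cell == 0:
            continue
        cell = cells.iloc[i]
        lo, hi = AGE_BAND_BOUNDS[cell["age_band"]]
        draws = sampler(cell["province"], cell["sex"], cell["age_band"], n_cell, rng)
        frame = pd.DataFrame({
            "id": np.arange(offset, offset + n_cell),
            "province": cell["province"],
            "region": cell.get("region", REGION_OF.get(cell["province"], "")),
            "sex": cell["sex"],
            "age": rng.integers(lo, hi, size=n_cell),
            "age_band": cell["age_band"],
            "usual_sodium_g": draws[:, 0],
        })
        for j, col in enumerate(SHARE_COLS):
            frame[col] = draws[:, 1 + j]
        frames.append(frame)
        offset += n_cell
    df = pd.concat(frames, ignore_index=True)
    df["tmrel_g"] = float(tmrel_g)

    # initial health states: prevalent GCa first, then excess vs healthy
    if rates is not None:
        sex_idx = df["sex"].map(SEXES.index).to_numpy()
        bidx = df["age_band"].map(band_index).to_numpy()
        prev = np.asarray(rates.gca_prev(sex_idx, bidx, base_year))
        has_gca = rng.random(len(df)) < prev
    else:
        has_gca = np.zeros(len(df), dtype=bool)
    excess = df["usual_sodium_g"].to_numpy(float) > float(tmrel_g)
    state = np.where(has_gca, "gca", np.where(excess, "sodium_excess", "healthy"))
    df["state"] = state
    df["year_of_gca"] = np.where(has_gca, float(base_year), np.nan)
    return Population(df=df, base_year=base_year)
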