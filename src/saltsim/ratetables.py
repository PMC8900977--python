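"""Rate tables: mortality, gastric-cancer prevalence/mortality, trends, life expectancy.

All age-specific quantities are stored as dense ``(2, n_bands)`` arrays
(rows male/female, columns census age bands) valid at a base year, with
annual-percent-change (APC) slopes used to extrapolate other years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._demography import AGE_BANDS, SEXES, band_index

__all__ = ["RateTables", "extrapolate_rate"]


def extrapolate_rate(base_rate, apc: float, years_elapsed) -> np.ndarray | float:
    """Project a base-year probability forward (or back) along a constant
    annual percent change, clamping to [0, 1].

    ``rate * (1 + apc/100) ** years_elapsed``; ``apc`` is in percent per year
    and ``years_elapsed`` may be negative.
    """
    base = np.asarray(base_rate, dtype=float)
    if np.any(base < 0) or np.any(base > 1):
        raise ValueError("base_rate must lie in [0, 1]")
    out = base * (1.0 + apc / 100.0) ** np.asarray(years_elapsed, dtype=float)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


@dataclass
class RateTables:
    """Stratum-keyed epidemiological inputs for the simulation.

    Parameters
    ----------
    all_cause_mortality, gca_mortality, gca_prevalence
        ``(2, n_bands)`` annual probabilities / proportions at ``base_year``.
        GCa mortality is the population-level rate (deaths per person, not
        per case).
    apc_mortality, apc_prevalence, apc_all_cause
        Signed annual percent changes used to extrapolate the GCa mortality,
        GCa prevalence and all-cause mortality surfaces to other years.
    disability_weight
        Single unstratified GCa disability weight in [0, 1].
    life_expectancy
        ``(2, n_bands)`` residual life expectancy in years.
    rr_per_gram
        Linear excess-risk slope: RR = 1 + rr_per_gram * (intake - TMREL)+.
    gca_incidence
        Optional explicit ``(2, n_bands)`` annual incidence probabilities at
        ``base_year``.  When absent, incidence is derived from prevalence and
        mortality through a one-compartment balance (see :meth:`incidence`).
    """

    all_cause_mortality: np.ndarray
    gca_mortality: np.ndarray
    gca_prevalence: np.ndarray
    life_expectancy: np.ndarray
    disability_weight: float
    rr_per_gram: float
    apc_mortality: float = 0.0
    apc_prevalence: float = 0.0
    apc_all_cause: float = 0.0
    base_year: int = 2010
    gca_incidence: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        shape = (len(SEXES), len(AGE_BANDS))
        for name in ("all_cause_mortality", "gca_mortality", "gca_prevalence",
                     "life_expectancy"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            setattr(self, name, arr)
        if self.gca_incidence is not None:
            self.gca_incidence = np.asarray(self.gca_incidence, dtype=float)
            if self.gca_incidence.shape != shape:
                raise ValueError(f"gca_incidence must have shape {shape}")
        for name in ("all_cause_mortality", "gca_mortality", "gca_prevalence"):
            arr = getattr(self, name)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.disability_weight <= 1.0:
            raise ValueError("disability_weight must lie in [0, 1]")
        if self.rr_per_gram < 0:
            raise ValueError("rr_per_gram must be nonnegative")
        if np.any(np.diff(self.life_expectancy, axis=1) >= 0):
            raise ValueError("life_expectancy must decrease with age within sex")

    # -- year-resolved lookups (vectorised over sex/band index arrays) -----

    def all_cause(self, sex_idx, band_idx, year: int):
        return extrapolate_rate(
            self.all_cause_mortality[sex_idx, band_idx],
            self.apc_all_cause, year - self.base_year)

    def gca_mort(self, sex_idx, band_idx, year: int):
        return extrapolate_rate(
            self.gca_mortality[sex_idx, band_idx],
            self.apc_mortality, year - self.base_year)

    def gca_prev(self, sex_idx, band_idx, year: int):
        return extrapolate_rate(
            self.gca_prevalence[sex_idx, band_idx],
            self.apc_prevalence, year - self.base_year)

    def case_fatality(self, sex_idx, band_idx, year: int):
        """Annual GCa death probability among prevalent cases: the
        population-level GCa mortality divided by prevalence (capped)."""
        prev = np.asarray(self.gca_prev(sex_idx, band_idx, year), dtype=float)
        mort = np.asarray(self.gca_mort(sex_idx, band_idx, year), dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            cf = np.where(prev > 0, mort / np.maximum(prev, 1e-12), 0.0)
        return np.clip(cf, 0.0, 0.95)

    def incidence(self, sex_idx, band_idx, year: int):
        """Baseline annual GCa incidence probability among the susceptible.

        Uses the explicit table when provided; otherwise a remission-free
        one-compartment balance: at equilibrium inflow i*(1-P) matches the
        outflow P*(case fatality + background mortality).
        """
        if self.gca_incidence is not None:
            return extrapolate_rate(
                self.gca_incidence[sex_idx, band_idx],
                self.apc_prevalence, year - self.base_year)
        prev = np.asarray(self.gca_prev(sex_idx, band_idx, year), dtype=float)
        exit_rate = self.case_fatality(sex_idx, band_idx, year) + \
            np.asarray(self.all_cause(sex_idx, band_idx, year), dtype=float)
        inc = prev * exit_rate / np.maximum(1.0 - prev, 1e-12)
        return np.clip(inc, 0.0, 1.0)

    def residual_life_expectancy(self, sex_idx, band_idx):
        return self.life_expectancy[sex_idx, band_idx]

    # -- CSV round-trip ----------------------------------------------------

    _ARRAY_MEASURES = ("all_cause_mortality", "gca_mortality", "gca_prevalence",
                       "life_expectancy")
    _SCALAR_MEASURES = ("disability_weight", "rr_per_gram", "apc_mortality",
                        "apc_prevalence", "apc_all_cause", "base_year")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        measures = self._ARRAY_MEASURES + (
            ("gca_incidence",) if self.gca_incidence is not None else ())
        for measure in measures:
            arr = getattr(self, measure)
            for i, sex in enumerate(SEXES):
                for j, band in enumerate(AGE_BANDS):
                    rows.append((measure, sex, band, arr[i, j]))
        for measure in self._SCALAR_MEASURES:
            rows.append((measure, "", "", float(getattr(self, measure))))
        return pd.DataFrame(rows, columns=["measure", "sex", "age_band", "value"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RateTables":
        kwargs: dict = {}
        shape = (len(SEXES), len(AGE_BANDS))
        for measure in cls._ARRAY_MEASURES + ("gca_incidence",):
            sub = df[df["measure"] == measure]
            if sub.empty:
                if measure == "gca_incidence":
                    continue
                raise ValueError(f"rates table missing measure {measure!r}")
            arr = np.zeros(shape)
            for _, row in sub.iterrows():
                arr[SEXES.index(row["sex"]), band_index(row["age_band"])] = row["value"]
            kwargs[measure] = arr
        for measure in cls._SCALAR_MEASURES:
            sub = df[df["measure"] == measure]
            if sub.empty:
                raise ValueError(f"rates table missing measure {measure!r}")
            kwargs[measure] = float(sub["value"].iloc[0])
        kwargs["base_year"] = int(kwargs["base_year"])
        return cls(**kwargs)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "RateTables":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))
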