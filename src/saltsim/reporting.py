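"""Summary quantities: percent reductions, burden shares, equity ratios,
validation relative errors, and stratified breakdowns.

Every reported percent is emitted together with its own numerator and
denominator, so each value is recomputable from the same table row.
Percents are rounded to two decimals, half-up.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from itertools import permutations
from typing import Mapping

import pandas as pd

from .burden import BurdenResult

__all__ = [
    "round_half_up",
    "percent_reduction",
    "burden_share",
    "equity_ratio",
    "relative_error",
    "stratified_summary",
    "averted_summary",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), matching printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent_reduction(averted: float, baseline: float) -> float:
    """100 x averted / baseline, to two decimals (half-up).

    ``averted`` and ``baseline`` are cumulative DALY burdens in the same
    units (e.g. per-capita DALYs averted by an intervention over the
    baseline attributable burden)."""
    if baseline <= 0:
        raise ValueError("baseline burden must be positive")
    if averted < 0:
        raise ValueError("averted burden must be nonnegative")
    return round_half_up(100.0 * averted / baseline, 2)


def burden_share(component: float, total: float) -> float:
    """Percent share of a burden component in a total (unrounded)."""
    if total <= 0:
        raise ValueError("total burden must be positive")
    return 100.0 * component / total


def equity_ratio(per_capita_by_region: Mapping[str, float]) -> dict[str, float]:
    """Pairwise per-capita burden ratios between regions, keyed 'a/b'."""
    for region, value in per_capita_by_region.items():
        if value <= 0:
            raise ValueError(f"per-capita burden for {region!r} must be positive")
    return {f"{a}/{b}": per_capita_by_region[a] / per_capita_by_region[b]
            for a, b in permutations(per_capita_by_region, 2)}


def relative_error(model_value: float, reference_value: float) -> float:
    """Signed percent relative error of a model value against a literature
    reference: 100 x (model - reference) / reference."""
    if reference_value == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (model_value - reference_value) / reference_value


def stratified_summary(result: BurdenResult, by: str) -> pd.DataFrame:
    """Per-stratum DALY table (total, per 1000, person counts) for one run."""
    if by not in result.strata:
        raise ValueError(
            f"unknown stratifier {by!r}; available: {sorted(result.strata)}")
    return result.strata[by].copy()


def averted_summary(baseline: BurdenResult, intervention: BurdenResult,
                    by: str) -> pd.DataFrame:
    """Per-stratum averted burden of an intervention against baseline.

    Both results must stem from the same population under common random
    numbers.  Adds per-capita averted burden and the percent of the
    stratum's baseline burden averted."""
    base = stratified_summary(baseline, by).set_index(by)
    scen = stratified_summary(intervention, by).set_index(by)
    out = pd.DataFrame(index=base.index)
    out["baseline_daly"] = base["daly"]
    out["scenario_daly"] = scen["daly"].reindex(base.index).fillna(0.0)
    out["averted_daly"] = out["baseline_daly"] - out["scenario_daly"]
    out["n_persons"] = base["n_persons"]
    out["averted_per_1000"] = 1000.0 * out["averted_daly"] / out["n_persons"].clip(lower=1)
    out["percent_averted"] = [
        percent_reduction(max(a, 0.0), b) if b > 0 else 0.0
        for a, b in zip(out["averted_daly"], out["baseline_daly"])]
    return out.reset_index()
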