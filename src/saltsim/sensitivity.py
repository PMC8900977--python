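"""One-way deterministic and probabilistic (Monte-Carlo) sensitivity analysis.

The one-way analysis reruns the model with each parameter alone perturbed
by +/-10 % under the baseline seed.  The probabilistic analysis draws every
uncertain parameter jointly from its distribution once per run (10,000 runs
at full scale), reruns the model, and summarises each outcome by its mean
and an equal-tailed empirical credible interval.  Per-run seeds are spawned
deterministically from the root seed, so runs are independent, reproducible
and order-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PsaSpec", "UncertainEstimate", "one_way", "psa", "sample_distribution"]

#: Distribution families accepted in a PSA spec.
_FAMILIES = ("point", "normal", "lognormal", "beta", "uniform", "pert")


@dataclass(frozen=True)
class UncertainEstimate:
    """Mean of draws with an equal-tailed credible interval."""

    point: float
    lower: float
    upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not self.lower <= self.point <= self.upper:
            raise ValueError("interval must bracket the point estimate")


@dataclass
class PsaSpec:
    """Probabilistic-sensitivity-analysis settings.

    ``distributions`` maps parameter name to a spec dict such as
    ``{"kind": "beta", "a": 2, "b": 5}``, ``{"kind": "lognormal",
    "mu": 0, "sigma": 0.2}``, ``{"kind": "pert", "min": 0.6, "mode": 1.5,
    "max": 2.0}`` or ``{"kind": "point", "value": 0.2}``.
    """

    distributions: Mapping[str, Mapping]
    n_runs: int = 10_000
    interval_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0 < self.interval_level < 1:
            raise ValueError("interval_level must lie in (0, 1)")
        for name, spec in self.distributions.items():
            _validate_distribution(name, spec)


def _validate_distribution(name: str, spec: Mapping) -> None:
    kind = spec.get("kind")
    if kind not in _FAMILIES:
        raise ValueError(f"parameter {name!r}: unknown distribution kind {kind!r}")
    if kind == "beta" and (spec.get("a", 0) <= 0 or spec.get("b", 0) <= 0):
        raise ValueError(f"parameter {name!r}: beta needs positive a, b")
    if kind == "pert" and not (spec.get("min", 0) < spec.get("mode", 0)
                               < spec.get("max", 0)):
        raise ValueError(f"parameter {name!r}: pert needs min < mode < max")
    if kind in ("normal", "lognormal") and spec.get("sigma", -1) < 0:
        raise ValueError(f"parameter {name!r}: sigma must be nonnegative")
    if kind == "uniform" and not spec.get("low", 0) <= spec.get("high", 0):
        raise ValueError(f"parameter {name!r}: uniform needs low <= high")
    if kind == "point" and "value" not in spec:
        raise ValueError(f"parameter {name!r}: point mass needs a value")


def sample_distribution(spec: Mapping, rng: np.random.Generator, size=None):
    """Draw from a validated distribution spec."""
    kind = spec["kind"]
    if kind == "point":
        v = spec["value"]
        return v if size is None else np.full(size, v, dtype=float)
    if kind == "normal":
        return rng.normal(spec.get("mu", 0.0), spec["sigma"], size=size)
    if kind == "lognormal":
        return rng.lognormal(spec.get("mu", 0.0), spec["sigma"], size=size)
    if kind == "beta":
        return rng.beta(spec["a"], spec["b"], size=size)
    if kind == "uniform":
        return rng.uniform(spec["low"], spec["high"], size=size)
    if kind == "pert":
        a, m, b = spec["min"], spec["mode"], spec["max"]
        s = spec.get("shape", 4.0)
        alpha = 1.0 + s * (m - a) / (b - a)
        beta = 1.0 + s * (b - m) / (b - a)
        return a + (b - a) * stats.beta.rvs(alpha, beta, size=size, random_state=rng)
    raise ValueError(f"unknown distribution kind {kind!r}")


def _as_outcome_dict(result) -> dict[str, float]:
    if isinstance(result, Mapping):
        return {k: float(v) for k, v in result.items()}
    return {"outcome": float(result)}


def one_way(runner: Callable[[Mapping[str, float]], Mapping[str, float] | float],
            baseline: Mapping[str, float], delta: float = 0.10) -> pd.DataFrame:
    """Rerun the model with each parameter alone at (1 +/- delta) x baseline.

    Returns one row per (parameter, outcome) with the baseline, low and high
    outputs; a runner failure on a perturbed input is recorded in the
    ``error`` column instead of aborting the table.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    base_out = _as_outcome_dict(runner(dict(baseline)))
    rows = []
    for name, value in baseline.items():
        outs: dict[str, dict[str, float]] = {}
        errors = []
        for side, mult in (("low", 1.0 - delta), ("high", 1.0 + delta)):
            params = dict(baseline)
            params[name] = value * mult
            try:
                outs[side] = _as_outcome_dict(runner(params))
            except Exception as exc:  # recorded per-row, not fatal
                outs[side] = {}
                errors.append(f"{side}: {exc}")
        for outcome, base_val in base_out.items():
            rows.append({
                "parameter": name,
                "outcome": outcome,
                "baseline": base_val,
                "low": outs["low"].get(outcome, np.nan),
                "high": outs["high"].get(outcome, np.nan),
                "error": "; ".join(errors),
            })
    return pd.DataFrame(rows)


def psa(runner: Callable[[Mapping[str, float], int], Mapping[str, float] | float],
        spec: PsaSpec) -> tuple[pd.DataFrame, dict[str, UncertainEstimate]]:
    """Monte-Carlo parameter uncertainty propagation.

    For each of ``spec.n_runs`` runs, every parameter is drawn from its
    distribution with an independent child generator of the root seed and
    the runner is called as ``runner(params, run_seed)``.  Returns the draw
    table (one row per run: parameters and outcomes) and, per outcome, the
    mean with empirical equal-tailed interval at ``spec.interval_level``.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_runs)
    rows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        run_seed = int(child.generate_state(1)[0] % (2 ** 31))
        params = {name: float(sample_distribution(d, rng))
                  for name, d in spec.distributions.items()}
        out = _as_outcome_dict(runner(params, run_seed))
        rows.append({"run": i, **params, **out})
    draws = pd.DataFrame(rows)
    outcome_cols = [c for c in draws.columns
                    if c not in ("run", *spec.distributions)]
    tail = (1.0 - spec.interval_level) / 2.0
    estimates = {}
    for col in outcome_cols:
        vals = draws[col].to_numpy(float)
        lo, hi = np.percentile(vals, [100 * tail, 100 * (1 - tail)])
        estimates[col] = UncertainEstimate(
            point=float(vals.mean()), lower=float(lo), upper=float(hi),
            level=spec.interval_level)
    return draws, estimates
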