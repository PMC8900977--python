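"""End-to-end driver: generate inputs, build the cohort, run scenarios,
compute attributable burden, and write the report tables.

The standard analysis runs the no-intervention world, each intervention
scenario, and a shared TMREL counterfactual on the same population under
common random numbers.  Attributable burden per scenario is its DALY total
minus the counterfactual's; the burden a scenario averts is the baseline
attributable burden minus its own.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._demography import REGIONS
from .burden import BurdenConfig, BurdenResult, attributable_burden, compute_burden
from .disease import DiseaseConfig, simulate
from .exposure import (
    TmrelSpec,
    TrendParams,
    estimate_usual_intake,
    fit_log_decline,
    province_year_means,
)
from .interventions import (
    SPOON_SIZES_MG,
    SUBSTITUTE_FRACTIONS,
    ScenarioSpec,
)
from .population import Population, build_population
from .ratetables import RateTables
from .reporting import burden_share, equity_ratio, percent_reduction, relative_error
from .synthetic_data import (
    GeneratorConfig,
    generate_census,
    generate_fct,
    generate_rate_tables,
    generate_recalls,
)

__all__ = [
    "ModelInputs",
    "ScenarioResult",
    "Comparison",
    "default_scenarios",
    "parse_scenario",
    "prepare_inputs",
    "run_scenario",
    "compare_scenarios",
    "write_report",
    "make_psa_runner",
    "make_one_way_runner",
]


@dataclass
class ModelInputs:
    """Everything a scenario run needs, prepared once and shared."""

    gen_config: GeneratorConfig
    census: pd.DataFrame
    fct: pd.DataFrame
    recalls: pd.DataFrame
    rates: RateTables
    usual: pd.DataFrame
    trends: dict[str, TrendParams]
    population: Population
    disease_config: DiseaseConfig
    burden_config: BurdenConfig

    def with_tmrel(self, tmrel_g: float) -> "ModelInputs":
        """Copy with every individual's TMREL (and excess-dependent initial
        state) reset to a new shared draw."""
        df = self.population.df.copy()
        df["tmrel_g"] = float(tmrel_g)
        non_gca = df["state"] != "gca"
        excess = df["usual_sodium_g"] > float(tmrel_g)
        df.loc[non_gca, "state"] = np.where(excess[non_gca], "sodium_excess", "healthy")
        pop = Population(df=df, base_year=self.population.base_year)
        return replace(self, population=pop)


@dataclass
class ScenarioResult:
    scenario: ScenarioSpec
    log: pd.DataFrame
    burden: BurdenResult
    attributable_daly: float

    @property
    def attributable_per_1000(self) -> float:
        return 1000.0 * self.attributable_daly / self.burden.population_size


@dataclass
class Comparison:
    """Scenario results sharing one population, seed and counterfactual."""

    counterfactual: BurdenResult
    results: dict[str, ScenarioResult] = field(default_factory=dict)
    baseline_id: str = "none"

    @property
    def baseline(self) -> ScenarioResult:
        return self.results[self.baseline_id]

    def averted_daly(self, scenario_id: str) -> float:
        return (self.baseline.attributable_daly
                - self.results[scenario_id].attributable_daly)

    def percent_reduction(self, scenario_id: str) -> float:
        base = self.baseline.attributable_daly
        if base <= 0:  # tiny cohorts can carry no attributable burden
            return 0.0
        return percent_reduction(max(self.averted_daly(scenario_id), 0.0), base)


def default_scenarios() -> list[ScenarioSpec]:
    """Baseline plus every spoon size and substitute fraction of the study."""
    scenarios = [ScenarioSpec(kind="none")]
    scenarios += [ScenarioSpec(kind="spoon", spoon_sodium_mg=s) for s in SPOON_SIZES_MG]
    scenarios += [ScenarioSpec(kind="substitute", substitute_fraction=f)
                  for f in SUBSTITUTE_FRACTIONS]
    return scenarios


def parse_scenario(text: str) -> ScenarioSpec:
    """Parse 'none', 'spoon-<mg>', 'substitute-<fraction>' or a YAML path."""
    if text.endswith((".yaml", ".yml")):
        return ScenarioSpec.from_yaml(text)
    if text == "none":
        return ScenarioSpec(kind="none")
    if text.startswith("spoon-"):
        return ScenarioSpec(kind="spoon",
                            spoon_sodium_mg=float(text.removeprefix("spoon-").removesuffix("mg")))
    if text.startswith("substitute-"):
        return ScenarioSpec(kind="substitute",
                            substitute_fraction=float(text.removeprefix("substitute-")))
    raise ValueError(f"cannot parse scenario {text!r}")


def prepare_inputs(gen_config: GeneratorConfig | None = None,
                   n_persons: int = 10_000, seed: int = 0,
                   tmrel_g: float | None = None,
                   horizon: tuple[int, int] = (2010, 2030)) -> ModelInputs:
    """Generate inputs, estimate exposure, fit trends and build the cohort.

    ``tmrel_g`` defaults to the PERT mode (1.5 g/day); probabilistic runs
    re-draw it per iteration through :meth:`ModelInputs.with_tmrel`.
    """
    if gen_config is None:
        gen_config = GeneratorConfig(seed=seed)
    census = generate_census(gen_config)
    fct = generate_fct(gen_config)
    recalls = generate_recalls(census, fct, gen_config)
    rates = generate_rate_tables(gen_config)

    usual_all = estimate_usual_intake(recalls, fct)
    means = province_year_means(usual_all)
    trends = {}
    for prov, sub in means.groupby("province"):
        series = dict(zip(sub["survey_year"], sub["mean_g"]))
        trends[prov] = fit_log_decline(
            series, province=prov, megacity=gen_config.provinces[prov].megacity)

    # one row per person: the latest observed wave
    usual = (usual_all.sort_values("survey_year")
             .groupby("person_id", as_index=False).last())

    tmrel = TmrelSpec().mode_g if tmrel_g is None else float(tmrel_g)
    pop_seed = int(np.random.SeedSequence(seed, spawn_key=(10,)).generate_state(1)[0]
                   % (2 ** 31))
    population = build_population(census, usual, n_persons, seed=pop_seed,
                                  tmrel_g=tmrel, rates=rates,
                                  base_year=horizon[0])
    disease_config = DiseaseConfig(trends=trends, horizon=horizon)
    burden_config = BurdenConfig.from_rates(rates, base_year=horizon[0])
    return ModelInputs(gen_config=gen_config, census=census, fct=fct,
                       recalls=recalls, rates=rates, usual=usual, trends=trends,
                       population=population, disease_config=disease_config,
                       burden_config=burden_config)


def run_scenario(inputs: ModelInputs, scenario: ScenarioSpec, seed: int,
                 force_tmrel: bool = False) -> pd.DataFrame:
    return simulate(inputs.population, inputs.rates, scenario,
                    inputs.disease_config, seed, force_tmrel=force_tmrel)


def compare_scenarios(inputs: ModelInputs, scenarios: list[ScenarioSpec],
                      seed: int) -> Comparison:
    """Run every scenario plus the TMREL counterfactual under one seed."""
    if not any(s.kind == "none" for s in scenarios):
        scenarios = [ScenarioSpec(kind="none")] + list(scenarios)
    n = len(inputs.population)
    log_cf = run_scenario(inputs, ScenarioSpec(kind="none"), seed, force_tmrel=True)
    cf_burden = compute_burden(log_cf, inputs.burden_config, n)
    comparison = Comparison(counterfactual=cf_burden)
    for scenario in scenarios:
        log = run_scenario(inputs, scenario, seed)
        burden = compute_burden(log, inputs.burden_config, n)
        attr = attributable_burden(log, log_cf, inputs.burden_config)
        comparison.results[scenario.scenario_id] = ScenarioResult(
            scenario=scenario, log=log, burden=burden, attributable_daly=attr)
    return comparison


def _attributable_by(comparison: Comparison, inputs: ModelInputs,
                     scenario_id: str, by: str) -> pd.DataFrame:
    """Per-stratum attributable DALYs: scenario minus counterfactual."""
    scen = comparison.results[scenario_id].burden.strata[by].set_index(by)
    cf = comparison.counterfactual.strata[by].set_index(by)
    out = pd.DataFrame(index=scen.index.union(cf.index))
    out["attributable_daly"] = (scen["daly"].reindex(out.index).fillna(0.0)
                                - cf["daly"].reindex(out.index).fillna(0.0))
    out["n_persons"] = scen["n_persons"].reindex(out.index).fillna(
        cf["n_persons"].reindex(out.index)).fillna(0)
    out["attributable_per_1000"] = (1000.0 * out["attributable_daly"]
                                    / out["n_persons"].clip(lower=1))
    return out.reset_index(names=by)


def write_report(comparison: Comparison, inputs: ModelInputs, outdir,
                 validation_references: dict[str, float] | None = None,
                 all_disease_daly_reference: float | None = None) -> dict[str, str]:
    """Write burden.csv, table2.csv, table3.csv, shares.csv, equity.csv and
    (when reference values are supplied) validation.csv."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    rows = []
    for sid, res in comparison.results.items():
        rows.append({
            "scenario": sid, "yll": res.burden.yll, "yld": res.burden.yld,
            "daly": res.burden.daly, "daly_per_1000": res.burden.daly_per_1000,
            "attributable_daly": res.attributable_daly,
            "attributable_per_1000": res.attributable_per_1000,
        })
    burden_df = pd.DataFrame(rows)
    paths["burden"] = os.path.join(outdir, "burden.csv")
    burden_df.to_csv(paths["burden"], index=False)

    # dose-response table: percent of baseline attributable burden averted
    base_attr_pc = comparison.baseline.attributable_per_1000
    t2 = []
    for sid, res in comparison.results.items():
        if res.scenario.kind == "none":
            continue
        averted_pc = (comparison.averted_daly(sid) * 1000.0
                      / res.burden.population_size)
        t2.append({
            "scenario": sid, "kind": res.scenario.kind,
            "dose": (res.scenario.spoon_sodium_mg if res.scenario.kind == "spoon"
                     else res.scenario.substitute_fraction),
            "averted_daly_per_1000": averted_pc,
            "baseline_attributable_per_1000": base_attr_pc,
            "percent_reduction": comparison.percent_reduction(sid),
        })
    paths["table2"] = os.path.join(outdir, "table2.csv")
    pd.DataFrame(t2).to_csv(paths["table2"], index=False)

    # province table: averted per-1000 in province over the national
    # per-capita baseline attributable burden (shared denominator)
    t3 = []
    base_by_prov = _attributable_by(comparison, inputs, comparison.baseline_id,
                                    "province").set_index("province")
    for sid, res in comparison.results.items():
        if res.scenario.kind == "none":
            continue
        scen_by_prov = _attributable_by(comparison, inputs, sid,
                                        "province").set_index("province")
        for prov in base_by_prov.index:
            averted_pc = (base_by_prov.loc[prov, "attributable_per_1000"]
                          - scen_by_prov.loc[prov, "attributable_per_1000"])
            t3.append({
                "province": prov, "scenario": sid,
                "averted_daly_per_1000": averted_pc,
                "national_baseline_attributable_per_1000": base_attr_pc,
                "percent_reduction": percent_reduction(
                    max(averted_pc, 0.0), base_attr_pc) if base_attr_pc > 0 else 0.0,
            })
    paths["table3"] = os.path.join(outdir, "table3.csv")
    pd.DataFrame(t3).to_csv(paths["table3"], index=False)

    # attributable share of each scenario's total simulated GCa burden
    shares = []
    for sid, res in comparison.results.items():
        shares.append({
            "scenario": sid,
            "attributable_daly": res.attributable_daly,
            "total_daly": res.burden.daly,
            "attributable_share_percent": (
                burden_share(res.attributable_daly, res.burden.daly)
                if res.burden.daly > 0 else 0.0),
        })
        if all_disease_daly_reference:
            shares[-1]["share_of_all_disease_percent"] = burden_share(
                res.attributable_daly, all_disease_daly_reference)
    paths["shares"] = os.path.join(outdir, "shares.csv")
    pd.DataFrame(shares).to_csv(paths["shares"], index=False)

    # regional equity: baseline attributable per-capita burden and ratios
    by_region = _attributable_by(comparison, inputs, comparison.baseline_id,
                                 "region").set_index("region")
    per_capita = {r: max(by_region.loc[r, "attributable_per_1000"], 1e-12)
                  for r in REGIONS if r in by_region.index}
    ratios = equity_ratio(per_capita)
    eq_rows = [{"measure": f"attributable_per_1000[{r}]", "value": v}
               for r, v in per_capita.items()]
    eq_rows += [{"measure": f"ratio[{k}]", "value": v} for k, v in ratios.items()]
    paths["equity"] = os.path.join(outdir, "equity.csv")
    pd.DataFrame(eq_rows).to_csv(paths["equity"], index=False)

    if validation_references:
        model_values = model_validation_values(comparison, inputs)
        v_rows = []
        for name, ref in validation_references.items():
            if name not in model_values:
                raise KeyError(f"no model value for validation quantity {name!r}")
            v_rows.append({
                "quantity": name, "model": model_values[name], "reference": ref,
                "relative_error_percent": relative_error(model_values[name], ref),
            })
        paths["validation"] = os.path.join(outdir, "validation.csv")
        pd.DataFrame(v_rows).to_csv(paths["validation"], index=False)
    return paths


def model_validation_values(comparison: Comparison,
                            inputs: ModelInputs) -> dict[str, float]:
    """Model quantities comparable against user-supplied literature values:
    2015 mean projected sodium intake by region and cumulative DALY totals."""
    log = comparison.baseline.log
    y2015 = log[log["year"] == 2015]
    values = {f"mean_sodium_2015[{region}]": float(sub["intake_g"].mean())
              for region, sub in y2015.groupby("region")}
    values["baseline_daly_per_1000"] = comparison.baseline.burden.daly_per_1000
    values["attributable_daly_per_1000"] = comparison.baseline.attributable_per_1000
    return values


# -- sensitivity-analysis runners ------------------------------------------

def make_psa_runner(inputs: ModelInputs,
                    scenarios: tuple[ScenarioSpec, ...] = (
                        ScenarioSpec(kind="spoon", spoon_sodium_mg=788.0),
                        ScenarioSpec(kind="substitute", substitute_fraction=0.95),
                    )):
    """Runner for :func:`saltsim.sensitivity.psa`.

    Per run: reset the shared TMREL draw, override the dose-response slope
    and disability weight, rerun baseline + scenarios + counterfactual, and
    report attributable burden per 1000 and each scenario's percent
    reduction."""

    def runner(params, run_seed: int):
        inp = inputs
        if "tmrel_g" in params:
            inp = inp.with_tmrel(params["tmrel_g"])
        if "rr_per_gram" in params:
            inp = replace(inp, disease_config=replace(
                inp.disease_config, rr_per_gram=float(params["rr_per_gram"])))
        if "disability_weight" in params:
            inp = replace(inp, burden_config=replace(
                inp.burden_config,
                disability_weight=float(np.clip(params["disability_weight"], 0, 1))))
        comparison = compare_scenarios(inp, list(scenarios), seed=run_seed)
        out = {"attributable_daly_per_1000":
               comparison.baseline.attributable_per_1000}
        for s in scenarios:
            out[f"percent_reduction[{s.scenario_id}]"] = \
                comparison.percent_reduction(s.scenario_id)
        return out

    return runner


def make_one_way_runner(inputs: ModelInputs, seed: int,
                        scenario: ScenarioSpec | None = None):
    """Runner for :func:`saltsim.sensitivity.one_way`; parameters:
    rr_per_gram, disability_weight, tmrel_g, discount_rate, intake_scale."""
    scenario = scenario or ScenarioSpec(kind="substitute", substitute_fraction=0.95)

    def runner(params):
        inp = inputs
        if "tmrel_g" in params:
            inp = inp.with_tmrel(params["tmrel_g"])
        if "intake_scale" in params and params["intake_scale"] != 1.0:
            df = inp.population.df.copy()
            df["usual_sodium_g"] *= float(params["intake_scale"])
            inp = replace(inp, population=Population(df, inp.population.base_year))
        if "rr_per_gram" in params:
            inp = replace(inp, disease_config=replace(
                inp.disease_config, rr_per_gram=float(params["rr_per_gram"])))
        bcfg_kwargs = {}
        if "disability_weight" in params:
            bcfg_kwargs["disability_weight"] = float(
                np.clip(params["disability_weight"], 0, 1))
        if "discount_rate" in params:
            bcfg_kwargs["discount_rate"] = max(float(params["discount_rate"]), 0.0)
        if bcfg_kwargs:
            inp = replace(inp, burden_config=replace(inp.burden_config, **bcfg_kwargs))
        comparison = compare_scenarios(inp, [scenario], seed=seed)
        return {
            "attributable_daly_per_1000": comparison.baseline.attributable_per_1000,
            "percent_reduction": comparison.percent_reduction(scenario.scenario_id),
        }

    return runner
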