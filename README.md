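# saltsim

A discrete-time stochastic microsimulation of excess dietary sodium and the
gastric-cancer (GCa) burden it causes in a multi-province Chinese population,
with two culturally tailored salt-reduction interventions: salt-restriction
spoons and low-sodium salt substitutes.

**Who it is for.** Epidemiological modellers who want a tested, reusable
implementation of comparative risk assessment for dietary sodium: usual-intake
estimation from 24-h recalls, exposure projection, lagged linear dose-response,
DALY accounting with discounting, counterfactual attribution under common
random numbers, and one-way plus probabilistic sensitivity analysis. Because
the original survey/census/rate inputs are restricted, the package ships a
synthetic-data generator that reproduces their statistical structure
(right-skewed province/sex/age-specific intake, a source decomposition
dominated by added cooking salt, declining 2004–2011 intake, age-increasing
mortality), so every stage runs and is testable without any download.

## The model

Each simulated individual carries a province, sex, integer age, a usual daily
sodium intake S (g/day) decomposed into six source categories, and one of four
health states: healthy, sodium-excess, GCa, dead. Each year from 2010 to 2030
the model (1) updates risk factors (age; intake projected along a province
trend S(t) = a − b·ln(t − 2004 + 1), held constant in megacities), (2)
re-classifies sodium-excess status against a risk-free threshold
TMREL ~ PERT(0.6, 1.5, 2.0) g/day, (3) draws first-episode GCa incidence with

    RR = 1 + β · max(0, S(t − L) − TMREL),    L = 8-year mean exposure lag,

(4) draws binomial deaths (all-cause, plus GCa case fatality for prevalent
cases), and (5) applies the intervention to the sodium source mix:

* **spoon(m)** — caps added-salt sodium at the spoon content m ∈ {197, 394,
  591, 788} mg/day (¼ to 1 of a 2-g spoon at 39.4 % sodium);
* **substitute(f)** — replaces a fraction f ∈ [0, 1] of the five high-sodium
  categories by a 65 % NaCl / 25 % KCl / 10 % MgSO₄ blend, multiplying the
  replaced sodium by 0.65.

Burden is net-present DALYs = YLL + YLD at 3 %/yr discount; the burden
*attributable* to excess sodium is DALY(factual) − DALY(everyone at TMREL),
both worlds run with common random numbers. Averted burden and percent
reductions per scenario follow from the same contrast.

## Worked example

Intervention contrasts are Monte-Carlo differences, so stable estimates come
from averaging the coupled comparison over simulation seeds:

```python
import numpy as np
from saltsim import pipeline

inputs = pipeline.prepare_inputs(n_persons=2000, seed=7)
scenarios = pipeline.default_scenarios()
base, averted = [], {"spoon-788mg": [], "substitute-0.95": []}
for seed in range(10):
    comp = pipeline.compare_scenarios(inputs, scenarios, seed=seed)
    base.append(comp.baseline.attributable_per_1000)
    for sid in averted:
        averted[sid].append(1000 * comp.averted_daly(sid) / 2000)
print(f"baseline attributable DALYs/1000 (10-seed mean): {np.mean(base):.2f}")
for sid, v in averted.items():
    print(f"{sid}: averted {np.mean(v):.2f} DALYs/1000 "
          f"({100 * np.mean(v) / np.mean(base):.1f}% of attributable burden)")
```

which prints

```
baseline attributable DALYs/1000 (10-seed mean): 49.62
spoon-788mg: averted 14.85 DALYs/1000 (29.9% of attributable burden)
substitute-0.95: averted 9.45 DALYs/1000 (19.1% of attributable burden)
```

i.e. in this synthetic world excess sodium costs ≈ 50 discounted DALYs per
1000 persons over 2010–2030; a one-spoon cap averts ≈ 30 % of that burden
and a 95 % substitute programme ≈ 19 % (the relative ranking of the two
strategies depends on how much sodium comes from added salt — see
`docs/methods.md`). The same analysis is available from the shell:

```
saltsim generate --seed 1 --out inputs/
saltsim compare --seed 1 --n 2000 --out report/
saltsim report --in report/
saltsim psa --seed 1 --n-runs 200 --out psa/
```

`compare` writes `burden.csv`, `table2.csv` (intervention dose-response with
numerator, denominator and percent per row), `table3.csv` (province ×
strategy), `shares.csv`, `equity.csv`.

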