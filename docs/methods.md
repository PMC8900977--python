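# Methods

## Model structure

`saltsim` is a closed-cohort, discrete-time (annual) stochastic
microsimulation over 2010–2030. Individuals are exchangeable within
(province, sex, age-band) strata; there are no births or migration, and only
first episodes of gastric cancer (GCa) are modelled — no staging, treatment
or recurrence, and no other sodium-related outcomes (e.g. CVD). A person is
in exactly one of four states — healthy, sodium-excess, GCa, dead — with
dead absorbing. The annual loop applies, in order: intervention on the
sodium source mix, risk-factor update (age, projected intake), excess
re-classification, GCa incidence, deaths. The intervention feeds the same
year's exposure, so through the lag its first effect on incidence arrives
`start_year + L`.

## Exposure

**Usual intake.** Per-record sodium is `amount_g × mg_per_100g / 10⁵` g.
Short-term recalls (3 days per wave) mix day-to-day variation into observed
person means, so usual intake shrinks each person-wave mean toward its
(province, sex, age-band, wave) stratum mean with the reliability factor
`B / (B + W/k)`, where B and W are between- and within-person variance
components from a one-way method-of-moments ANOVA (person-wave as factor,
stratum-centred day totals) and k the observed days. Estimation is on the
natural scale; the shrinkage target and the contract examples are stated on
that scale, and a log-scale variant would change estimates only at the few
percent level for the CVs involved. Source shares are category sums over all
a person's recall days.

**Trend.** Province means follow S(t) = a − b·ln(t − 2004 + 1), least-squares
fitted to the four survey waves (2004, 2006, 2009, 2011). The three
megacities, observed only in 2011, are held constant at their 2011 level.
Each person's trajectory is the province trend plus a constant personal
offset anchored at 2010, preserving within-province rank order (which the
intervention contrast needs). Years before 2004 evaluate the trend at its
2004 level; projections are floored at 0.6 g/day, the bottom of the
risk-free range, to prevent non-physical intakes.

**TMREL.** The risk-free intake is PERT(min 0.6, mode 1.5, max 2.0) g/day
with the classic shape 4, i.e. Beta(1 + 4(m−a)/(b−a), 1 + 4(b−m)/(b−a))
rescaled; its mean is (a + 4m + b)/6 = 1.4333. It is a parameter-uncertainty
quantity, not individual heterogeneity: deterministic runs fix it at the
mode, and each probabilistic-sensitivity iteration draws one value shared by
all individuals.

## Disease dynamics

The dose-response is linear above threshold: RR = 1 + β·(S − TMREL)₊ with
β = `rr_per_gram` (default 0.20 /g, giving RR ≈ 1.5 at typical adult excess).
Incidence at year y uses exposure at y − L; the lag defaults to a fixed
L = 8 years (an individual Poisson(8) option exists), with pre-2010 exposure
back-filled from the trend over 2002–2009. Baseline incidence among the
susceptible is derived from prevalence P, population GCa mortality and
all-cause mortality m through a remission-free one-compartment balance,
i = P·(case fatality + m)/(1 − P), with case fatality = GCa mortality / P
(capped at 0.95); an explicit incidence table can replace the derivation.
Deaths combine all-cause mortality with GCa case fatality for prevalent
cases (two coupled binomial draws; the GCa draw decides cause attribution);
sodium-excess status affects mortality only through the GCa pathway. GCa
mortality, prevalence and all-cause mortality extrapolate across years by
constant annual percent changes, `rate·(1 + apc/100)^Δt`, clamped to [0, 1].

**Common random numbers.** Every uniform draw (adoption, lag, incidence, GCa
death, other death, optional intake noise) is made up front in a fixed order
from the run seed, so scenarios run on identical randomness. Incidence
probabilities are monotone in intake, which makes incident-case sets nested
across doses path by path; scenario differences therefore isolate the
intervention effect, and attributable burden is non-negative by construction.

## Burden accounting

DALY = YLL + YLD in net-present terms, discounted at 3 %/yr to 2010, no age
weighting, no half-cycle correction. YLL present-values the whole stream of
residual life-years behind each GCa death: Σₖ min(1, L−k)·(1+r)^−(y−2010+k)
for residual life expectancy L at the death age/sex. YLD weights each
person-year in the GCa state by a single unstratified disability weight
(default 0.288). Attribution contrasts the factual run with a counterfactual
of the same population and seed in which every person's entire exposure
history is clamped to the TMREL — a coupled two-world difference rather than
a PAF formula, which would double-count the lag structure. Averted burden of
a scenario is baseline attributable minus scenario attributable; percent
reductions are reported to two decimals, half-up, always alongside their own
numerator and denominator.

## Synthetic inputs

The generator emulates the structure the analysis assumes, not any real
records. Twelve provinces in three dietary regions (north/central/south,
central saltiest), full province × sex × 19-band census cross from a
stylised 2010-like pyramid, multinomial counts. Recalls: person effects and
day deviations are lognormal (right skew is standard for dietary sodium;
the exposure estimator does not assume the family) with log-scale SDs 0.25
between and 0.40 within person — the within:between ratio is a generator
knob, not an estimate, as no public value exists. Source shares are
Dirichlet around targets summing to 1 with added salt at 0.67; a fixed
30-item toy food-composition table spans all six categories (the smallest
set exercising matching and decomposition), including pure salt at
39,340 mg/100 g. Rates: Gompertz all-cause mortality with an infant bump,
GCa prevalence rising from age 20 with population mortality at 25 % of
prevalence — both strictly below all-cause mortality everywhere — annual
percent changes of −2/−1/−1 for GCa mortality/prevalence/all-cause, and
linearly declining residual life expectancy. All randomness flows from one
root seed through named independent streams (census/recalls/rates), so each
file is reproducible on its own and fixed seeds give byte-identical CSVs.

What the generator does **not** emulate: real food nomenclature, survey
weights and non-response, urbanicity, seasonality, urinary-sodium
calibration, and the joint geographic covariance of intake and disease
rates. Passing tests therefore demonstrate correctness of the machinery and
its statistical contracts on data with the assumed structure, not the
magnitude of any real-world burden.

## Scale, defaults and reproducibility

Default analysis scale is 10,000 individuals; tests and the acceptance
script run 2,000 (and 1,000 inside the PSA) so the whole suite and the
script each finish in about a minute — per-capita quantities are unbiased in
cohort size, only noisier. The probabilistic sensitivity analysis defaults
to 10,000 runs at full scale with per-run seeds spawned deterministically
from the root seed (order-independent, parallelisable); intervals are
equal-tailed empirical percentiles, standard for PSA. One-way analysis
perturbs each parameter alone by ±10 % under the baseline seed. PSA
distribution families (beta for probabilities/weights, lognormal for the RR
slope, PERT for the TMREL) are configuration defaults, not claims.

## Interpretation notes and limitations

At 2,000 persons a single-seed intervention contrast hinges on a handful of
coupled incident cases; percent reductions should be averaged over seeds
(the pipeline and acceptance script do so). In this synthetic world the
one-spoon cap averts more burden than 95 % substitution, because capping
added salt at 788 mg removes more sodium than a 33 % cut of the high-sodium
categories when added salt supplies two-thirds of ~4.5 g/day; the ranking
flips as the added-salt share falls, so it is a property of the exposure
decomposition rather than of the mechanics. The within-family dose-response
orderings (averted burden rising with substitute fraction, falling with
spoon size) are invariant to that and are verified under common random
numbers. The spoon is read as a hard daily cap at its sodium content; a
subtraction reading is available by transforming the source mix directly.
Uptake defaults to full compliance; partial adherence is a knob for
sensitivity use only.
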