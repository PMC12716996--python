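# Methods

`fstkit` is a desk-scale re-implementation of the rule layer of a
multi-measure, multi-indicator food-system assessment. This note documents
the models, the parameter conventions, what the synthetic data generator
does and does not emulate, the numerical choices, and the limitations.

## World state

A `WorldState` holds, for one year: per-country demography (six age groups ×
two sexes), a BMI-class distribution over five classes, a diet profile
(kcal cap⁻¹ day⁻¹ over eleven food items plus a waste ratio = supply per
intake ≥ 1), a lognormal income distribution (mean income in
Int$ 2011 PPP cap⁻¹ day⁻¹, Gini), wages, factor costs, shadow prices, and
cause × age × sex mortality rates; plus abstract grid cells carrying land
areas by class (eight crop classes, fallow, pasture, two natural forest age
classes, other natural land, built-up), protection and hotspot flags, a
range-rarity weight, water availability/withdrawal/environmental-flow terms,
a nitrogen budget and emission source terms (CO₂, CH₄, N₂O by source).
Cells are area-bearing and country-tagged, not georeferenced: every
indicator depends only on per-cell quantities, so grid resolution is
emulated by cell count.

**BMI classes.** Adults: `<18.5`, `18.5–20`, `20–25`, `25–30`, `>30`
(children use ±1/±2 s.d. bands in the same five slots). The underweight
*indicator* counts only the `<18.5` class (strict inequality, as is the
obesity threshold at 30); the underweight-eradication *measure* lifts both
sub-20 classes to the healthy class. The two thresholds are deliberately
kept distinct and configurable.

## Synthetic data generator

`generate_world(SynthConfig)` draws a world whose statistical structure
matches what the downstream stages assume: incomes log-uniform over
800–60,000 USD cap⁻¹ yr⁻¹; Gini uniform over 0.28–0.58; an age pyramid that
tilts older with income; a BMI distribution whose overweight/obese mass
rises with log income (the nutrition transition) and whose underweight mass
falls with it; diets consistent with the demand regressions at each
country's income; baseline protection of exactly 15% of each country's land
area; water withdrawals drawn up to 15% above the environmentally allowable
volume so that baseline flow violations exist; nitrogen budgets with
plausible per-hectare input/withdrawal rates; and a relative-risk table with
RR = 1 at the theoretical-minimum-risk exposure level (TMREL) and
log-linearly increasing category risks attenuating with age.

Per-country random streams derive from `(seed, country index)`, so country
*k* is identical regardless of how many countries are generated, and a fixed
seed reproduces the serialized world byte-for-byte.

What it does **not** emulate: real spatial structure and autocorrelation,
fitted (rather than shaped) regression coefficients, FAO/GBD/World Bank
magnitudes, trade flows, or any supply-side market equilibrium. Passing
tests therefore demonstrate the correctness of rules, accounting identities
and couplings — not empirical calibration to the real food system.

## Demand and anthropometrics

Dietary composition over four main groups (animal-source; empty calories;
staples incl. legumes; fruits/vegetables/nuts) follows a softmax of affine
predictors in log₁₀ income — saturating shares with the animal-source share
rising in income. The waste ratio is a scaled logistic in log income with
lower asymptote 1 (no waste) and upper asymptote `1 + span` (default span
0.65). The functional forms are package choices (the shapes, not fitted
coefficients, are what matters at desk scale); coefficients live in
`SynthConfig`. Demand is price-inelastic throughout: no price feedback on
quantities anywhere.

Mean per-capita intake is anchored to the anthropometric tables: intake by
cohort and BMI class (class multipliers 0.80/0.92/1.00/1.15/1.30 around an
age- and sex-specific requirement), aggregated with cohort populations and
class shares.

## Measures

Every measure is a pure transform `WorldState → WorldState` given a year.
Phase-in is linear from 2020 to the measure's target year (2030 for
protected-area expansion, 2050 otherwise). Phase-in interpolates the
*parameter*, never the state: a floor rises as `f · floor`, a cap relaxes as
`cap / f`, the wage floor as `f · 3.0`. This keeps every cap/floor/waste/
flow transform idempotent at fixed year and monotone in the phase-in
factor, and measures are re-applied each evaluation year to a freshly
advanced baseline state, so effects never compound across years.

Dietary caps/floors operate on item groups with staple compensation:
sub-items scale proportionally to meet a group cap, and staples (cereals,
roots, tubers — not legumes) absorb the difference so total intake is
conserved exactly; driving staples negative raises a measure-infeasibility
error. Dietary reference levels default to planetary-health-diet style
values (kcal cap⁻¹ day⁻¹: monogastrics 150, ruminant products 190, sugar
120, oils/fats 400, legumes 250, fruits/vegetables/nuts 500); users working
against a specific reference table should override them in
`MEASURE_DEFAULTS`.

Canonical in-package order: cross-sector driver swaps → intake-level BMI
shifts → composition caps → composition floors → waste cap → wage/capital/
trade settings → land, water, nutrient and emission transforms. Caps run
before floors so a floor cannot be undone; the order is fixed because the
measure definitions are silent on it.

**Demand pass-through.** Between the demand-side and the land-side measures
the engine rescales cell pressures to the changed food demand: livestock
pressures (enteric and manure CH₄, excretion) follow aggregate animal-
calorie supply; cropping pressures (fertiliser, harvest N, soil gases,
land-use-change CO₂, the irrigation share of withdrawals) follow plant-
calorie supply plus a 30% feed share of the animal change; factor costs
follow a 50:50 livestock/cropping blend. This configured pass-through
stands in for a land-use model's response, so that demand-side measures
carry environmental and labour consequences and environmental constraints
(e.g. the flow requirement) bind on post-diet-change pressures. It is
deliberately linear and parameter-driven; it does not reallocate land.

**Specific conventions.** The crop-rotation measure is a per-cell cap on
each crop's share of cropland (default 25%, excess parked as fallow) — a
stand-in for a rotation-length tax schedule that is not reproducible here.
The biodiversity no-net-loss floor restores semi-natural land (cropland →
other natural) within each biome-region until its range-rarity-weighted BII
recovers its 2020 value; the restoration is distributed over cells in
proportion to their cropland. Protected-area expansion fills hotspot/intact
cells first and protects the marginal cell fractionally so the global share
lands exactly on target. Mitigation measures scale their emission source
terms by configured maximum-mitigation fractions; manure digesters set the
recycled fraction to `0.5·0.9 + 0.5·r₀` at full adoption. Cost-bearing
measures inflate factor costs and pass a configured share (default 0.5)
through to the shadow-price index; tax-style measures (carbon/rotation
prices) raise the price index and recycle their revenue.

## Health model

A comparative risk assessment with eight diet- and weight-related risk
factors (high red meat; low fruits, vegetables, nuts, legumes; underweight,
overweight, obese) and five endpoints (coronary heart disease, stroke,
type 2 diabetes, cancer in aggregate, respiratory disease). Colorectal
cancer is treated as a reporting slice of aggregate cancer (configurable
share), not an additional endpoint, to avoid double counting.

Continuous dietary exposure is mapped onto four categories (category 0 =
TMREL, RR ≡ 1) with the intake's mass split linearly between the two
neighbouring categories, so risk responds log-linearly to intake between
category anchors rather than jumping at breakpoints. Weight exposure uses
each cohort's BMI-class mass directly. Potential impact fractions
`(ΣP·RR − ΣP′·RR)/ΣP·RR` are combined multiplicatively across factors
(`1 − Π(1 − PIF)`, the GBD convention) with no mediation adjustment between
weight and diet factors — a documented simplification. Attributable deaths
are `rate × population × PIF` per (endpoint, age, sex) stratum; YLL weights
deaths by a standard abridged life table (strictly decreasing remaining
life expectancy). The premature-mortality indicator is the YLL attributable
to current exposure relative to the TMREL counterfactual. The analytic
chain is verified against an independent individual-level Monte-Carlo
simulation (categorical exposures, Bernoulli deaths, n = 10⁵, 3 s.e.).

## Income and poverty

Within-country incomes are lognormal; the Gini maps to the dispersion via
`G = 2Φ(σ/√2) − 1` and the headcount below a line `z` is
`population · Φ((ln z − μ)/σ)` (default line Int$ 3.20 day⁻¹). A
regression-based refinement toward observed poverty data is out of scope;
the pure lognormal headcount is used.

Food-price changes act quantile-wise: `y′(q) = y(q)(1 − s(y)π)` with a
power-law Engel curve `s(y) = s̄ (y/mean)^(ε−1)` (single parameter, default
elasticity ε = 0.8, share capped at 0.95) and π the relative food-price
change from the measures' price index. With ε < 1 the shock is regressive:
Gini and headcount weakly increase. The shocked distribution is summarised
on a 1,000-point quantile grid by trapezoidal Lorenz integration; mean and
Gini changes are *differenced against the unshocked grid* so the finite-
grid bias cancels exactly — a homothetic shock (ε = 1) leaves the Gini
unchanged to machine precision. Minimum-wage premiums and recycled tax
revenues enter as distribution-neutral proportional scalings (every
quantile scaled by `1 + revenue/mean`), which leave the Gini exactly
invariant and never increase the headcount.

## Indicators and aggregation

Shannon crop diversity uses the natural logarithm with `0·ln 0 = 0`,
per cell over the cropland classes including fallow, aggregated as a
cropland-area-weighted mean over cells with cropland. Cell BII is the
unweighted area mean of land-class intactness coefficients (reference
classes = 1); range-rarity weights enter at cross-cell aggregation — the
within-cell/cross-cell placement of the weight is genuinely ambiguous and
the cross-cell choice is flagged here. The cropland-landscape selection
keeps cells with ≥ 100 ha cropland; the hotspot selection keeps flagged
cells. Nitrogen surplus is inputs − withdrawals for cropland and pasture
(negative = soil mining, flagged), excretion − recycled for manure
management, and fixation for natural land (steady state); an
"agricultural soils" subtotal (cropland + pasture only) is exposed for
planetary-boundary comparisons. CO₂e uses GWP100 factors CH₄ 27 and
N₂O 273. The wage index aggregates country wage ratios to 2020 with
constant 2010 population weights. Bioeconomy supply and production-factor
use are quantity × fixed-2010-price sums. Global surface warming is
reported as not computed; `indicators.WARMING_HOOK` accepts a user-supplied
emissions-to-temperature mapping.

## Scenario runner

Baseline drivers advance exponentially at per-country rates (population,
income, wages, factor costs), diets are re-projected from the regressions
at the advanced income, a slow BMI drift (0.004 yr⁻¹ of class mass)
reproduces falling underweight and rising obesity, and cell pressures scale
with population. Evaluation years are 2020–2050 in 5-year steps. The delta
matrix compares each scenario to the baseline in 2050; classification uses
a desirability map encoded as data (lower-is-better, higher-is-better, and
a special rule for agricultural labour demand: scenarios containing the
human-development setting are evaluated against that setting's single run,
which is itself classed neutral, wages being the more welfare-relevant
indicator there). Deltas below a per-indicator epsilon are neutral. The
interaction term is defined as `Δ(package) − Σ Δ(members)`, making the
decomposition exact by construction (verified to 1e-9 relative).

Default problem sizes — 3 countries × 12 cells, 7 time steps, baseline plus
28 single runs plus 7 packages — were chosen so a full ensemble runs in
seconds on one CPU while every structural property (conservation,
idempotence, decomposition, floors) is exercised; all sizes are
configurable.

## Known limitations

No supply-side market equilibrium, land reallocation or yield response: the
demand pass-through is linear and configured, not optimised. No trade-flow
modelling (trade liberalisation is a parameter transform only). No
morbidity, disease incidence dynamics or time-lagged risk accumulation in
the health layer. No within-country sectoral income disaggregation: wage
and tax effects are recycled distribution-neutrally, so the poverty effects
of the minimum wage reflect only the regressive price channel. Waste
composition is held proportional to supply under dietary shifts. Children
contribute to headcount indicators but not to the mortality model. The
climate chain is absent by design.
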