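# Methods

## The substitution model

The package models two counterfactual diets per person-day and, for each,
a removal-only and a replacement variant.

**Identifying dairy fat.** A food's dairy fat per 100 g is the sum, over
all dairy-flagged ingredients reached by recursive recipe expansion, of
(effective grams of ingredient per 100 g of food) × (the ingredient's fat
per gram). Expansion is linear in the recipe proportions, depth-capped at
10 levels with cycle detection (real recipe files are shallow; deeper
nesting indicates corrupt data). An implausible record — expanded dairy
fat exceeding the food's own total fat — is resolved by clamping to total
fat and logging, since the nutrient record is the more curated source.

**Replacement eligibility.** A food can serve as replacement material iff
it contains no dairy fat and does not contain more saturated than
unsaturated fat. The comparison is strict: a tie (SFA = MUFA + PUFA)
remains eligible, because only an *excess* of saturated fat is disqualifying.

**Strata.** Replacement composites are specific to
4 age groups × 4 meal types × 6 energy-density sextiles × 6 %E-fat
sextiles = 576 cells. The default sextile cutpoints (49.8, 70.7, 151.5,
235.6, 308.8 kcal/100 g; 16.4, 24.9, 38.4, 48.3, 63.5 %E) are the
consumption-weighted percentiles of the reference national survey
distribution and ship as config defaults; they can also be recomputed from
any loaded intake table with the left-continuous weighted-quantile
operator (smallest value whose cumulative normalized weight reaches p).
That definition is exact and oracle-checkable; interpolating alternatives
differ negligibly at survey scale. Cutpoints act as lower bounds of
categories 2–6, so a boundary value falls in the upper category.

**Composite profiles.** Within a stratum, each eligible consumption event
contributes its food's per-gram nutrient vector with weight
survey weight × grams. "Frequency of consumption" weighting is thus
operationalized as grams-weighting, matching the grams-weighted
consumption percentiles; a config switch (`consumption_weighting`)
offers kcal- or event-weighting instead. Every composite nutrient
therefore lies within the [min, max] of its contributing foods, and no
composite can carry dairy fat. Unoccupied strata are resolved by
marginalizing dimensions in order fat sextile → energy-density sextile →
meal type → age group → global pool, recomputing the weighted composite at
each level; the order drops the most granular (least behaviorally
meaningful) dimension first.

**Model 1** removes every item whose food carries any dairy fat — whole
items, mixed dishes included. Whole-item removal (rather than stripping
only the dairy ingredient) is the behaviorally coherent reading of a
food-level model: one does not eat a cheeseburger minus its cheese fat,
and only whole-item removal produces the characteristic energy drop that a
~5.6%E dairy-fat diet shows on removal.

**Model 2** caps removal at 5% of the person's *observed* (pre-removal)
total energy. Dairy items are visited in a uniformly random order drawn
from a per-person stream seeded by (global seed, participant id), so
population results are independent of processing order and fully
reproducible; randomization prevents systematically sacrificing one meal
type. The item that would overshoot the cap is partially removed by
scaling its grams so removed dairy-fat energy equals the cap exactly
("up to but not exceeding"); `boundary="skip"` instead leaves the boundary
item intact and keeps trying smaller items, leaving removal below the cap.
Persons at or below the cap lose all dairy items, identically to Model 1.
The cap is referenced to observed rather than post-removal energy because
the cap defines how much to remove and must not move while removal
proceeds.

**Swap.** Each removed portion is replaced by the same number of grams of
the composite resolved for (consumer's age group, the occasion at which
the item was eaten, the removed food's energy-density and %E-fat
categories). Because the composite matches the removed food's energy
density and fat share by construction, the swap is approximately
iso-caloric without any explicit energy constraint; total grams are
preserved exactly.

## Scoring

**NRF 9.3 = NR − LIM.** NR sums nine components, each
min(100, 100 × intake per 2,000 kcal / DV), DVs: protein 50 g, fiber 28 g,
vitamin A 900 RAE, vitamin C 90 mg, vitamin D 20 mcg, calcium 1,300 mg,
iron 18 mg, potassium 4,700 mg, magnesium 420 mg. Range 0–900; truncation
prevents one abundant nutrient compensating for another's inadequacy.
LIM scores added sugars (%E, thresholds 6/26), saturated fat (%E, 8/16)
and sodium (mg, 1,100/2,000): zero at or below the minimum, full at or
above the maximum, proportional between. Each component is a fraction in
[0, 1] contributing 100 points, reconciling the per-nutrient "0.5 limiting
points" arithmetic with a 300-point LIM maximum. Sodium is evaluated on
the 2,000 kcal energy-adjusted amount by default (consistent with every
other scored intake being energy-adjusted); `sodium_energy_adjusted=False`
scores raw mg instead. Zero-energy days cannot be energy-adjusted and are
excluded from scoring with a logged warning.

**HEI-2015.** Thirteen components with maxima
(5,5,5,5,10,10,5,5,10,10,10,10,10) summing to 100, scored against the
published per-1,000 kcal density standards stored in config (e.g. total
fruits ≥ 0.8 cup eq/1,000 kcal for 5 points; sodium ≤ 1.1 g/1,000 kcal for
10 points, 0 points at ≥ 2.0 g; added sugars full at ≤ 6.5%E, zero at
≥ 26%E). The fatty-acids component scores (MUFA+PUFA)/SFA, full at ≥ 2.5,
zero at ≤ 1.2; a day with zero saturated fat receives the maximum by
defined limit (logged). Nutrients outside the scored sets (B-vitamins,
folic acid, …) are reported as energy-adjusted intakes only.

## Survey estimation

Means are weighted ratios Σwx/Σw; variance comes from Taylor linearization
with between-PSU variation accumulated within strata
(Σ_h n_h/(n_h−1) Σ_j (t_hj − t̄_h)², t_hj = PSU totals of the linearized
scores). CIs use the normal reference with 1.96; estimates are invariant
to uniform weight rescaling, and any stratum with a single PSU is rejected
with a remediation hint. Subgroups (dairy-fat consumers) are estimated as
domains: out-of-domain observations score zero but remain in the design,
which changes the SE — not the mean — relative to naive filtering whenever
subsetting empties a PSU.

The significance rule for modeled-vs-observed comparisons is a
conjunction: the relative change must strictly exceed 10% *and* a Wald
test that the absolute difference exceeds 10% of the observed mean
(combined SE, normal reference) must reject at α = 0.05. The two-part rule
keeps tiny-but-precise differences from being flagged at survey sample
sizes while remaining a well-defined test; it is this package's
operationalization, not a claim about how any particular published
analysis computed its asterisks.

## The synthetic generator

The generator emulates the joint structure the analysis depends on, with
all defaults chosen to mirror the reference population:

- **Foods** (default 400): energy density spans ~0–682 kcal/100 g and %E
  fat ~0.7–97.8, matching the reference consumption spread; nutrient
  vectors use exact Atwater energy (9/4/4) and archetype-specific
  log-normal micronutrients (grain/vegetable/fruit/meat/seafood/
  legume-nut/oil/sweets/beverage/mixed) so that dairy foods are the
  dominant carriers of calcium, vitamins A/D, riboflavin and B12. Dairy
  status is Bernoulli(`frac_dairy_foods`, default 0.25); dairy foods reach
  their dairy fat only through 1–3-level recipes over six dairy leaf
  ingredients, so recipe expansion is genuinely exercised. The first 36
  non-dairy foods are pinned one per sextile cell with eligible fat
  splits, guaranteeing the coverage invariant (every cell resolvable
  without fallback); a config that cannot populate the cells fails naming
  the first empty cell.
- **Population** (default 1,000; 5,000 for the calibration checks): ages
  uniform over 4–85 y, log-normal weights independent of everything else,
  `n_strata` (default 15) × 2 PSUs with every cell guaranteed occupied.
- **Recalls:** one day per person. A fraction (default 0.16, matching a
  ~84% consumer share) consumes no dairy fat; consumers draw a dairy-fat
  %E propensity from a Gamma(shape 2) scaled to make the survey-weighted
  population mean equal `target_dairy_pct_energy` (default 5.6), with mild
  age and ethnicity gradients (declining with age; highest in the
  majority-population subgroup) normalized to leave the population mean
  unchanged. Dairy item grams are solved per person so dairy-fat energy is
  exactly the target share of the realized day's energy (up to gram
  clipping); non-dairy items fill the remaining energy. Occasion labels
  are drawn with frequencies breakfast 20%, lunch 25%, dinner 25%, snack
  25%, dessert 5% (lunch/dinner jointly 50%); within-person day structure
  (6–12 items) is config, not an asserted fact about real surveys.

Everything is a pure function of the config seed; the three generator
stages and the Model-2 randomization use disjoint named substreams of the
study seed, so any stage can be rerun in isolation.

**What passing tests do and do not show.** The generator reproduces the
marginal spreads, the calibrated dairy-fat share, the consumer/
non-consumer split and a two-PSU design, but not real food co-occurrence,
within-person day structure, measurement error of recalls, true sampling
weights, or nonresponse adjustment. Tests passing on synthetic data
demonstrate the *machinery* (identities, caps, weighting, variance
formulas) — not that any particular population's numbers would be
reproduced.

## Numerical choices and degenerate inputs

- Fat energy uses the Atwater factor 9 kcal/g throughout; %E from fat per
  food is 100 × 9 × fat g / kcal.
- Zero-energy, zero-fat foods (water, diet drinks) are defined to have
  0 %E fat and fall in the lowest fat sextile so they remain classifiable;
  zero-energy foods reporting fat are flagged unclassifiable, logged, and
  excluded from fat-sextile use.
- Weighted quantiles use the left-continuous inverse CDF with a 1e-12
  mass slack against floating-point rounding at exact-mass boundaries.
- The Model-2 cap comparison carries a 1e-6 kcal tolerance in tests;
  the boundary item's fraction is computed in exact arithmetic.
- Per-person Model-2 streams are seeded by SeedSequence(global seed,
  crc32(participant id)), keeping all derived seeds well below 2^31.

## Problem sizes

Unit and property tests run on constructed micro-examples and
150–400-person synthetic cohorts; the population-scale invariant and
calibration checks use a 5,000-person, 400-food cohort, the scale at which
the generator's Monte-Carlo error on the mean dairy-fat share is
comfortably inside ±0.5 percentage points of the 5.6 target.

## Known limitations

- No behavioral realism: no compensatory eating or meal re-planning; the
  modeled diets are accounting counterfactuals.
- No usual-intake (measurement-error) modeling; a single recall day
  estimates population means, not the share of individuals meeting
  thresholds — the calcium-threshold share is reported descriptively.
- No replicate-weight (BRR/jackknife) variance, no multiple-testing
  correction, and the normal (not t) reference for CIs; NHANES-style
  degrees-of-freedom corrections would be a config extension.
- Recipe expansion ignores moisture/yield adjustment and retention
  factors.
- The loaders read the package's documented CSV dictionary, not official
  federal release formats.
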