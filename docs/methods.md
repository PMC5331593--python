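# Methods

This note documents the models, defaults and numerical choices behind
`dietopt`, in the order data flows through the package.

## Free-sugar annotation of a food table

Free sugars follow the WHO definition: sugars added by manufacturer, cook or
consumer, plus those naturally present in honey, syrups, fruit juices and
concentrates. A composition table is annotated per food through one of four
rule classes:

* `sugars_equal_free` — beverages, honey and syrups: free sugars equal total
  sugars;
* `recipe` — composite foods: free sugars are estimated from the average
  recipe as `100 × Σ weight_fraction × converting factor`, where the
  converting factor expresses the equivalent-sugar content of each
  assimilated-sugar ingredient (white sugar 1.0 and honey 0.8 are fixed
  anchors; syrup 0.8 and fruit-juice concentrate 1.0 are configurable
  defaults, since only the two anchors are authoritative);
* `expert_zero` / `expert_value` — explicit expertise estimates supplied in
  the input file, never inferred.

Recipe estimates occasionally exceed the analyzed total sugars; they are
clipped to the total with a warning, preserving the invariant
`0 ≤ free ≤ total`. Carbohydrate closure (`starch + sugars ≤ carb × 1.02`)
and the energy-free-drink rule (beverage with < 4 kcal/100 g, density 1
assumed for the per-100 mL threshold) are validated on load.

## Diaries, intakes and screening

Diaries record one consumption event per (day 1–7, moment, food, grams),
with six moments: breakfast, lunch, dinner and three between-meal snacking
occasions. Diet vectors are 7-day mean amounts (g/day); alcoholic beverages
are excluded throughout, because nutrient recommendations apply to
non-alcoholic energy. Meal-vs-snacking sub-totals of energy and free sugars
are computed from events before averaging, so the decomposition
`meals + snacking = total` is exact.

Free-sugar energy share uses 4 kcal/g (the Atwater carbohydrate factor; the
underlying analysis never states one). The 10% boundary is inclusive on the
acceptable side: share > 10 ⇒ FS-EXCESS, share ≤ 10 ⇒ FS-ACCEPTABLE.

The under-reporting screen is the Goldberg/Black cutoff: reported energy /
BMR below `PAL × exp(−2·S/100)`, with
`S = √(CV²_intake/7 + CV²_BMR + CV²_PAL)` and defaults CV_intake = 23%,
CV_BMR = 8.5%, CV_PAL = 15%. BMR uses Schofield weight-only equations; PAL
maps low/moderate/high activity to 1.55/1.7/1.9. All constants are
configuration — only the method itself is prescribed — and no particular
exclusion rate is asserted.

## Diet-quality indicators

* **SED** — energy of solid foods over their weight, kcal/100 g; solids are
  all non-beverage items (soups count as solid, milk/juices/soft drinks do
  not). Undefined (distinct error) for an all-beverage diet.
* **Variety** — distinct foods over the 7 days, beverages included.
* **MAR** — mean over 23 key nutrients of the percent of the recommended
  intake achieved by the weekly mean, capped at 100%.
* **MER** — mean over sodium, saturated fat and free sugars of the percent
  *above* the maximum recommended value; below-maximum nutrients contribute
  0, so MER ≥ 0 with 0 meaning no excess. (The third nutrient is free
  sugars by default, configurable to added sugars.) Percent-energy maxima
  (SFA 12%E, free sugars 10%E) are converted at the individual's energy.
* **PANDiet-style score** — for each of 22 adequacy nutrients,
  `P(usual intake ≥ requirement)` under a Gaussian with variance
  `(cv·EAR)² + s²/7`, where `s²` is the within-person day-to-day variance of
  the 7 daily intakes; for the 3 moderation nutrients,
  `P(usual intake ≤ maximum)` with the analogous variance. The score is
  100 × the mean of the adequacy and moderation sub-scores. Zero total
  variance with the mean exactly at threshold returns probability 0.5 by
  convention.

The 23-nutrient MAR list, the 25 PANDiet nutrients and all reference values
(`config/nutrient_references.yaml`) are reconstructions from French adult
dietary reference values; the original study's appendix lists are not
public. EARs default to roughly 0.77 × the reference intake with CVs of
10–15%.

## The individual optimization model

Variables are one amount per non-alcoholic food ever consumed in the
population; repertoire foods (observed > 0) are split
`q = o + d⁺ − d⁻, d± ≥ 0`. The objective
`Σ_rep (w⁺d⁺ + w⁻d⁻)/o + π Σ_nonrep q/m` realizes three aims — prefer
repertoire foods, minimize their reduction, control non-repertoire
introductions — with defaults w⁺ = 1, w⁻ = 2, π = 5. The acceptance
properties (iso-energy, constraint satisfaction, free-sugar direction) are
verified across a grid of these weights; the defaults only set the
trade-off scale.

Constraints:

* iso-energy equality at the observed non-alcoholic energy;
* 33 nutritional rows (`config/constraints.yaml`, a documented
  reconstruction): macronutrient %-energy windows (protein 10–20, fat
  35–40, carbohydrate 40–55, SFA ≤ 12), the conditional free-sugar ceiling,
  sodium ≤ 3150 mg, cholesterol ≤ 300 mg, a retinol ceiling, fiber ≥ 25 g
  and 21 vitamin/mineral minima. Percent-energy bounds are linearized at
  the fixed energy target;
* acceptability: per-food and per-sub-category caps at the 95th percentile
  of consumption among consumers; non-repertoire foods are additionally
  capped at the population mean among consumers `m_f`;
* total diet weight (energy-free drinks excluded, so water never competes
  with nutrient-dense foods) and total diet cost, each ≤ 1.1 × the
  observed value. The factor 1.1 (not 1.0) is deliberate: at exactly the
  observed bulk and budget, individuals at the low-energy tail cannot fit
  the absolute micronutrient minima inside their small diets, and the
  infeasibility rate rises an order of magnitude above the published
  handful of cases; allowing 10% headroom restores it.
* acceptability, weight and cost bounds are relaxed per individual to the
  observed value whenever the observed diet already exceeds them, so a
  person's own diet is never infeasible at the acceptability level.

The LP is solved with HiGHS (scipy.optimize.linprog), deterministic under
the fixed variable ordering. Optimal status requires every row within the
solver tolerance (1e-8); anything other than clean optimal/infeasible raises
a distinct error. Duals are reported as the sensitivity of the optimal
objective to each constraint's *stated* bound (so binding minima carry
positive duals, binding maxima negative ones), and a constraint is counted
binding when |dual| > 1e-6. The population ranking reports, per constraint,
the percentage of optimal individuals binding it, in decreasing order with
ties broken by id. The tests verify duals against finite-difference shadow
prices and complementary slackness, and verify whole optima against an
independent brute-force enumeration of polytope/kink intersections.

## The synthetic survey generator

The generator's defaults are the study conditions; they are not tuning
knobs. It emulates:

* the two-group mixture (41% above 10%E), free-sugar shares drawn from
  truncated normals on (0.5, 10] and (10, 35] %E. Parent parameters are
  moment-matched so the *realized* truncated moments equal the configured
  6.3 ± 2.5 and 14.2 ± 4.2. One caveat: a normal truncated above 10 cannot
  realize an SD ≥ (mean − 10) — that is the exponential limit of the family
  — so for the high group the mean is matched exactly and the realized SD
  (~3.8) falls somewhat short of 4.2, which reflects right-skew a truncated
  normal cannot mimic;
* total energy per group from truncated normals on [1500, 3700] kcal/day
  (a plausibility-screened cohort contains neither under-reporters nor
  gross over-reporters; an untruncated draw would pile implausible mass at
  a clipping floor);
* snacking energy from gamma distributions matching mean and SD (131 ± 154
  and 258 ± 220 kcal/day have SD > mean, outside the reach of a
  non-negative normal);
* sub-category amounts centred on the published observed group means with
  multiplicative gamma noise (CV ≈ 0.45) and realistic non-consumption
  probabilities; a few staples (refined starches, water, table sugar,
  vegetables, meats, hot beverages, added fats, cheese) are consumed by
  everyone;
* survey weights: lognormal (σ = 0.5), normalized to mean 1.

Food composition is built from per-sub-category archetypes with lognormal
per-food variation, plus cyclic within-sub-category variants (bread vs
pasta, butter vs oil vs margarine, processed vs lean meat vs fish, hard vs
fresh cheese) — the compositional heterogeneity real tables have and the
optimizer needs for substitutions; each variant-bearing sub-category is
guaranteed its full variant set. Energy is recomputed from Atwater factors
so percent-energy rows are exactly consistent, and carbohydrate closure is
exact by construction. Micronutrient contents are specified as relative
density patterns across sub-categories and calibrated so the whole-sample
reference diet covers each recommendation at 1.0–1.6×, then re-normalized
against the realized table; water, soft drinks and sugar carry only their
explicit (near-zero) entries.

Each diary hits its drawn energy and free-sugar share **exactly**: after
scaling to the energy target, non-lever sugar-bearing foods are scaled as a
block within safe bounds and the residual free-sugar gap is closed with the
table-sugar lever, with sugar-free energy foods absorbing the energy
difference; the same fit is applied to each jittered day. Exactness is what
makes the generator label and the >10%E classifier agree for every
individual, including arbitrarily close to the boundary. Foods are assigned
to moments by a snack-affinity order (sweet drinks and products first) until
the drawn snacking energy is met, splitting the marginal food between a
snack and a meal.

What the generator does **not** emulate: correlations between food
categories beyond those induced by the allocation (the published table
gives no covariances), seasonal or weekday structure, portion-size
granularity, sociodemographic joint distributions, and the skewness of the
high group's share distribution noted above. Observed-diet quality scores
(MAR ≈ 90–95 on synthetic data) run higher than in the real survey because
micronutrient coverage is calibrated near adequacy to keep the optimization
feasible for ≥ 95% of individuals — so passing tests demonstrate pipeline
correctness and qualitative behavior (directions of change, binding
hierarchy), not real-survey score magnitudes.

## Problem sizes and numerics

Default runs use 100 foods and populations of 60–1693 individuals; the
full-pipeline check optimizes 500 individuals against all 33 nutrient rows.
Per-individual LPs have ~100–260 variables and ~70 rows and solve in
milliseconds. Reported tables round to one decimal in g/day and kcal/day.
Feasibility tolerance 1e-8, dual threshold 1e-6; ties in the binding
ranking break lexicographically; degenerate inputs (empty diet, zero
energy, all-beverage diet, missing anthropometrics) raise typed errors
rather than propagating NaNs.
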