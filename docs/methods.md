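# Methods

This note documents the models, conventions and numerical choices behind
`bqikit`, and what the synthetic-data calibration does and does not
establish.

## Recall resolution and averaging

Each recall line contributes `grams × per-100 g value / 100` of every
nutrient; aggregation is purely additive, so splitting or merging lines
never changes a total. Breakfast is identified by an explicit meal label in
the recall file — the package deliberately does not infer meals from clock
time, which recalls rarely record reliably.

With two recall days per child, the breakfast indices are computed **per day
against that day's total energy, then averaged over the days a breakfast is
present**. The alternative — pooling the two days' foods and scoring the
average composition — would blur the per-meal criteria (a food eaten on one
day would count toward both) and would be inconsistent with defining
recall-based skipping at the day level. A consequence worth knowing: the
two-day BQI can take half-point values, and per-item columns report 0/0.5/1.
Total daily energy is always the mean of both days. Children with fewer than
two resolvable recall days are excluded, with a per-child reason logged.

## BQI conventions

Four criteria need operational choices the index's verbal definition leaves
open; each is a keyword argument of `score_bqi` with these defaults:

* **Sugar-rich foods (item iv).** Foods carry a `sugar_rich` library tag
  (biscuits, pastries, sugared cereals, sweetened dairy, artificial juices,
  soft drinks); the criterion compares their breakfast energy with 5% of
  *total daily* energy, strict `<`.
* **MUFA/SFA ≥ 2 (item vi).** When SFA is exactly zero the ratio is taken
  as its limit: met if MUFA > 0, not met if both are zero.
* **Energy share (item vii).** The 20–25% band is inclusive at both ends.
* **Calcium (item ix).** The published range "200–300 mg" is resolved at
  its lower bound, ≥ 200 mg; the threshold is configurable for the stricter
  variant.

An absent breakfast scores 0 with all items false. Item viii (cereal +
fruit + dairy together) is derived from items i–iii and is asserted to imply
them on every evaluation.

## Energy density

BEDs divides solid-food energy by solid-food mass; BEDb divides
energy-beverage energy by energy-beverage mass. The partition is by the
library's beverage flags: solids exclude *all* beverages, and non-energy
beverages (water, zero-kcal drinks) are excluded from both denominators —
including them would deflate density without representing energy exposure.
A density is reported missing, not zero, when its denominator is empty.
Note the convention that olive oil served on bread is a solid (it is not
drinkable), while soluble cocoa dissolved in milk travels with the milk as
a beverage; the demo library encodes the latter as a combined
milk-with-cocoa item.

## Skipping

Recall-based skipping requires breakfast absent on **both** recall days:
two sampled days can easily catch a habitual skipper eating breakfast by
chance, so a one-day definition would over-call skipping. The
questionnaire-based flag (KIDMED breakfast item) is echoed as reported and
is `unknown` when missing; the two definitions are reported side by side,
never merged.

## Outcome derivation

* **HOMA-IR** = insulin (µU/mL) × glucose (mmol/L) / 22.5, with glucose
  converted from mg/dL at 18.016 mg/dL per mmol/L.
* **IDF MetS**: five factors (waist ≥ sex/age 90th percentile; SBP ≥ 130
  *or* DBP ≥ 85 mmHg as one blood-pressure factor; TG ≥ 150; HDL < 40;
  glucose ≥ 100 mg/dL), syndrome at ≥ 3. All "elevated" boundaries are
  inclusive; the HDL boundary is strict. Missing components leave the
  verdict unknown rather than guessing.
* **MetS z-score**: sum of sex/age-stratified z-scores of TG, HDL, glucose,
  SBP, DBP, with the HDL term negated (configurable) so a higher composite
  is always a worse profile. Reference strata are whole years of age; the
  packaged reference tables are *synthetic plausible* pediatric values (so
  the composite's location is interpretable only within a run, not against
  published norms).
* **Adiposity z-scores** (FMI, abdominal fat) are standardized within study
  center (sample SD, ddof = 1) to absorb systematic between-device
  differences; a center with fewer than two observations or zero SD is an
  error, not a silent pass-through.
* **Log policy**: TG, GGT, insulin and HOMA are natural-log transformed; a
  manifest records the transform applied to every column. The log base is
  irrelevant to standardized β and p (affine change), which the tests
  assert.

## The association ladder

OLS on complete cases per cell. Exposure and outcome are z-standardized on
the analysis sample of that cell, so β is standardized; covariates are left
in natural units (their scaling cannot affect the exposure coefficient).
Categorical covariates (sex, center, maternal education) enter as
`drop-first` indicators. Model 1: sex, age, center, maternal education,
energy intake; Model 2: + FMI; Model 3: + total physical activity (ENMO).
The FMI z-score outcome is fitted under Model 1 only — adjusting an
adiposity outcome for FMI would be self-adjustment. p-values are two-sided
t-tests on the exposure coefficient, with no multiplicity correction.
Rank-deficient designs and cells with fewer complete cases than design
columns + 1 raise a fit error naming the cell.

Within activity strata (MVPA ≥ 60 min/day, boundary inclusive on the active
side), the Model 2 covariate set is used: total PA is the conditioning
variable and re-entering it inside a PA-defined stratum would be
near-degenerate. The sex-interaction test adds standardized-exposure × sex
to Model 1. The puberty sensitivity replaces age with a binary Tanner ≥ III
indicator across all three models.

## The synthetic cohort

The generator emulates a two-center cohort of 8–12-year-old children with
overweight/obesity: sex (47.3% girls), center split (≈ 55/45),
age ~ N(10.3, 1.1²) clipped to [8, 12.9], FMI ~ N(10.7, 2.5²), MVPA
~ N(54.4, 20.9²), maternal education high at 26.2%, habitual-skipper
prevalence 12% (skippers miss each recall-day breakfast with probability
0.7, regulars 0.02), KIDMED item missing at 15%, measurement-wise biomarker
missingness at 4%. Breakfasts are drawn per day from the packaged ~34-item
demo library (milk or cocoa-milk, a bakery/cereal solid, olive oil or
butter on bread with center-dependent olive-oil propensity, occasional
fruit and water); lunch/dinner/snack items bring total daily energy to a
realistic ~1700–2000 kcal. Under the defaults the scored metrics land near
BQI ≈ 4.3, BEDs ≈ 3.4 kcal/g, BEDb ≈ 0.6 kcal/g, which is the descriptive
regime the pipeline is meant to operate in.

Outcomes are simulated on the standardized scale as
`Σ effect·z(exposure) + Σ loading·z(confounder) + noise`, with the noise SD
set to `sqrt(1 − Σcoef²)` (floor 0.2) so each outcome has ≈ unit variance
and a configured effect *is* the standardized β the ladder estimates. Two
design points matter:

* **Effects act on computed exposures.** The generator runs its own recalls
  through the real resolution and scoring code before simulating outcomes,
  so a configured effect propagates through exactly the path the analysis
  uses. A child with a missing exposure (e.g. no energy beverage)
  contributes the exposure mean (z = 0).
* **HOMA is generated, insulin derived.** log-HOMA is simulated directly
  and insulin back-computed from it and glucose, so the pipeline's HOMA
  re-derivation reproduces the configured effect exactly. Effects on TG,
  GGT and HOMA act on the natural-log scale, matching the analysis model.
  Effects on the MetS z composite are rejected: the composite is derived
  from its components downstream, and an effect should be placed on those.

A mediation path exposure → total PA (`mediator_effects`) combined with a
PA loading on an outcome reproduces the tier-2 → tier-3 attenuation pattern.
Each run writes a truth table of every generating coefficient, and a fixed
seed gives bit-identical output.

**What the generator does not emulate:** real dietary-pattern correlation
structure (foods are drawn near-independently given the slot), reporting
error in recalls, non-random missingness, measurement error in biomarkers,
or growth-curve anthropometry. Passing calibration tests therefore shows the
*statistical machinery* is unbiased and correctly sized under the assumed
structure — not that any particular epidemiological estimate in real data
is correct.

## Calibration results asserted by the tests

With all effects zero, the Model 1 rejection rate at α = 0.05 stays inside
the binomial 95% band over 500 cohorts of 200 children; a standardized
effect of 0.25 of BEDb on log HOMA is recovered with |mean bias| < 0.02 and
≥ 93% CI coverage over 500 replications; the ladder reproduces a
normal-equations solve to 1e-8 on small instances. Simulation sizes (500
replications at n = 200; 25 replications at n = 250 for the attenuation
check) were chosen to make the binomial/Monte-Carlo error small relative to
the asserted margins while keeping the default test run quick.

## Known limitations

* The packaged MetS reference and waist cutoffs are synthetic; absolute
  MetS prevalence and composite levels are not comparable to published
  cohorts.
* The BQI's sugar-rich and calcium conventions are declared choices among
  defensible readings of the index; both are configurable, and conclusions
  sensitive to them should be checked under the variants.
* The two-day average is a noisy estimate of habitual intake; the pipeline
  makes no usual-intake (measurement-error) correction.
* Complete-case analysis assumes missingness unrelated to the missing
  values; no imputation is provided.
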