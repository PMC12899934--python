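# Methods

This note documents the generative model, the calibration of its defaults,
the numerical choices in each analysis stage, and what the shipped defaults
can and cannot say about real dietary data.

## Population generator

Each simulated person belongs to one of four dietary patterns
(Mediterranean, Western, Plant-based, Mixed; 375 persons per pattern by
default) and receives:

* **Demographics.** Age and BMI from truncated normals (age on [18, 80]
  years, BMI on [15, 50] kg/m²) at pattern-specific means/SDs; sex and
  tertiary education as Bernoulli draws; income quintile as a normal
  discretized and clipped to {1..5}; season uniform on {1..4}. Truncation
  shifts the realized age means by at most ~0.2 years relative to the
  nominal parameters.
* **Food-group shares.** `s ~ Dirichlet(alpha0 * p)` with concentration
  `alpha0 = 12` and pattern base composition `p`. At this concentration the
  within-pattern coefficients of variation of derived intakes come out near
  40–50%, consistent with the calibration targets' SD-to-mean ratios.
* **Daily food mass.** A truncated normal on [0.5, 6] kg/day, independent of
  the shares. Consumption is mass x shares; all derived quantities (energy,
  protein, iron, calcium, zinc, vitamin D, B12, GHG, water, cost) are exact
  weighted sums of consumption against the per-kg database densities.
  Per-100 g densities are converted to per-kg exactly once, inside
  `compute_intakes`.
* **Diversity score.** An integer count of distinct foods per day from a
  discretized normal (mean 11.1, SD 2.0, clipped to [4, 20]). It is a
  sampled person attribute, *not* derived from the consumption vector: no
  derivation exists at the eight-group level. Treat analyses that lean on
  it accordingly.
* **Plant-to-animal ratio.** (non-animal, non-dairy mass)/(animal + dairy
  mass), capped at 50 so all-plant diets stay finite.

Rows are person-days: `days_per_person > 1` repeats a person's demographics
with fresh consumption draws, and all statistics operate on rows.

## Calibration of the shipped defaults

Only population-level outputs constrain the generator, so the defaults are
solved, not hand-picked (`scripts/calibrate_defaults.py`):

1. **Expected consumption per pattern.** The pattern-mean targets for
   energy, protein, iron, calcium, GHG, water and cost are linear in the
   expected consumption vector `c` (kg/day per group). A linear program
   finds the minimum achievable maximum relative error; a second stage then
   minimizes distance to a pattern-typical prior composition subject to a
   1.5% error budget. Because the four patterns' targets are numerically
   very close, the feasible compositions are themselves similar across
   patterns — the generator reproduces the targets' *convergent* profile,
   and pattern labels differ more in composition nuance than in outcome
   space. The Plant-based pattern keeps a small residual animal share
   (cap 0.12 kg/day, ~6%): with animal at zero, its target row is not
   jointly reachable (best error >6.5%).
2. **Mass distribution.** Base shares are `c / sum(c)`; the truncated
   normal's (location, scale) are moment-matched so the analytic mean and
   SD of energy intake hit each pattern's energy mean/SD target, using the
   exact Dirichlet variance of the per-kg energy density.
3. **Extension nutrients (zinc, vitamin D, B12).** No group-level reference
   densities exist for these; they are *synthetic calibrated stand-ins*.
   The 4-pattern mean constraints leave 8 group densities underdetermined;
   among non-negative exact solutions the solver picks the one minimizing
   the analytic within-pattern intake variance (plus a weak pull toward
   plausible food-composition priors). This spreads vitamin D and B12
   across staple groups — read it as a fortified food supply — and keeps
   the Monte-Carlo noise of these columns comparable to the core nutrients.
   Their within-group SDs in the food table are set to half the mean and
   are not used downstream.

With these defaults, all pattern-level means of the eleven derived metrics
fall within ±10% of their calibration targets (worst cell ~7% at the
default seed; ≤ ~9.5% across 40 re-seedings), and the pooled energy
mean/SD land within 5%/10% of their targets.

**What the defaults do not emulate.** Adequacy *prevalences* are emergent,
not calibrated: with sex-specific requirements (iron EAR 8/18 mg,
calcium 1000 mg, zinc 11/8 mg, vitamin D 20 µg, B12 6 µg, protein
0.8 g/kg — all configurable) the default cohort shows ~82% iron and ~35%
calcium adequacy. Reference prevalence figures for similar cohorts are not
reproducible from printed parameters alone, so benchmark rows requiring
>90% adequacy fail honestly under the defaults. Likewise real-data features
— under-reporting, meal skipping, day-to-day correlation, bioavailability —
are deliberately absent; passing tests demonstrate the *machinery*, not
behavioral realism.

## Classification and regression

The random forest uses 500 trees, depth ≤ 20, ≥ 5 samples per leaf, 4
candidate features per split, on a stratified 70/30 split (seed-controlled).
The default feature list has 12 entries (age, sex, BMI, income, season,
energy, protein, GHG, water, cost, diversity, plant/animal ratio).
Importances are mean decrease in Gini impurity normalized to sum to 1; their
SEs are the SD of per-tree normalized importances over √500. Per-class
F1 is defined as 0 when precision and recall are both undefined (empty
prediction class), with a logged note. Support-weighted recall equals
overall accuracy by construction; the package exposes that identity for
re-deriving accuracy from per-class tables.

The adequacy regression is OLS of the iron intake/requirement ratio on 15
predictors, scored on the held-out 30% (R², RMSE, MAPE; zero-valued targets
are excluded from MAPE with a logged count; rank-deficient designs fail
loudly naming the collinear columns). Per-pattern R² is computed within
test-set pattern subsets.

## Latent structure

PCA standardizes features (population SD) and uses SVD; component signs are
fixed by making each component's largest-magnitude loading positive.
Explained percentages always refer to all p components. Cost is excluded
from the default 14-feature reduction list so the latent axes reflect
composition, not pricing. t-SNE delegates to scikit-learn (perplexity 30,
learning rate 200, 1000 iterations, PCA initialization) and reports the
final KL divergence; n must exceed 3x perplexity. Convex-hull overlap
fractions use Monte-Carlo point-in-hull sampling with a fixed seed;
degenerate (collinear) clusters get area 0 and overlap 0.

## Statistics

* Percentile bootstrap: B resamples with replacement; SE with Bessel's
  correction; the 95% interval uses the literal order statistics at ranks
  0.025·B and 0.975·B (no interpolation). B < 100 warns.
* Chi-square independence: expected counts from marginals, no continuity
  correction; ANOVA computes the between/within mean-square ratio
  explicitly. Both agree with the scipy reference implementations to 1e-8
  in the property tests (dual-route check).
* Post hoc testing defaults to pairwise Welch t-tests at the
  Bonferroni-adjusted level `alpha / (k(k-1)/2)`; Tukey's HSD is available
  behind a flag.
* Prevalence SEs, where needed, are binomial `sqrt(p(1-p)/n)`.
* Reported percentage deviations are rounded half-away-from-zero at two
  decimals and then at one, matching the printed convention of the
  reference tables this package validates against (e.g. −4.547 → −4.6).

## Optimization

Diets are encoded as 9 genes in [0, 1]: eight share genes mapped through
inverse-gamma(0.3) quantiles (so the uniform genome space reaches sparse,
few-group compositions) and repaired onto the 0.4-capped simplex by
iterative clip-and-redistribute, plus a mass gene scaled to [0.5, 6] kg.
The energy window (2000–3500 kcal) is also handled by repair: energy is
monotone in mass at fixed shares, so the mass gene is projected into the
feasible interval whenever one exists. The protein-to-energy constraint
(10–35%, 4 kcal/g) is mass-invariant and is handled by feasibility-first
domination (feasible solutions always dominate infeasible ones; infeasible
ones rank by total violation). NSGA-II itself is a standard implementation
— fast non-dominated sorting, crowding distance, binary tournament,
simulated binary crossover (eta 15), polynomial mutation (eta 20) — with
population 200, crossover 0.9, mutation 0.1, 100 generations, all
seed-deterministic. This repair-based design was chosen because pure
constraint-domination left the search short of the weighted-sum optima at
the front's extremes; with it, all three weighting schemes sit within ~0.01
of the exhaustive grid oracle at the default settings.

f1 evaluates adequacy for a configurable reference person (default: female
thresholds — the stricter iron case — at 70 kg body mass for the protein
RDA). f2 normalizes by the fixed observed maxima (3.96 kg CO₂e/day, 4175
L/day); f3 by `cost_max`, which has no printed reference value and defaults
to the simulated population's maximum observed daily cost (recorded in run
metadata), paralleling the observed-maximum convention of f2.

The grid oracle enumerates every share lattice point (step 0.05, components
≤ 0.4) crossed with a 0.25 kg mass grid (~1.2 M feasible combinations),
entirely vectorized; it is the independent check that weighted selections
from the NSGA-II front are near-optimal, and it doubles as the cost
minimizer for the affordability scenario.

## Scenarios and validation

Scenario mechanics are a convex combination with a single blend weight
lambda (default 0.5): each person's shares move toward a target composition
(the Mediterranean base shares; the Plant-based base shares with animal and
dairy zeroed and renormalized, so a full shift removes animal foods; the
grid-oracle cost minimizer for affordability), keeping the person's total
daily mass and recomputing every derived field. The seasonal scenario
applies a shipped season x group share-delta table (fruit/vegetable boosted
in their growing seasons, compensated from grain). Published scenario
percentages depend on unprinted mechanics, so the package tests
directionality (plant-forward lowers mean GHG; affordability lowers mean
cost) rather than specific values. Scenario feasibility applies the energy
and protein-ratio windows to the scenario's population means.

Validation compares population summaries against two shipped tables:
sustainability thresholds (pass/fail per comparison rule, 20% deviation
convention) and survey reference intakes (signed percentage deviation and
IQR membership). Metrics missing from a summary produce not-evaluable rows
rather than disappearing.

## Orchestration and reproducibility

The pipeline derives one child seed per stage from the global seed
(`seed * 1000003 + crc32(stage)` mod 2³¹), so stages can be re-run
independently. All artifacts carry the seed and a config hash (output
location excluded). Two runs with identical configuration are byte-identical.

Default problem sizes: 1500 person-days, 500 trees, B = 1000, NSGA-II
200 x 100, grid step 0.05 — the full pipeline completes in well under a
minute on one CPU. The test suite uses smaller smoke sizes (50 per pattern,
B = 200, 15–40 generations, grid step 0.1) for pipeline-level tests and the
full defaults where a check's meaning requires them.

## Known limitations

* The four patterns are calibrated to near-identical outcome targets, so
  classification accuracy is modest by construction (~0.35–0.41) and
  pattern clusters overlap heavily in the embeddings; this mirrors the
  convergent-profile setting the framework is designed to probe, but means
  the defaults cannot demonstrate high-separability behavior.
* Extension-nutrient densities and the diversity score are synthetic
  stand-ins (see above).
* Adequacy uses total intake; no bioavailability adjustment.
* The affordability scenario blends toward the cheapest feasible diet at
  each person's own mass; because that diet is energy-dense, the blended
  population can exceed the energy window and be flagged infeasible even
  though each component diet is feasible.
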