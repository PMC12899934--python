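# dietsim

Simulation-based integrated assessment of dietary patterns: nutrient
adequacy, environmental footprints, and economic cost in one framework.

`dietsim` is for nutrition and sustainability researchers who want a
controlled, fully reproducible test bed for dietary analysis methods before
touching survey data. It generates a synthetic cohort of individuals
following four dietary patterns — Mediterranean, Western, Plant-based and
Mixed — from an eight-food-group composition database, and then runs a
five-stage analysis on it:

1. **simulate** — per-person Dirichlet food-group shares and daily food
   mass, with demographics, nutrient intakes, greenhouse-gas and water
   footprints, daily cost, and a dietary diversity score;
2. **classify** — a 500-tree random forest recovering pattern membership,
   with Gini feature importances and confusion-matrix metrics, plus an OLS
   regression predicting micronutrient adequacy ratios (R², RMSE, MAPE);
3. **reduce** — PCA (variance decomposition, loadings) and t-SNE embedding
   of the standardized feature space;
4. **optimize** — constrained tri-objective diet optimization with NSGA-II,
   weighted-sum diet selection, and an exhaustive grid-search oracle;
5. **scenarios / validate** — five intervention scenarios (baseline,
   Mediterranean shift, plant-forward, seasonal rotation, affordability)
   and validation against shipped sustainability/survey benchmark tables.

## The model

Per-person intakes are weighted sums over the eight food groups: for
nutrient *n* of person *i* with consumption `C_ij` (kg/day) and per-kg
density `d_nj`,

    N_ni = sum_j C_ij * d_nj,     GHG_i = sum_j C_ij * EF_j,
    Water_i = sum_j C_ij * WF_j,  Cost_i = sum_j C_ij * price_j.

Consumption is `C_ij = M_i * s_ij` with daily mass `M_i` a truncated normal
on [0.5, 6] kg and shares `s_i ~ Dirichlet(alpha0 * p)` for pattern-specific
base composition `p` (alpha0 = 12). Population adequacy prevalence uses the
EAR cut-point method: the fraction of people with intake/requirement >= 1.

The optimization searches diets `x` (8 shares on the simplex, each <= 0.4,
plus total mass) maximizing mean requirement coverage
`f1 = (I/EAR_Fe + Ca/EAR_Ca + Zn/EAR_Zn + P/RDA_prot) / 4` while minimizing
the dual-footprint composite `f2 = (GHG/GHG_max + Water/Water_max) / 2`
(maxima 3.96 kg CO₂e/day and 4175 L/day) and normalized cost `f3`, subject
to 2000 ≤ energy ≤ 3500 kcal/day and a protein share of energy in
[0.10, 0.35]. Uncertainty is quantified by the percentile bootstrap
(B = 1000, order-statistic interval, Bessel-corrected SE).

## Worked example

```python
import dietsim
from dietsim.stats import bootstrap_summary

db = dietsim.default_food_table()
pop = dietsim.simulate_population(db, n_per_pattern=375, seed=42)
b = bootstrap_summary(pop.df["energy_kcal"].to_numpy(), B=1000, seed=42)
print(f"energy {b.point_mean:.0f} kcal/day, bootstrap SE {b.se:.1f}, "
      f"95% CI [{b.ci_low:.0f}, {b.ci_high:.0f}]")
```

prints

```
energy 3349 kcal/day, bootstrap SE 33.8, 95% CI [3283, 3413]
```

i.e. the 1500 simulated person-days average ~3350 kcal/day and the
population mean is pinned down to about ±34 kcal (1% coefficient of
variation) — the generator is calibrated for nutritional adequacy, so this
sits deliberately above typical survey intakes. The `examples/` directory
holds one short script per capability (simulation, classification, latent
structure, bootstrap/tests, optimization, scenarios); each prints its
numbers with a note on what they mean. For instance
`python examples/05_optimize_diet.py` reports a 138-diet Pareto front and,
for the balanced weighting, a legume/vegetable-dominated diet with adequacy
2.86, environment 1.10 and cost 0.32, within 0.01 of the exhaustive
grid-oracle optimum.

The full pipeline is also available from the shell:

```sh
dietsim run --out-dir my_run --seed 42      # all five stages + report.txt
dietsim simulate --out pop.csv              # or stage by stage
dietsim classify --pop pop.csv --out report.json
```

Two runs with the same seed produce byte-identical summaries.

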