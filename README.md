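# poststrat

Cell-based poststratification and saturated g-methods for making
population-level inferences from nonprobability samples.

Most epidemiological samples — cohorts, convenience samples, volunteer
panels — are not probability samples of their target population, so crude
sample means need not represent population quantities. When the joint
distribution of a set of categorical auxiliary variables X is known in both
the sample and the target population (from a census, registry, or prior
survey), poststratification reweights the sample so the distribution of X
matches the population, removing the selection bias attributable to X.

This package treats sample inclusion δ ∈ {0, 1} like a treatment
assignment, which puts poststratification on the same footing as the
g-methods used for causal inference and makes their assumptions,
estimators, and diagnostics carry over directly:

* **Weighting route (IPW form).** Each sampled unit in stratum j gets the
  weight w_j = N_j / n_j = 1 / P̂(δ=1 | X=x_j); the estimate is
  Σ_j Σ_i Y_ij w_j / Σ_j N_j.
* **Aggregation route (standardization / g-formula form).** Stratum sample
  means are averaged under the population cell distribution:
  Σ_j N_j Ȳ_j / Σ_j N_j.

The two are algebraically identical — the saturated-model equivalence of
IPW and standardization. Validity needs three assumptions: conditional
independence Y ⊥ δ | X, positivity P(δ=1 | X=x) > 0 for every population
cell, and non-reactive sampling Y = Y^{δ=0} = Y^{δ=1}.

What's here:

* `data_model` — readers/validators for CSV microdata and population cell
  tables, cross-classification, sample/population alignment checks.
* `estimators` — the two poststratification estimators, cell weights with
  an explicit empty-cell policy, the crude mean.
* `gmethods` — saturated (cell-frequency) IPW and standardization for
  counterfactual means E[Y^a] and the ATE, with structured positivity
  errors.
* `twostage` — poststratify each exposure group to its own population,
  then standardize both to a common covariate distribution for comparison.
* `diagnostics` — Kish effective sample size / design effect, covariate
  balance before/after weighting, positivity reports.
* `simulate` — a Monte-Carlo laboratory with explicit knobs that violate
  each assumption (outcome-dependent selection, reactive sampling), plus
  closed-form oracles for the resulting biases.
* `cli` — a `poststrat` command with subcommands for all of the above.

## Worked example

The packaged illustration is the Korean Genome and Epidemiology Study
(KoGES) baseline cohort — 10,030 adults aged 40–69 in 2001 — poststratified
to the 2001 Korean Population Census on age group and sex to estimate the
current-smoking prevalence of all Korean adults aged 40–69:

```sh
poststrat make-fixtures fx
poststrat poststratify \
    --microdata fx/koges_table1_sample.csv \
    --population fx/koges_table1_census.csv \
    --covariates age_group,sex --outcome smoker
```

prints

```
n = 10030, population total = 1.54132e+07
cell weights (N_j / n_j):
  40-49 / men: 1651
  40-49 / women: 1594.43
  50-59 / men: 1789.55
  50-59 / women: 1623.6
  60-69 / men: 1276.74
  60-69 / women: 1188.75
crude mean:          0.2555333998005982  (25.6%)
poststratified mean: 0.2646439675885303  (26.5%)
```

Men aged 40–49 are weighted by 3,886,462 / 2354 = 1651.0: the cohort
under-represents them relative to the census. Because the cohort oversamples
older participants (who smoke less), the crude rate understates the
population rate; poststratification raises the estimate to 26.5%. The crude
rate of the regenerated unit-level file is 25.6% rather than the 25.7%
computed on the original microdata, because the fixture is expanded from
stratum rates printed at one decimal — see `poststrat/fixtures.py`.

The same pipeline in Python:

```python
from poststrat import (Schema, read_microdata, read_population_table,
                       crosstab, compute_cell_weights, weighted_mean)

schema = Schema(covariates=("age_group", "sex"), outcome="smoker")
data = read_microdata("fx/koges_table1_sample.csv", schema)
census = read_population_table("fx/koges_table1_census.csv", ["age_group", "sex"])
weights = compute_cell_weights(crosstab(data, ["age_group", "sex"]), census)
print(weighted_mean(data, weights).value)   # 0.2646439675885303
```

## Documentation

`docs/methods.md` describes the estimators, their assumptions, the
simulation laboratory's design (including the closed-form bias oracles),
and the package's numerical conventions and limitations.
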