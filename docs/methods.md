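# Methods

## Setting and estimands

A target population of N units is partitioned into J strata by the
cross-classification of categorical auxiliary variables X; stratum j has
population count N_j (known externally) and contributes n_j units to the
observed sample. Sample inclusion is encoded by δ_i ∈ {0, 1}; microdata
contain only δ = 1 rows. The estimand of the poststratification machinery
is the population mean E[Y]; the g-methods module targets counterfactual
means E[Y^a] under a categorical treatment A and their difference, the ATE.

## Estimators

**Poststratification, weighting route.** Each sampled unit in stratum j
receives w_j = N_j / n_j, the inverse of the estimated inclusion
probability p̂_j = n_j / N_j; the estimate is Σ_j Σ_i Y_ij w_j / Σ_j N_j.
This is inverse-probability weighting with δ in the role of the treatment,
except that the weights come nonparametrically from cell counts plus
external knowledge of P(X = x_j), not from a fitted propensity model — the
δ = 0 group is unobservable, so nothing can be regressed on it.

**Poststratification, aggregation route.** Σ_j N_j Ȳ_j / Σ_j N_j, the
g-formula/standardization form: stratum means averaged under the population
covariate distribution. The two routes are algebraically identical, which
the suite verifies to 1e-12 on randomized inputs; it is the saturated-model
equivalence of IPW and standardization.

**Saturated g-methods.** Propensities are within-cell relative frequencies
P̂(A=a | X=x_j) = n_{j,a} / n_j; IPW computes
(1/n) Σ_i Y_i I(A_i=a)/P̂(a|X_i) and standardization computes
Σ_j Ȳ_{j,a} P(X=x_j) with P(X=x_j) taken either from the sample (n_j/n) or
from an external population table. No parametric propensity or outcome
model is offered anywhere: the package deliberately stays in the saturated
regime where weighting and standardization coincide, and where every
failure of support is a visible empty cell rather than a silent
extrapolation.

**Two-stage comparison.** To compare exposure groups drawn
nonrandomly from different populations: stage 1 poststratifies each group
a to its own population over the selection stratifiers W
(w^(a)_j = N^(a)_j / n^(a)_j); stage 2 forms stage-1-weighted outcome means
per cell of the confounders Z and averages them under a common standard
distribution. W and Z may differ. When W = Z, within-cell reweighting
cannot change cell means, so stage 1 provably cancels from the final
estimates; the implementation allows this configuration (it is the natural
default) and logs a note that stage 1 then only rescales. Stage-2 cell
means use the stage-1 weights; discarding them would make stage 1
meaningless under any W, Z.

## Assumptions and their encodings

1. **Conditional independence** Y ⊥ δ | X — inclusion carries no outcome
   information within strata. Simulator knob `outcome_dependence` d breaks
   it: units with Y = 1 are included with probability s_j + d. The shift is
   additive on the probability scale, the simplest analytically tractable
   form; a logistic-scale alternative would be monotone-equivalent but
   without closed-form cell means.
2. **Positivity** P(δ=1 | X=x) > 0 for every population cell. Violations
   surface as `PositivityError`s naming the cells, or descriptively in
   alignment/positivity reports. Only δ = 1 needs support; nothing is ever
   estimated for the unsampled group.
3. **Consistency, strengthened** Y = Y^{δ=0} = Y^{δ=1} — being sampled does
   not change the outcome. Knob `reactivity` r breaks it: included units
   report Y + r. This is a minimal encoding; no functional form for
   reactive behaviour is implied beyond a constant shift.

## Simulation laboratory

A finite population is realized once per study: cells drawn from the
configured joint proportions π_j, outcomes drawn once per unit from
Bernoulli(q_j) and then held fixed — the sampling-theory stance that Y_i is
an attribute and only δ_i is random. Each replication includes unit i
independently with probability s_j + d·Y_i and reports Y_i + r.
Configurations whose shifted probabilities leave [0, 1] are rejected
outright, never clipped, so the stated mechanism is exactly the simulated
one. Per-replication generators derive from the master seed via
`SeedSequence(master, spawn_key=(rep+1,))`, making reports byte-identical
across runs and replications independent.

The poststratification target inside a study is the *realized* population
cell table, so estimator bias is measured conditionally on the population
actually simulated. Replications where a population cell drew no sampled
units are counted as positivity failures and excluded from the averages;
the report carries the count.

**Closed-form oracles.** With inclusion probability p_i = s_{j(i)} + d·Y_i,
the crude estimator's conditional expectation is approximately
Σ_i p_i (Y_i + r) / Σ_i p_i (ratio-of-expectations; the neglected
ratio-estimator term is O(1/n)), and the poststratified estimator's is
Σ_j (N_j/N) · [Σ_{i∈j} p_i (Y_i + r) / Σ_{i∈j} p_i]. Superpopulation
versions replace realized cells by (π_j, q_j):

    E[crude] ≈ Σ_j π_j [q_j (s_j+d)(1+r) + (1−q_j) s_j r]
               / Σ_j π_j [q_j (s_j+d) + (1−q_j) s_j]
    E[poststrat] ≈ Σ_j π_j [q_j (s_j+d)(1+r) + (1−q_j) s_j r]
                   / [q_j (s_j+d) + (1−q_j) s_j]

At d = r = 0 the poststratified expectation reduces to Σ_j π_j q_j, the
truth — poststratification is unbiased under covariate-only selection —
while the crude expectation stays a selection-tilted mixture. These
formulas are exposed (`expected_*`, `analytic_*`) and the Monte-Carlo means
are tested against them at 3 Monte-Carlo standard errors.

**Study conditions.** The default bias study uses the two-stratum
configuration of the worked obesity example: π = (0.5, 0.5),
q = (0.30, 0.10), s = (0.4, 0.6) — strong stratum–outcome and
stratum–selection association, giving crude expectation 0.18 against truth
0.20. The packaged acceptance-level study runs 500 replications on a
100,000-unit population (sample size ≈ 50,000 per replication), sizes at
which the Monte-Carlo standard error (~6×10⁻⁵) cleanly separates the
designed biases from noise while a full study completes in under two
minutes on one core. The violation study adds d = 0.2.

**What the generator does and does not emulate.** It produces categorical
strata with Bernoulli outcomes and independent per-unit inclusion — the
exact regime in which the estimators' claims are theorems. It has no
within-stratum outcome heterogeneity beyond Bernoulli noise, no clustered
or dependent selection, no measurement error, and no continuous covariates.
Passing simulations therefore demonstrate correctness of the estimators
under their stated assumptions, not robustness of poststratification on
real cohorts, where conditional independence is untestable and only
partially attainable.

## Worked-example fixtures

The KoGES illustration ships as stratum summaries (six age-by-sex cells:
census counts, cohort counts, smoking rates) expanded deterministically to
unit level: cell j contributes n_j rows of which round(n_j · rate_j) have
outcome 1 (half-up rounding; no ties occur at these values). Rates are
published at one decimal, so the expanded file's crude rate is ≈ 25.6%
rather than the 25.7% computed on the original microdata — the discrepancy
is asserted in the suite as a property of the fixture, and the
poststratified rate is 26.5% either way. The obesity toy (400/600 sample
from a 1000/1000 population, rates 30%/10%) expands the same way.
`make_fixtures` writes byte-identical files on every run; files are
regenerated on demand rather than stored.

## Numerical conventions and degenerate inputs

* Estimates are carried at full float precision; percentage rounding to one
  decimal happens only in presentation (CLI summary lines, the acceptance
  script's JSON).
* Cell keys order covariates lexicographically by name, then levels as
  strings; all tables iterate in that order, so outputs are deterministic.
* Levels are compared as exact strings after trimming surrounding
  whitespace; no case folding, since coercion could silently merge strata.
* Missing values are rejected with the row and column named; nothing is
  imputed.
* Equivalence and identity properties are asserted at absolute 1e-12;
  weight accounting (Σ_j n_j w_j = N) at relative 1e-12.
* Empty-cell policy: population cells without sampled units raise by
  default; `drop_and_renormalize` removes them and rescales the remaining
  N_j so the total is preserved, logging the dropped population share.
  Collapsing adjacent cells is not implemented — there is no principled
  collapsing rule without additional structure on the covariates. Sample
  cells absent from the population table always raise: they indicate a
  coding mismatch between the two sources.
* Weight scale: `population` (w_j = N_j/n_j) by default; `normalized`
  (mean unit weight 1) is available for variance heuristics. Estimates are
  scale-invariant, which is tested.
* Treatment variables may be any finite categorical; ATE requires naming
  the two levels to contrast.

## Known limitations

* No variance or confidence-interval estimation for poststratified or
  standardized estimates; the weight summary's design effect is a
  heuristic, not an inferential quantity.
* No raking/calibration to marginal distributions, no continuous
  covariates, no model-based (e.g. multilevel) stratum estimates, no
  doubly-robust estimators.
* The Kish effective sample size (Σw)²/Σw² is a survey convention adopted
  here for weight diagnostics, not a derived quantity.
* Balance is reported on per-variable marginals plus joint cells; exact
  joint balance for the poststratifiers holds by construction and is
  asserted in the tests.
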