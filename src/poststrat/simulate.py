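"""Monte-Carlo laboratory for selection bias and poststratification.

A finite population is created once per study: every unit gets a fixed
covariate cell and a fixed binary outcome Y (the sampling-theory stance —
outcomes are fixed attributes, only sample inclusion is random). Each
replication then draws a sample by independent per-unit inclusion and
compares the crude and poststratified estimators against the realized
population mean.

Two knobs break the identifying assumptions, one each:

* ``outcome_dependence`` d: a unit with Y=1 is included with probability
  s_j + d instead of s_j, violating conditional independence of outcome and
  inclusion given the stratifiers (d on the probability scale, the simplest
  analytically tractable form).
* ``reactivity`` r: included units *report* Y + r, violating consistency
  (sampling alters the outcome). The stored population outcome is never
  re-randomized.

Configurations whose shifted probabilities leave [0, 1] are rejected, not
clipped. Per-replication random streams derive from the master seed by a
fixed counter scheme, so studies are reproducible and parallelizable by
replication.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import CellKey, Microdata, PopulationTable, Schema, crosstab
from .errors import ConfigError, PositivityError
from .estimators import cell_mean_aggregate, crude_mean
from .fixtures import make_fixtures  # re-exported: fixture writing lives here

__all__ = [
    "SimConfig",
    "SimPopulation",
    "BiasReport",
    "generate_population",
    "draw_sample",
    "run_bias_study",
    "expected_crude",
    "expected_poststratified",
    "analytic_crude",
    "analytic_poststratified",
    "make_fixtures",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions: population structure, selection mechanism, knobs.

    ``cells`` are covariate-level combinations (joint distribution given
    cell by cell via ``proportions``); ``outcome_probs`` are per-cell
    Bernoulli outcome probabilities q_j; ``selection_probs`` are per-cell
    base inclusion probabilities s_j.
    """

    covariates: tuple[str, ...]
    cells: tuple[CellKey, ...]
    proportions: tuple[float, ...]
    outcome_probs: tuple[float, ...]
    selection_probs: tuple[float, ...]
    outcome_dependence: float = 0.0
    reactivity: float = 0.0
    population_size: int = 10_000
    seed: int = 0
    replications: int = 100

    def __post_init__(self) -> None:
        ncell = len(self.cells)
        object.__setattr__(self, "cells", tuple(tuple(c) for c in self.cells))
        for name in ("proportions", "outcome_probs", "selection_probs"):
            vals = tuple(float(v) for v in getattr(self, name))
            if len(vals) != ncell:
                raise ConfigError(f"{name} must have one entry per cell ({ncell})")
            object.__setattr__(self, name, vals)
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ConfigError(
                f"cell proportions sum to {sum(self.proportions)!r}, not 1"
            )
        if any(p < 0 for p in self.proportions):
            raise ConfigError("cell proportions must be nonnegative")
        for q in self.outcome_probs:
            if not 0.0 <= q <= 1.0:
                raise ConfigError(f"outcome probability {q} outside [0, 1]")
        d = self.outcome_dependence
        for s, q in zip(self.selection_probs, self.outcome_probs):
            if not 0.0 <= s <= 1.0:
                raise ConfigError(f"selection probability {s} outside [0, 1]")
            if q > 0 and not 0.0 <= s + d <= 1.0:
                raise ConfigError(
                    f"shifted inclusion probability {s + d} outside [0, 1]; "
                    "rejecting rather than clipping"
                )
        if self.population_size <= 0:
            raise ConfigError("population_size must be positive")

    @property
    def schema(self) -> Schema:
        return Schema(covariates=self.covariates, outcome="y")


@dataclass
class SimPopulation:
    """A realized finite population: fixed cells and fixed outcomes."""

    config: SimConfig
    cell_index: np.ndarray  # int per unit
    y: np.ndarray  # float per unit (0/1)

    def __len__(self) -> int:
        return len(self.y)

    @property
    def population_mean(self) -> float:
        return float(self.y.mean())

    def cell_counts(self) -> np.ndarray:
        return np.bincount(self.cell_index, minlength=len(self.config.cells))

    def to_population_table(self) -> PopulationTable:
        counts = self.cell_counts()
        cells = {
            cell: int(n)
            for cell, n in zip(self.config.cells, counts)
            if n > 0
        }
        return PopulationTable(self.config.covariates, cells)


def generate_population(config: SimConfig) -> SimPopulation:
    """Draw the finite population once; deterministic given ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.population_size
    cell_index = rng.choice(len(config.cells), size=n, p=config.proportions)
    q = np.asarray(config.outcome_probs)[cell_index]
    y = (rng.random(n) < q).astype(float)
    return SimPopulation(config, cell_index, y)


def _microdata_from_arrays(
    config: SimConfig, cell_index: np.ndarray, y: np.ndarray
) -> Microdata:
    labels = [np.asarray([c[i] for c in config.cells], dtype=object)
              for i in range(len(config.covariates))]
    frame = pd.DataFrame(
        {cov: lab[cell_index] for cov, lab in zip(config.covariates, labels)}
    )
    frame["y"] = y
    return Microdata(frame, config.schema)


def draw_sample(
    population: SimPopulation, config: SimConfig, rep_seed: int | np.random.SeedSequence
) -> Microdata:
    """One sampling replication: independent inclusion, observed outcomes.

    Unit i in cell j is included with probability s_j + d * Y_i; included
    units report Y_i + r. Only included rows are returned.
    """
    rng = np.random.default_rng(rep_seed)
    s = np.asarray(config.selection_probs)[population.cell_index]
    p = s + config.outcome_dependence * population.y
    if np.any(p < 0) or np.any(p > 1):
        raise ConfigError("per-unit inclusion probability outside [0, 1]")
    included = rng.random(len(population)) < p
    observed = population.y[included] + config.reactivity
    return _microdata_from_arrays(config, population.cell_index[included], observed)


def _rep_seed(master: int, rep: int) -> np.random.SeedSequence:
    # Fixed counter scheme: master entropy, replication number as spawn key.
    return np.random.SeedSequence(entropy=master, spawn_key=(rep + 1,))


@dataclass
class BiasReport:
    """Monte-Carlo summary per estimator, against the fixed population mean."""

    true_mean: float
    replications_requested: int
    replications_used: int
    positivity_failures: int
    estimators: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "schema_version": 1,
            "true_mean": self.true_mean,
            "replications_requested": self.replications_requested,
            "replications_used": self.replications_used,
            "positivity_failures": self.positivity_failures,
            "estimators": self.estimators,
        }
        return json.dumps(payload, sort_keys=True, indent=2)


def run_bias_study(config: SimConfig) -> tuple[BiasReport, pd.DataFrame]:
    """Replicate sampling + estimation; report bias of crude vs poststratified.

    The poststratification target is the *realized* population cell table.
    Replications in which some population cell drew no sampled units are
    counted as positivity failures and excluded from the averages (policy
    logged in the report). Returns the report and a per-replication
    estimate table.
    """
    if config.replications < 2:
        raise ConfigError("at least 2 replications are required")
    population = generate_population(config)
    pop_table = population.to_population_table()
    rows: list[dict] = []
    failures = 0
    for rep in range(config.replications):
        sample = draw_sample(population, config, _rep_seed(config.seed, rep))
        rec: dict[str, float] = {"replication": rep}
        try:
            counts = crosstab(sample, config.covariates)
            rec["poststratified"] = cell_mean_aggregate(counts, pop_table).value
            rec["crude"] = crude_mean(sample).value
            rec["n_sampled"] = len(sample)
        except PositivityError:
            failures += 1
            continue
        rows.append(rec)
    per_rep = pd.DataFrame(rows)
    if per_rep.empty:
        raise PositivityError(
            "every replication hit an empty population stratum; "
            "raise selection probabilities or merge cells"
        )
    report = BiasReport(
        true_mean=population.population_mean,
        replications_requested=config.replications,
        replications_used=len(per_rep),
        positivity_failures=failures,
    )
    for name in ("crude", "poststratified"):
        est = per_rep[name].to_numpy(dtype=float)
        mean = float(est.mean())
        report.estimators[name] = {
            "mean_estimate": mean,
            "bias": mean - report.true_mean,
            "mc_se": float(est.std(ddof=1) / np.sqrt(len(est))),
        }
    return report, per_rep


# ---------------------------------------------------------------------------
# Closed-form expectations (oracles for the Monte-Carlo study)


def expected_crude(population: SimPopulation, config: SimConfig) -> float:
    """Expected crude estimate conditional on the realized population.

    Ratio-of-expectations form: sum_i p_i (Y_i + r) / sum_i p_i with
    p_i = s_{j(i)} + d Y_i; exact up to the O(1/n) ratio-estimator term.
    """
    s = np.asarray(config.selection_probs)[population.cell_index]
    p = s + config.outcome_dependence * population.y
    return float(np.dot(p, population.y + config.reactivity) / p.sum())


def expected_poststratified(population: SimPopulation, config: SimConfig) -> float:
    """Expected poststratified estimate conditional on the population:
    sum_j (N_j / N) * [expected sample mean in cell j]."""
    counts = population.cell_counts()
    total = counts.sum()
    value = 0.0
    for j in range(len(config.cells)):
        mask = population.cell_index == j
        if not mask.any():
            continue
        yj = population.y[mask]
        pj = config.selection_probs[j] + config.outcome_dependence * yj
        cell_mean = np.dot(pj, yj + config.reactivity) / pj.sum()
        value += counts[j] / total * cell_mean
    return float(value)


def analytic_crude(config: SimConfig) -> float:
    """Superpopulation expectation of the crude estimate:
    sum_j pi_j [q_j (s_j + d)(1 + r) + (1 - q_j) s_j r] /
    sum_j pi_j [q_j (s_j + d) + (1 - q_j) s_j]."""
    num = den = 0.0
    d, r = config.outcome_dependence, config.reactivity
    for pi, q, s in zip(config.proportions, config.outcome_probs, config.selection_probs):
        num += pi * (q * (s + d) * (1.0 + r) + (1.0 - q) * s * r)
        den += pi * (q * (s + d) + (1.0 - q) * s)
    return num / den


def analytic_poststratified(config: SimConfig) -> float:
    """Superpopulation expectation of the poststratified estimate:
    sum_j pi_j [q_j (s_j + d)(1 + r) + (1 - q_j) s_j r] /
    [q_j (s_j + d) + (1 - q_j) s_j]; equals sum_j pi_j q_j when d = r = 0."""
    d, r = config.outcome_dependence, config.reactivity
    value = 0.0
    for pi, q, s in zip(config.proportions, config.outcome_probs, config.selection_probs):
        num = q * (s + d) * (1.0 + r) + (1.0 - q) * s * r
        den = q * (s + d) + (1.0 - q) * s
        value += pi * num / den
    return value
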