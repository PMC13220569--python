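"""Poststratification estimators of a population mean.

Two algebraically equivalent routes:

* ``weighted_mean`` — give every sampled unit in stratum j the weight
  w_j = N_j / n_j, then average:  sum_j sum_i Y_ij w_j / sum_j N_j.
* ``cell_mean_aggregate`` — average the stratum sample means under the
  population cell distribution:  sum_j N_j Ybar_j / sum_j N_j.

Both target E[Y] in the population under conditional independence of outcome
and sample inclusion given the stratifiers, positivity of inclusion in every
population cell, and non-reactive sampling. ``crude_mean`` is the unweighted
sample mean, valid only under simple random sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import (
    CellKey,
    Microdata,
    PopulationTable,
    StratumCounts,
    WeightTable,
    row_cells,
)
from .errors import PositivityError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Estimate",
    "compute_cell_weights",
    "drop_empty_cells",
    "weighted_mean",
    "cell_mean_aggregate",
    "crude_mean",
    "unit_weights",
]


@dataclass(frozen=True)
class Estimate:
    """A population mean (or proportion) estimate.

    ``total_weight`` is the sum of applied unit weights: the population
    total N for the weighted/aggregated methods on the population scale, the
    sample size n for the crude method.
    """

    value: float
    n_effective_cells: int
    total_weight: float
    method: str  # weighted | aggregated | crude


def drop_empty_cells(
    population: PopulationTable, sample: StratumCounts
) -> PopulationTable:
    """Remove population cells with no sampled units and renormalize.

    Remaining N_j are rescaled multiplicatively so their sum recovers the
    original total; the dropped population share is logged. This is the
    ``drop_and_renormalize`` positivity policy.
    """
    observed = {k for k, n in sample.counts.items() if n > 0}
    kept = {k: v for k, v in population.cells.items() if k in observed or v == 0}
    dropped = {k: v for k, v in population.cells.items() if k not in kept}
    if not dropped:
        return population
    total = population.total
    kept_total = sum(kept.values())
    if kept_total <= 0:
        raise PositivityError(
            "every population cell is empty in the sample", sorted(dropped)
        )
    share = sum(dropped.values()) / total
    logger.warning(
        "dropping %d population cell(s) with no sampled units (%.2f%% of the "
        "population mass): %s; remaining cells renormalized",
        len(dropped),
        100 * share,
        sorted(dropped),
    )
    return PopulationTable(
        population.covariates, {k: v * total / kept_total for k, v in kept.items()}
    )


def compute_cell_weights(
    sample: StratumCounts,
    population: PopulationTable,
    on_empty: str = "error",
    scale: str = "population",
) -> WeightTable:
    """Poststratification weights w_j = N_j / n_j per matched cell.

    ``on_empty`` controls population cells with no sampled units
    (positivity violations): ``"error"`` raises, ``"drop_and_renormalize"``
    removes them and rescales the remaining N_j (see
    :func:`drop_empty_cells`). Sample cells absent from the population
    table are always an error — they signal a covariate-coding mismatch,
    not a statistical condition.
    """
    if on_empty not in ("error", "drop_and_renormalize", "drop"):
        raise ValidationError(f"unknown on_empty policy {on_empty!r}")
    if sample.covariates != population.covariates:
        raise ValidationError(
            f"covariate mismatch: sample {sample.covariates} vs "
            f"population {population.covariates}"
        )
    observed = {k for k, n in sample.counts.items() if n > 0}
    sample_only = sorted(observed - set(population.cells))
    if sample_only:
        raise ValidationError(
            f"sample cells absent from the population table: {sample_only} "
            "(no population count to weight toward)"
        )
    zero_mass = sorted(k for k in observed if population.cells[k] == 0)
    if zero_mass:
        raise ValidationError(
            f"sampled cells carry zero population count: {zero_mass}"
        )
    population_only = sorted(
        k for k, v in population.cells.items() if v > 0 and k not in observed
    )
    if population_only:
        if on_empty == "error":
            raise PositivityError(
                f"population cells with no sampled units: {population_only}",
                population_only,
            )
        population = drop_empty_cells(population, sample)
    weights = {k: population.cells[k] / sample.counts[k] for k in sorted(observed)}
    if scale == "normalized":
        factor = sample.total / sum(sample.counts[k] * w for k, w in weights.items())
        weights = {k: w * factor for k, w in weights.items()}
    return WeightTable(sample.covariates, weights, scale=scale)


def unit_weights(
    data: Microdata, weights: WeightTable, covariates: Sequence[str] | None = None
) -> np.ndarray:
    """Per-row weights looked up from a cell weight table."""
    covs = weights.covariates if covariates is None else tuple(sorted(covariates))
    if covs != weights.covariates:
        raise ValidationError(
            f"covariates {covs} do not match weight table {weights.covariates}"
        )
    keys = row_cells(data, covs)
    out = np.empty(len(keys), dtype=float)
    for i, key in enumerate(keys):
        try:
            out[i] = weights.cells[key]
        except KeyError:
            raise ValidationError(f"row {i} falls in cell {key} with no weight") from None
    return out


def weighted_mean(
    data: Microdata, weights: WeightTable, covariates: Sequence[str] | None = None
) -> Estimate:
    """Individual-level weighting estimator: sum_i Y_i w_i / sum_i w_i."""
    w = unit_weights(data, weights, covariates)
    y = data.outcomes
    total = float(w.sum())
    keys = row_cells(data, weights.covariates)
    return Estimate(
        value=float(np.dot(y, w) / total),
        n_effective_cells=len(set(keys)),
        total_weight=total,
        method="weighted",
    )


def cell_mean_aggregate(sample: StratumCounts, population: PopulationTable) -> Estimate:
    """Stratum-aggregation estimator: sum_j N_j Ybar_j / sum_j N_j.

    Every population cell with positive mass must have a sample mean;
    apply :func:`drop_empty_cells` upstream to opt into the drop policy.
    """
    if sample.covariates != population.covariates:
        raise ValidationError(
            f"covariate mismatch: sample {sample.covariates} vs "
            f"population {population.covariates}"
        )
    missing = sorted(
        k for k, v in population.cells.items() if v > 0 and k not in sample.means
    )
    if missing:
        raise PositivityError(
            f"population cells with no sample mean: {missing}", missing
        )
    total = population.total
    value = (
        sum(v * sample.means[k] for k, v in population.cells.items() if v > 0) / total
    )
    used = [k for k, v in population.cells.items() if v > 0]
    return Estimate(
        value=float(value),
        n_effective_cells=len(used),
        total_weight=float(total),
        method="aggregated",
    )


def crude_mean(data: Microdata) -> Estimate:
    """Unweighted sample mean (population-valid only under SRS)."""
    if len(data) == 0:
        raise ValidationError("cannot take the crude mean of empty microdata")
    y = data.outcomes
    return Estimate(
        value=float(y.mean()),
        n_effective_cells=1,
        total_weight=float(len(y)),
        method="crude",
    )
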