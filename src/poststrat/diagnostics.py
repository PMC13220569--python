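"""Weight and assumption diagnostics.

The causal-inference toolbox transfers directly to poststratification
problems: weight concentration (Kish effective sample size, design effect),
covariate balance before/after weighting against the target population, and
positivity reports on the sample/population cell alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    AlignmentReport,
    CellKey,
    Microdata,
    PopulationTable,
    StratumCounts,
    validate_alignment,
)
from .errors import ValidationError

__all__ = [
    "WeightSummary",
    "weight_summary",
    "balance_table",
    "PositivityReport",
    "positivity_report",
]


@dataclass(frozen=True)
class WeightSummary:
    """Distributional summary of per-unit weights.

    ``effective_sample_size`` is the Kish heuristic (sum w)^2 / sum w^2 —
    a survey convention, not a quantity with a single canonical definition;
    ``design_effect`` = n / ESS >= 1 quantifies the variance inflation from
    unequal weights.
    """

    n: int
    min: float
    max: float
    mean: float
    effective_sample_size: float
    design_effect: float
    max_weight_share: float


def weight_summary(weights: Sequence[float] | np.ndarray) -> WeightSummary:
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValidationError("empty weight vector")
    if not np.all(w > 0):
        raise ValidationError("weights must be strictly positive")
    total = float(w.sum())
    ess = total**2 / float((w**2).sum())
    return WeightSummary(
        n=int(w.size),
        min=float(w.min()),
        max=float(w.max()),
        mean=total / w.size,
        effective_sample_size=ess,
        design_effect=w.size / ess,
        max_weight_share=float(w.max()) / total,
    )


def balance_table(
    data: Microdata,
    weights: Sequence[float] | np.ndarray,
    population: PopulationTable,
    covariates: Sequence[str],
) -> pd.DataFrame:
    """Covariate distributions before/after weighting vs. the target.

    Returns one row per level of each covariate (marginals) plus one row per
    joint cell, with columns ``variable, level, before, after, target,
    abs_diff_after`` (all proportions). For covariates used as the
    poststratifiers, ``after`` matches ``target`` exactly by construction.
    """
    covs = tuple(sorted(covariates))
    if covs != population.covariates:
        raise ValidationError(
            f"covariates {covs} do not match population table {population.covariates}"
        )
    w = np.asarray(weights, dtype=float)
    if w.size != len(data):
        raise ValidationError("weights are not aligned with the microdata rows")
    n = len(data)
    total_w = w.sum()
    pop_props = population.proportions()

    rows: list[dict] = []

    def add(variable: str, level: str, before: float, after: float, target: float) -> None:
        rows.append(
            {
                "variable": variable,
                "level": level,
                "before": before,
                "after": after,
                "target": target,
                "abs_diff_after": abs(after - target),
            }
        )

    # Per-variable marginals.
    for i, cov in enumerate(covs):
        values = data.frame[cov].to_numpy(dtype=object)
        target_marg: dict[str, float] = {}
        for key, p in pop_props.items():
            target_marg[key[i]] = target_marg.get(key[i], 0.0) + p
        for level in sorted(set(values) | set(target_marg)):
            mask = values == level
            add(
                cov,
                level,
                before=float(mask.sum()) / n,
                after=float(w[mask].sum()) / total_w,
                target=target_marg.get(level, 0.0),
            )

    # Joint cells.
    keys = list(zip(*(data.frame[c].to_numpy(dtype=object) for c in covs)))
    keys_arr = np.asarray([" / ".join(k) for k in keys], dtype=object)
    joint_name = " x ".join(covs)
    sample_cells = set(keys)
    for key in sorted(sample_cells | set(pop_props)):
        label = " / ".join(key)
        mask = keys_arr == label
        add(
            joint_name,
            label,
            before=float(mask.sum()) / n,
            after=float(w[mask].sum()) / total_w,
            target=pop_props.get(key, 0.0),
        )

    return pd.DataFrame(rows, columns=["variable", "level", "before", "after", "target", "abs_diff_after"])


@dataclass
class PositivityReport:
    """Alignment report augmented with per-cell inclusion fractions
    p-hat_j = n_j / N_j for matched cells."""

    alignment: AlignmentReport
    inclusion_fractions: dict[CellKey, float]

    @property
    def positivity_ok(self) -> bool:
        return self.alignment.positivity_ok


def positivity_report(
    sample: StratumCounts, population: PopulationTable
) -> PositivityReport:
    """Descriptive positivity check: never raises on violations."""
    alignment = validate_alignment(sample, population)
    fractions = {
        key: sample.counts[key] / population.cells[key]
        for key in alignment.matched
        if population.cells[key] > 0
    }
    return PositivityReport(alignment, fractions)
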