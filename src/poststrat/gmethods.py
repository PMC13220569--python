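"""Saturated (nonparametric) g-methods: IPW and standardization.

Counterfactual means E[Y^a] are estimated without any parametric model:
treatment propensities are raw cell frequencies P-hat(A=a | X=x_j) =
n_{j,a} / n_j, and standardization averages cell-and-arm outcome means over
a reference covariate distribution (the sample's own, or an external
population table). Under these saturated estimators IPW and standardization
are algebraically identical whenever both are defined — the same identity
that makes the two poststratification formulas agree.

Identifiability rests on conditional exchangeability (Y^a independent of A
given X), positivity of P(A=a | X=x) for the levels being contrasted, and
consistency (Y = Y^A).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import (
    CellKey,
    Microdata,
    PopulationTable,
    crosstab,
    row_cells,
    sorted_covariates,
)
from .errors import PositivityError, SchemaError, ValidationError

__all__ = [
    "PropensityTable",
    "CounterfactualEstimate",
    "estimate_propensity",
    "ipw_mean",
    "standardized_mean",
    "ate",
]


@dataclass
class PropensityTable:
    """Cell-frequency treatment propensities.

    ``entries`` maps (cell, level) to P-hat(A=level | X=cell) for *observed*
    levels only; probabilities within a cell sum to 1. ``support`` lists the
    levels observed per cell, so a level missing from some cell — a
    positivity gap for that contrast — is visible rather than stored as a
    zero.
    """

    covariates: tuple[str, ...]
    entries: dict[tuple[CellKey, str], float]
    support: dict[CellKey, list[str]] = field(default_factory=dict)
    levels: tuple[str, ...] = ()

    def gaps(self, level: str) -> list[CellKey]:
        """Cells where ``level`` was never observed."""
        return sorted(c for c, obs in self.support.items() if level not in obs)


@dataclass(frozen=True)
class CounterfactualEstimate:
    level: str
    value: float
    method: str  # ipw | standardization
    reference_distribution: str  # sample | external


def estimate_propensity(data: Microdata, covariates: Sequence[str]) -> PropensityTable:
    """Saturated propensities: within-cell relative frequencies of A."""
    if data.schema.treatment is None:
        raise SchemaError("microdata declares no treatment column")
    covs = sorted_covariates(covariates)
    keys = row_cells(data, covs)
    a = data.treatments
    cell_n: dict[CellKey, int] = defaultdict(int)
    cell_level_n: dict[tuple[CellKey, str], int] = defaultdict(int)
    for key, level in zip(keys, a):
        cell_n[key] += 1
        cell_level_n[(key, str(level))] += 1
    entries = {
        (key, level): count / cell_n[key]
        for (key, level), count in sorted(cell_level_n.items())
    }
    support: dict[CellKey, list[str]] = defaultdict(list)
    for key, level in sorted(cell_level_n):
        support[key].append(level)
    levels = tuple(sorted({level for _, level in cell_level_n}))
    return PropensityTable(covs, entries, dict(support), levels)


def ipw_mean(
    data: Microdata,
    a: str,
    propensity: PropensityTable,
    covariates: Sequence[str] | None = None,
) -> CounterfactualEstimate:
    """Inverse-probability-weighted counterfactual mean.

    (1/n) sum_i Y_i I(A_i = a) / P-hat(A=a | X_i): units at the requested
    level are inflated by the inverse of their cell propensity, forming a
    pseudo-population in which assignment is independent of the covariates.
    """
    covs = propensity.covariates if covariates is None else tuple(sorted(covariates))
    if covs != propensity.covariates:
        raise ValidationError(
            f"covariates {covs} do not match propensity table {propensity.covariates}"
        )
    keys = row_cells(data, covs)
    treatments = data.treatments
    y = data.outcomes
    total = 0.0
    missing: set[CellKey] = set()
    for key, level, yi in zip(keys, treatments, y):
        if str(level) != a:
            continue
        p = propensity.entries.get((key, a))
        if p is None or p <= 0:
            missing.add(key)
            continue
        total += yi / p
    if missing:
        raise PositivityError(
            f"units with A={a!r} in cells lacking a propensity for that level: "
            f"{sorted(missing)}",
            sorted(missing),
        )
    return CounterfactualEstimate(
        level=a,
        value=total / len(data),
        method="ipw",
        reference_distribution="sample",
    )


def standardized_mean(
    data: Microdata,
    a: str,
    covariates: Sequence[str],
    reference: PopulationTable | None = None,
) -> CounterfactualEstimate:
    """Standardization (g-formula): sum_x E-hat[Y | A=a, X=x] P(X=x).

    With ``reference=None`` the covariate distribution is the sample's own
    (n_j / n); an external :class:`PopulationTable` standardizes to its
    cell distribution instead. Every reference cell with positive mass must
    contain at least one unit at level ``a``.
    """
    if data.schema.treatment is None:
        raise SchemaError("microdata declares no treatment column")
    covs = sorted_covariates(covariates)
    arm = data.subset(np.asarray([str(t) == a for t in data.treatments]))
    if len(arm) == 0:
        raise PositivityError(f"no units with A={a!r}")
    arm_means = crosstab(arm, covs).means

    if reference is None:
        counts = crosstab(data, covs)
        dist = {k: n / counts.total for k, n in counts.counts.items()}
        ref_name = "sample"
    else:
        if reference.covariates != covs:
            raise ValidationError(
                f"reference covariates {reference.covariates} do not match {covs}"
            )
        dist = reference.proportions()
        ref_name = "external"

    missing = sorted(k for k, p in dist.items() if p > 0 and k not in arm_means)
    if missing:
        raise PositivityError(
            f"reference cells with no A={a!r} units: {missing}", missing
        )
    value = sum(p * arm_means[k] for k, p in dist.items() if p > 0)
    return CounterfactualEstimate(
        level=a, value=float(value), method="standardization",
        reference_distribution=ref_name,
    )


def ate(
    data: Microdata,
    covariates: Sequence[str],
    treated: str = "1",
    control: str = "0",
    method: str = "standardization",
    reference: PopulationTable | None = None,
) -> float:
    """Average treatment effect E[Y^treated] - E[Y^control]."""
    if method == "ipw":
        if reference is not None:
            raise ValidationError(
                "IPW is defined against the sample distribution; "
                "use method='standardization' with an external reference"
            )
        prop = estimate_propensity(data, covariates)
        e1 = ipw_mean(data, treated, prop)
        e0 = ipw_mean(data, control, prop)
    elif method == "standardization":
        e1 = standardized_mean(data, treated, covariates, reference)
        e0 = standardized_mean(data, control, covariates, reference)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return e1.value - e0.value
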