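"""Two-stage comparison of exposure groups from nonprobability samples.

Stage 1 poststratifies each exposure group to its own complete population
(weights N^(a)_j / n^(a)_j over the selection stratifiers W, the predictors
of sample inclusion). Stage 2 direct-standardizes both reweighted groups to
a common covariate distribution over the confounders Z, making the group
contrast comparable.

W and Z may differ. When they coincide, stage 1 provably cancels out of the
final estimate — cell means are invariant to within-cell reweighting — so
stage 1 then only rescales; a note is logged in that case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import (
    CellKey,
    Microdata,
    PopulationTable,
    WeightTable,
    crosstab,
    row_cells,
    sorted_covariates,
)
from .errors import PositivityError, ValidationError
from .estimators import compute_cell_weights, unit_weights

logger = logging.getLogger(__name__)

__all__ = ["TwoStageSpec", "StandardizedComparison", "twostage_compare"]


@dataclass
class TwoStageSpec:
    """Configuration of the two-stage procedure.

    ``group_populations`` maps each compared treatment level to its own
    target population over the selection covariates W;
    ``standard_distribution`` is the common reference over the
    standardization covariates Z.
    """

    selection_covariates: tuple[str, ...]
    standardization_covariates: tuple[str, ...]
    group_populations: dict[str, PopulationTable]
    standard_distribution: PopulationTable
    treated: str = "1"
    control: str = "0"

    def __post_init__(self) -> None:
        if not self.selection_covariates or not self.standardization_covariates:
            raise ValidationError("selection and standardization covariates must be nonempty")
        self.selection_covariates = sorted_covariates(self.selection_covariates)
        self.standardization_covariates = sorted_covariates(self.standardization_covariates)
        for level in (self.treated, self.control):
            if level not in self.group_populations:
                raise ValidationError(f"no group population for treatment level {level!r}")


@dataclass
class StandardizedComparison:
    per_group: dict[str, float]
    difference: float  # per_group[treated] - per_group[control], exactly
    stage1_weight_tables: dict[str, WeightTable] = field(default_factory=dict)


def _group_estimate(
    group: Microdata,
    level: str,
    spec: TwoStageSpec,
) -> tuple[float, WeightTable]:
    W = spec.selection_covariates
    Z = spec.standardization_covariates
    counts_w = crosstab(group, W)
    try:
        wtab = compute_cell_weights(counts_w, spec.group_populations[level])
    except (PositivityError, ValidationError) as err:
        raise type(err)(f"stage 1, group A={level!r}: {err}") from err
    w = unit_weights(group, wtab)
    y = group.outcomes
    z_keys = row_cells(group, Z)
    num: dict[CellKey, float] = {}
    den: dict[CellKey, float] = {}
    for key, wi, yi in zip(z_keys, w, y):
        num[key] = num.get(key, 0.0) + wi * yi
        den[key] = den.get(key, 0.0) + wi
    dist = spec.standard_distribution.proportions()
    missing = sorted(k for k, p in dist.items() if p > 0 and k not in den)
    if missing:
        raise PositivityError(
            f"stage 2, group A={level!r}: standard cells with no group units: {missing}",
            missing,
        )
    value = sum(p * num[k] / den[k] for k, p in dist.items() if p > 0)
    return float(value), wtab


def twostage_compare(data: Microdata, spec: TwoStageSpec) -> StandardizedComparison:
    """Run the two-stage procedure and return the standardized contrast."""
    if data.schema.treatment is None:
        raise ValidationError("microdata declares no treatment column")
    if spec.standard_distribution.covariates != spec.standardization_covariates:
        raise ValidationError(
            "standard distribution covariates "
            f"{spec.standard_distribution.covariates} do not match Z "
            f"{spec.standardization_covariates}"
        )
    if spec.selection_covariates == spec.standardization_covariates:
        logger.info(
            "selection and standardization covariates coincide; stage-1 "
            "reweighting only rescales within cells and cancels from the "
            "standardized means"
        )
    treatments = np.asarray([str(t) for t in data.treatments], dtype=object)
    per_group: dict[str, float] = {}
    tables: dict[str, WeightTable] = {}
    for level in (spec.treated, spec.control):
        group = data.subset(treatments == level)
        if len(group) == 0:
            raise ValidationError(f"treatment group A={level!r} is empty")
        per_group[level], tables[level] = _group_estimate(group, level, spec)
    return StandardizedComparison(
        per_group=per_group,
        difference=per_group[spec.treated] - per_group[spec.control],
        stage1_weight_tables=tables,
    )
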