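"""Core containers: unit-level microdata, population cell tables, stratum
counts, weight tables, and sample/population alignment.

Conventions
-----------
* Categorical levels are strings, compared exactly after stripping
  surrounding whitespace; no case folding (silent coercion could merge
  distinct strata).
* A *cell key* is a tuple of level strings ordered by the lexicographic
  order of the covariate names, so outputs are deterministic across runs.
* Delimited text is UTF-8 CSV with a header row; the dialect is fixed, not
  sniffed.
* Missing values are rejected, never imputed: the estimators downstream
  assume complete cells.

Every row of a :class:`Microdata` is a sampled unit — the sample-inclusion
indicator is implicitly 1 for all rows; unsampled units are represented only
through the external :class:`PopulationTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

CellKey = tuple[str, ...]

__all__ = [
    "CellKey",
    "Schema",
    "Microdata",
    "PopulationTable",
    "StratumCounts",
    "WeightTable",
    "AlignmentReport",
    "read_microdata",
    "write_microdata",
    "read_population_table",
    "write_population_table",
    "crosstab",
    "validate_alignment",
    "row_cells",
]


def _clean_level(value: object) -> str:
    return str(value).strip()


def sorted_covariates(names: Iterable[str]) -> tuple[str, ...]:
    """Canonical (lexicographic) covariate ordering used for all cell keys."""
    return tuple(sorted(names))


def _reorder_key(key: Sequence[str], given: Sequence[str], target: Sequence[str]) -> CellKey:
    pos = {name: i for i, name in enumerate(given)}
    return tuple(_clean_level(key[pos[name]]) for name in target)


@dataclass(frozen=True)
class Schema:
    """Declaration of microdata columns: covariates, outcome, optional
    treatment."""

    covariates: tuple[str, ...]
    outcome: str
    treatment: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if not self.covariates:
            raise SchemaError("at least one covariate must be declared")
        names = [*self.covariates, self.outcome]
        if self.treatment is not None:
            names.append(self.treatment)
        if len(set(names)) != len(names):
            raise SchemaError(f"duplicate column names in schema: {sorted(names)}")


@dataclass
class Microdata:
    """Validated unit-level records (sampled units only, delta = 1).

    ``frame`` holds one row per unit with string covariate/treatment columns
    and a float outcome column, in original row order.
    """

    frame: pd.DataFrame
    schema: Schema

    def __post_init__(self) -> None:
        cols = [*self.schema.covariates, self.schema.outcome]
        if self.schema.treatment is not None:
            cols.append(self.schema.treatment)
        missing = [c for c in cols if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"microdata is missing declared columns: {missing}")
        frame = self.frame.loc[:, cols].copy()
        frame.index = pd.RangeIndex(len(frame))
        categorical = list(self.schema.covariates)
        if self.schema.treatment is not None:
            categorical.append(self.schema.treatment)
        for col in categorical:
            frame[col] = frame[col].map(lambda v: _clean_level(v) if pd.notna(v) else v)
        for col in cols:
            bad = frame[col].isna() | (frame[col].astype(str).str.len() == 0)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(f"missing value in column {col!r} at row {row}")
        outcome = pd.to_numeric(frame[self.schema.outcome], errors="coerce")
        if outcome.isna().any():
            row = int(np.flatnonzero(outcome.isna().to_numpy())[0])
            raise ValidationError(
                f"non-numeric outcome in column {self.schema.outcome!r} at row {row}"
            )
        frame[self.schema.outcome] = outcome.astype(float)
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def outcomes(self) -> np.ndarray:
        return self.frame[self.schema.outcome].to_numpy(dtype=float)

    @property
    def treatments(self) -> np.ndarray:
        if self.schema.treatment is None:
            raise SchemaError("no treatment column declared")
        return self.frame[self.schema.treatment].to_numpy(dtype=object)

    def subset(self, mask: np.ndarray) -> "Microdata":
        """Row subset sharing the schema (used to split treatment groups)."""
        return Microdata(self.frame.loc[np.asarray(mask, dtype=bool)], self.schema)


@dataclass
class PopulationTable:
    """Target-population counts (or masses) per covariate cell.

    ``cells`` maps cell keys — ordered by the sorted covariate names — to
    nonnegative counts N_j; ``total`` is their sum N, so N_j / N estimates
    P(X = x_j) in the target population.
    """

    covariates: tuple[str, ...]
    cells: dict[CellKey, float]

    def __post_init__(self) -> None:
        order = sorted_covariates(self.covariates)
        if order != tuple(self.covariates):
            self.cells = {
                _reorder_key(k, self.covariates, order): v for k, v in self.cells.items()
            }
            self.covariates = order
        else:
            self.covariates = tuple(self.covariates)
            self.cells = {tuple(map(_clean_level, k)): float(v) for k, v in self.cells.items()}
        for key, value in self.cells.items():
            if len(key) != len(self.covariates):
                raise ValidationError(f"cell key {key} does not match covariates {self.covariates}")
            if value < 0:
                raise ValidationError(f"negative population count for cell {key}: {value}")
        if not self.cells or self.total <= 0:
            raise ValidationError("population table has zero total")
        self.cells = dict(sorted(self.cells.items()))

    @property
    def total(self) -> float:
        return float(sum(self.cells.values()))

    def proportions(self) -> dict[CellKey, float]:
        total = self.total
        return {k: v / total for k, v in self.cells.items()}

    def scaled(self, factor: float) -> "PopulationTable":
        return PopulationTable(self.covariates, {k: v * factor for k, v in self.cells.items()})


@dataclass
class StratumCounts:
    """Sample-side contingency table: n_j and the stratum outcome means."""

    covariates: tuple[str, ...]
    counts: dict[CellKey, int]
    means: dict[CellKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.covariates = sorted_covariates(self.covariates)
        self.counts = dict(sorted(self.counts.items()))
        self.means = dict(sorted(self.means.items()))

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class WeightTable:
    """Per-cell poststratification weights w_j.

    ``scale='population'``: w_j = N_j / n_j so that sum_j n_j w_j = N.
    ``scale='normalized'``: rescaled so the mean unit weight is 1
    (sum_j n_j w_j = n). Estimates are invariant to the scale.
    """

    covariates: tuple[str, ...]
    cells: dict[CellKey, float]
    scale: str = "population"

    def __post_init__(self) -> None:
        if self.scale not in ("population", "normalized"):
            raise ValidationError(f"unknown weight scale {self.scale!r}")
        self.covariates = sorted_covariates(self.covariates)
        for key, w in self.cells.items():
            if not w > 0:
                raise ValidationError(f"nonpositive weight for cell {key}: {w}")
        self.cells = dict(sorted(self.cells.items()))


@dataclass
class AlignmentReport:
    """Descriptive comparison of sample and population cell support.

    ``population_only`` nonempty means positivity for sample inclusion fails:
    some population stratum contributed no sampled units.
    """

    covariates: tuple[str, ...]
    matched: list[CellKey]
    sample_only: list[CellKey]
    population_only: list[CellKey]

    @property
    def positivity_ok(self) -> bool:
        return not self.population_only


# ---------------------------------------------------------------------------
# I/O


def read_microdata(path: str | Path, schema: Schema) -> Microdata:
    """Read unit-level CSV microdata and validate it against ``schema``."""
    frame = pd.read_csv(path, dtype=str, encoding="utf-8")
    return Microdata(frame, schema)


def write_microdata(data: Microdata, path: str | Path) -> None:
    data.frame.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def read_population_table(
    path: str | Path,
    covariates: Sequence[str],
    count_column: str = "count",
    proportions: bool = False,
    total: float | None = None,
) -> PopulationTable:
    """Read a one-row-per-cell CSV population table.

    With ``proportions=True`` the count column holds cell proportions; they
    are scaled by ``total`` when given (census sources publish both forms).
    Duplicate cells, negative counts and a zero total are rejected.
    """
    frame = pd.read_csv(path, dtype=str, encoding="utf-8")
    missing = [c for c in [*covariates, count_column] if c not in frame.columns]
    if missing:
        raise SchemaError(f"population table is missing columns: {missing}")
    counts = pd.to_numeric(frame[count_column], errors="coerce")
    if counts.isna().any():
        row = int(np.flatnonzero(counts.isna().to_numpy())[0])
        raise ValidationError(f"non-numeric count in column {count_column!r} at row {row}")
    order = sorted_covariates(covariates)
    keys = [
        tuple(_clean_level(frame.iloc[i][name]) for name in order) for i in range(len(frame))
    ]
    if len(set(keys)) != len(keys):
        seen: set[CellKey] = set()
        dup = next(k for k in keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate population cell {dup}")
    values = counts.to_numpy(dtype=float)
    if proportions and total is not None:
        values = values * float(total)
    return PopulationTable(order, dict(zip(keys, values)))


def write_population_table(
    table: PopulationTable, path: str | Path, count_column: str = "count"
) -> None:
    rows = [
        {**dict(zip(table.covariates, key)), count_column: value}
        for key, value in table.cells.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


# ---------------------------------------------------------------------------
# Cross-classification and alignment


def row_cells(data: Microdata, covariates: Sequence[str]) -> list[CellKey]:
    """Cell key of every microdata row, in row order."""
    order = sorted_covariates(covariates)
    bad = [c for c in order if c not in data.schema.covariates]
    if bad:
        raise SchemaError(f"covariates not declared in microdata schema: {bad}")
    cols = [data.frame[c].to_numpy(dtype=object) for c in order]
    return list(zip(*cols)) if cols else []


def crosstab(data: Microdata, covariates: Sequence[str]) -> StratumCounts:
    """Cross-classify microdata into strata: n_j and mean outcome per cell.

    One cell per *observed* covariate combination; cells the sample never
    saw simply do not appear (alignment against a population table reveals
    them).
    """
    if not covariates:
        raise ValidationError(
            "empty covariate list: request the grand mean via crude_mean instead"
        )
    order = sorted_covariates(covariates)
    keys = row_cells(data, order)
    grouped = (
        pd.DataFrame({"_cell": keys, "_y": data.outcomes}).groupby("_cell", sort=True)["_y"]
    )
    counts = {k: int(v) for k, v in grouped.size().items()}
    means = {k: float(v) for k, v in grouped.mean().items()}
    return StratumCounts(order, counts, means)


def validate_alignment(sample: StratumCounts, population: PopulationTable) -> AlignmentReport:
    """Partition cells into matched / sample-only / population-only.

    Purely descriptive: positivity failures are reported, not raised.
    Population cells with N_j = 0 and no sampled units carry no information
    either way and are omitted.
    """
    if sample.covariates != population.covariates:
        raise SchemaError(
            f"covariate mismatch: sample {sample.covariates} vs "
            f"population {population.covariates}"
        )
    sample_keys = {k for k, n in sample.counts.items() if n > 0}
    pop_keys = set(population.cells)
    pop_positive = {k for k, v in population.cells.items() if v > 0}
    matched = sorted(sample_keys & pop_keys)
    sample_only = sorted(sample_keys - pop_keys)
    population_only = sorted(pop_positive - sample_keys)
    return AlignmentReport(sample.covariates, matched, sample_only, population_only)
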