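"""Poststratification estimators and their equivalence."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from poststrat import (
    Microdata,
    PopulationTable,
    PositivityError,
    Schema,
    StratumCounts,
    ValidationError,
    cell_mean_aggregate,
    compute_cell_weights,
    crosstab,
    crude_mean,
    drop_empty_cells,
    weighted_mean,
)
from conftest import random_dataset


@pytest.fixture()
def koges_counts(koges_data):
    return crosstab(koges_data, ["age_group", "sex"])


@pytest.fixture()
def obesity_counts(obesity_data):
    return crosstab(obesity_data, ["sex"])


class TestCellWeights:
    def test_koges_men_40s_weight(self, koges_counts, koges_population):
        weights = compute_cell_weights(koges_counts, koges_population)
        assert round(weights.cells[("40-49", "men")], 1) == 1651.0

    def test_obesity_toy_weights(self, obesity_counts, obesity_population):
        weights = compute_cell_weights(obesity_counts, obesity_population)
        assert weights.cells[("men",)] == pytest.approx(1000 / 400)
        assert weights.cells[("women",)] == pytest.approx(1000 / 600)

    def test_proportional_sampling_gives_constant_weight(self):
        sample = StratumCounts(("x",), {("a",): 10, ("b",): 30}, {("a",): 0.5, ("b",): 0.5})
        population = PopulationTable(("x",), {("a",): 100, ("b",): 300})
        weights = compute_cell_weights(sample, population)
        assert list(weights.cells.values()) == pytest.approx([10.0, 10.0])

    def test_weight_accounting(self, koges_counts, koges_population):
        weights = compute_cell_weights(koges_counts, koges_population)
        applied = sum(koges_counts.counts[k] * w for k, w in weights.cells.items())
        assert applied == pytest.approx(koges_population.total, rel=1e-12)

    def test_normalized_scale_sums_to_n(self, koges_counts, koges_population):
        weights = compute_cell_weights(koges_counts, koges_population, scale="normalized")
        applied = sum(koges_counts.counts[k] * w for k, w in weights.cells.items())
        assert applied == pytest.approx(koges_counts.total, rel=1e-12)

    def test_empty_population_cell_errors_by_default(self):
        sample = StratumCounts(("x",), {("a",): 5}, {("a",): 0.2})
        population = PopulationTable(("x",), {("a",): 10, ("b",): 10})
        with pytest.raises(PositivityError, match=r"\('b',\)") as exc:
            compute_cell_weights(sample, population)
        assert exc.value.cells == [("b",)]

    def test_drop_and_renormalize_recovers_total(self, caplog):
        sample = StratumCounts(("x",), {("a",): 5}, {("a",): 0.2})
        population = PopulationTable(("x",), {("a",): 30, ("b",): 10})
        with caplog.at_level(logging.WARNING, logger="poststrat.estimators"):
            weights = compute_cell_weights(
                sample, population, on_empty="drop_and_renormalize"
            )
        # remaining cell rescaled: 30 * 40/30 = 40, weight 40/5
        assert weights.cells == {("a",): pytest.approx(8.0)}
        assert "25.00%" in caplog.text

    def test_sample_only_cell_always_errors(self):
        sample = StratumCounts(("x",), {("a",): 5, ("z",): 1})
        population = PopulationTable(("x",), {("a",): 10})
        with pytest.raises(ValidationError, match="coding|absent"):
            compute_cell_weights(sample, population, on_empty="drop_and_renormalize")


class TestWeightedMean:
    def test_koges_poststratified_smoking_rate(
        self, koges_data, koges_counts, koges_population
    ):
        weights = compute_cell_weights(koges_counts, koges_population)
        est = weighted_mean(koges_data, weights)
        assert round(100 * est.value, 1) == 26.5
        assert est.method == "weighted"
        assert est.total_weight == pytest.approx(koges_population.total)

    def test_obesity_toy(self, obesity_data, obesity_counts, obesity_population):
        weights = compute_cell_weights(obesity_counts, obesity_population)
        assert weighted_mean(obesity_data, weights).value == pytest.approx(0.20, abs=1e-12)

    def test_equal_weights_reduce_to_crude(self, obesity_data):
        from poststrat import WeightTable

        weights = WeightTable(("sex",), {("men",): 2.0, ("women",): 2.0})
        est = weighted_mean(obesity_data, weights)
        assert est.value == pytest.approx(crude_mean(obesity_data).value, rel=1e-12)

    def test_row_in_unweighted_cell_errors(self, obesity_data):
        from poststrat import WeightTable

        weights = WeightTable(("sex",), {("men",): 2.5})
        with pytest.raises(ValidationError, match=r"\('women',\)"):
            weighted_mean(obesity_data, weights)


class TestCellMeanAggregate:
    def test_obesity_toy_exact(self, obesity_counts, obesity_population):
        est = cell_mean_aggregate(obesity_counts, obesity_population)
        assert est.value == pytest.approx(0.20, abs=1e-12)
        assert est.method == "aggregated"

    def test_koges_matches_weighted(
        self, koges_data, koges_counts, koges_population
    ):
        weights = compute_cell_weights(koges_counts, koges_population)
        wm = weighted_mean(koges_data, weights).value
        agg = cell_mean_aggregate(koges_counts, koges_population).value
        assert abs(wm - agg) <= 1e-12

    def test_single_stratum_returns_its_mean(self):
        sample = StratumCounts(("x",), {("a",): 3}, {("a",): 0.7})
        population = PopulationTable(("x",), {("a",): 12345})
        assert cell_mean_aggregate(sample, population).value == pytest.approx(0.7)

    def test_missing_cell_mean_is_positivity_error(self):
        sample = StratumCounts(("x",), {("a",): 3}, {("a",): 0.7})
        population = PopulationTable(("x",), {("a",): 10, ("b",): 5})
        with pytest.raises(PositivityError):
            cell_mean_aggregate(sample, population)

    def test_drop_policy_applied_upstream(self):
        sample = StratumCounts(("x",), {("a",): 3}, {("a",): 0.7})
        population = PopulationTable(("x",), {("a",): 10, ("b",): 5})
        reduced = drop_empty_cells(population, sample)
        assert reduced.total == pytest.approx(15)
        assert cell_mean_aggregate(sample, reduced).value == pytest.approx(0.7)


class TestCrudeMean:
    def test_obesity_toy(self, obesity_data):
        assert crude_mean(obesity_data).value == pytest.approx(0.18, abs=1e-12)

    def test_constant_outcome(self):
        frame = pd.DataFrame({"x": ["a", "b"], "y": [1, 1]})
        assert crude_mean(Microdata(frame, Schema(("x",), "y"))).value == 1.0

    def test_koges_fixture_crude_from_rounded_rates(self, koges_data):
        # The expanded fixture reproduces Table 1's rounded stratum rates, so
        # its crude mean is ~25.6%, not the 25.7% computed on unrounded data.
        assert crude_mean(koges_data).value == pytest.approx(0.2555, abs=5e-4)

    def test_empty_data_errors(self):
        frame = pd.DataFrame({"x": pd.Series(dtype=str), "y": pd.Series(dtype=float)})
        with pytest.raises(ValidationError):
            crude_mean(Microdata(frame, Schema(("x",), "y")))


class TestEquivalenceAndInvariance:
    @given(st.integers(0, 2**31 - 1))
    def test_weighted_equals_aggregated(self, seed):
        rng = np.random.default_rng(seed)
        data, population = random_dataset(rng)
        counts = crosstab(data, ["x"])
        weights = compute_cell_weights(counts, population)
        wm = weighted_mean(data, weights).value
        agg = cell_mean_aggregate(counts, population).value
        assert abs(wm - agg) <= 1e-12

    @given(st.integers(0, 2**31 - 1))
    def test_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        data, population = random_dataset(rng)
        counts = crosstab(data, ["x"])
        pop_scale = compute_cell_weights(counts, population, scale="population")
        norm_scale = compute_cell_weights(counts, population, scale="normalized")
        a = weighted_mean(data, pop_scale).value
        b = weighted_mean(data, norm_scale).value
        assert a == pytest.approx(b, rel=1e-12, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_estimate_is_convex_combination_of_cell_means(self, seed):
        rng = np.random.default_rng(seed)
        data, population = random_dataset(rng, binary_outcome=False)
        counts = crosstab(data, ["x"])
        est = cell_mean_aggregate(counts, population).value
        means = list(counts.means.values())
        assert min(means) - 1e-12 <= est <= max(means) + 1e-12

    def test_matched_sampling_fraction_reduces_to_crude(self):
        # n_j / n == N_j / N in every cell -> poststratification is a no-op
        rng = np.random.default_rng(11)
        records = []
        for j, n_j in enumerate([4, 6, 10]):
            for _ in range(n_j):
                records.append({"x": f"c{j}", "y": float(rng.integers(0, 2))})
        data = Microdata(pd.DataFrame(records), Schema(("x",), "y"))
        population = PopulationTable(
            ("x",), {("c0",): 40.0, ("c1",): 60.0, ("c2",): 100.0}
        )
        counts = crosstab(data, ["x"])
        weights = compute_cell_weights(counts, population)
        wm = weighted_mean(data, weights).value
        assert abs(wm - crude_mean(data).value) <= 1e-12


class TestBruteForceOracle:
    def test_aggregate_recovers_enumerated_population_mean(self):
        """Materialize a full population (N <= 200) cell by cell; when the
        sample cell means equal the population cell means, the aggregation
        estimator recovers the enumerated population mean exactly."""
        cells = {("a",): (40, 0.25), ("b",): (100, 0.50), ("c",): (60, 0.10)}
        population_units = [
            mean for _, (count, mean) in sorted(cells.items()) for _ in range(count)
        ]
        true_mean = sum(population_units) / len(population_units)
        sample = StratumCounts(
            ("x",),
            {k: 2 for k in cells},
            {k: mean for k, (_, mean) in cells.items()},
        )
        population = PopulationTable(
            ("x",), {k: float(count) for k, (count, _) in cells.items()}
        )
        est = cell_mean_aggregate(sample, population).value
        assert est == pytest.approx(true_mean, abs=1e-15)
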