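from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from poststrat import (
    Microdata,
    PopulationTable,
    Schema,
    make_fixtures,
    read_microdata,
    read_population_table,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """The packaged worked-example CSVs, regenerated once per session."""
    return make_fixtures(tmp_path_factory.mktemp("fixtures"))


@pytest.fixture(scope="session")
def koges_schema():
    return Schema(covariates=("age_group", "sex"), outcome="smoker")


@pytest.fixture(scope="session")
def koges_data(fixture_paths, koges_schema):
    return read_microdata(fixture_paths["koges_table1_sample"], koges_schema)


@pytest.fixture(scope="session")
def koges_population(fixture_paths):
    return read_population_table(
        fixture_paths["koges_table1_census"], ["age_group", "sex"]
    )


@pytest.fixture(scope="session")
def obesity_data(fixture_paths):
    return read_microdata(
        fixture_paths["obesity_toy"], Schema(covariates=("sex",), outcome="obese")
    )


@pytest.fixture(scope="session")
def obesity_population(fixture_paths):
    return read_population_table(fixture_paths["obesity_toy_population"], ["sex"])


@pytest.fixture()
def toy8():
    """8-unit treatment toy: X=0 has 2 treated (Y=1,0) and 2 controls (Y=0,0);
    X=1 has 1 treated (Y=1) and 3 controls (Y=1,0,0)."""
    rows = [
        ("0", "1", 1), ("0", "1", 0), ("0", "0", 0), ("0", "0", 0),
        ("1", "1", 1), ("1", "0", 1), ("1", "0", 0), ("1", "0", 0),
    ]
    frame = pd.DataFrame(rows, columns=["x", "a", "y"])
    return Microdata(frame, Schema(covariates=("x",), outcome="y", treatment="a"))


def random_dataset(
    rng: np.random.Generator,
    max_cells: int = 20,
    with_treatment: bool = False,
    binary_outcome: bool = True,
):
    """A random single-covariate dataset plus an aligned population table.

    With ``with_treatment=True`` every cell is guaranteed at least one unit
    at level "1" so the saturated estimators of E[Y^1] are all defined.
    """
    J = int(rng.integers(1, max_cells + 1))
    records = []
    for j in range(J):
        n_j = int(rng.integers(1, 8))
        for i in range(n_j):
            y = float(rng.integers(0, 2)) if binary_outcome else float(rng.normal())
            rec = {"x": f"c{j:02d}", "y": y}
            if with_treatment:
                rec["a"] = "1" if i == 0 else str(rng.integers(0, 2))
            records.append(rec)
    schema = Schema(
        covariates=("x",), outcome="y", treatment="a" if with_treatment else None
    )
    data = Microdata(pd.DataFrame(records), schema)
    population = PopulationTable(
        ("x",),
        {(f"c{j:02d}",): float(rng.integers(1, 1000)) for j in range(J)},
    )
    return data, population
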