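"""Packaged worked examples, written deterministically as CSV.

Two examples ship with the package:

* The KoGES illustration — the Korean Genome and Epidemiology Study
  baseline cohort (10,030 adults aged 40-69 in 2001) cross-classified by
  age group and sex against the 2001 Korean Population Census, with the
  stratum current-smoking rates. The unit-level sample file is *expanded*
  from the stratum summaries: each cell contributes n_j rows of which
  round(n_j * rate_j) are smokers. The rounding convention is ours (the
  published summaries carry rates at one decimal), so the crude rate of the
  expanded file is ~25.6%, not the 25.7% computed on the original
  microdata; the poststratified rate agrees at 26.5% either way.
* The obesity toy — a nonprobability sample of 400 men (obesity rate 30%)
  and 600 women (10%) drawn from a population of 1000 men and 1000 women.

``make_fixtures`` writes byte-identical files on every run.
"""

from __future__ import annotations

from pathlib import Path

__all__ = [
    "KOGES_TABLE1",
    "OBESITY_TOY",
    "make_fixtures",
]

# (age_group, sex, census count, sample count, stratum smoking rate)
KOGES_TABLE1: list[tuple[str, str, int, int, float]] = [
    ("40-49", "men", 3_886_462, 2354, 0.531),
    ("40-49", "women", 3_758_072, 2357, 0.036),
    ("50-59", "men", 2_208_310, 1234, 0.480),
    ("50-59", "women", 2_245_444, 1383, 0.031),
    ("60-69", "men", 1_493_790, 1170, 0.443),
    ("60-69", "women", 1_821_163, 1532, 0.049),
]

# (sex, population count, sample count, stratum obesity rate)
OBESITY_TOY: list[tuple[str, int, int, float]] = [
    ("men", 1000, 400, 0.30),
    ("women", 1000, 600, 0.10),
]


def _round_half_up(x: float) -> int:
    return int(x + 0.5)


def _write(path: Path, header: str, lines: list[str]) -> None:
    path.write_text("\n".join([header, *lines]) + "\n", encoding="utf-8", newline="\n")


def make_fixtures(output_dir: str | Path) -> dict[str, Path]:
    """Write the packaged fixture CSVs into ``output_dir``.

    Returns a name -> path mapping. Idempotent and byte-identical across
    runs: rows follow the fixed stratum order, with positive outcomes first
    within each stratum.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    census_lines = [f"{age},{sex},{census}" for age, sex, census, _, _ in KOGES_TABLE1]
    paths["koges_table1_census"] = out / "koges_table1_census.csv"
    _write(paths["koges_table1_census"], "age_group,sex,count", census_lines)

    sample_lines: list[str] = []
    for age, sex, _, n, rate in KOGES_TABLE1:
        smokers = _round_half_up(n * rate)
        sample_lines.extend(f"{age},{sex},1" for _ in range(smokers))
        sample_lines.extend(f"{age},{sex},0" for _ in range(n - smokers))
    paths["koges_table1_sample"] = out / "koges_table1_sample.csv"
    _write(paths["koges_table1_sample"], "age_group,sex,smoker", sample_lines)

    toy_lines: list[str] = []
    for sex, _, n, rate in OBESITY_TOY:
        obese = _round_half_up(n * rate)
        toy_lines.extend(f"{sex},1" for _ in range(obese))
        toy_lines.extend(f"{sex},0" for _ in range(n - obese))
    paths["obesity_toy"] = out / "obesity_toy.csv"
    _write(paths["obesity_toy"], "sex,obese", toy_lines)

    toy_pop_lines = [f"{sex},{pop}" for sex, pop, _, _ in OBESITY_TOY]
    paths["obesity_toy_population"] = out / "obesity_toy_population.csv"
    _write(paths["obesity_toy_population"], "sex,count", toy_pop_lines)

    return paths
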