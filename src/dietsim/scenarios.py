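"""Intervention scenarios, percent-change summaries and benchmark validation.

Five scenarios are built from a baseline population by transforming each
person's food-group shares and recomputing all derived quantities:

* ``baseline`` — the population unchanged;
* ``mediterranean_shift`` / ``plant_forward`` — convex combination of each
  person's shares with a target composition, controlled by a single blend
  weight lambda (default 0.5);
* ``seasonal`` — season-conditional share rotation from a shipped table
  (fruit/vegetable boosted in their growing seasons, compensated from grain);
* ``affordability`` — blend toward the cost-minimal feasible diet found by
  the exhaustive grid oracle.

Validation compares population summaries against shipped benchmark tables:
sustainability thresholds (pass/fail per comparison rule) and reference
intake distributions (signed percentage deviation and IQR membership).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .food_db import (FOOD_GROUPS, FoodGroupProfile, RequirementSet,
                      default_requirements)
from .optimize import (ENERGY_BOUNDS, KCAL_PER_G_PROTEIN,
                       PROTEIN_ENERGY_BOUNDS, WEIGHTING_SCHEMES,
                       GridOracleResult, grid_oracle)
from .simulate import (CONSUMPTION_COLUMNS, PopulationTable, derive_all,
                       default_pattern_specs, plant_animal_ratio)

log = logging.getLogger(__name__)

SCENARIO_NAMES = ("baseline", "mediterranean_shift", "plant_forward",
                  "seasonal", "affordability")


@dataclass
class ScenarioResult:
    """Headline metrics of one scenario, relative to baseline where noted."""

    name: str
    iron_adequacy_pct: float
    calcium_adequacy_pct: float
    ghg_pct_of_baseline: float
    water_pct_of_baseline: float
    cost_usd_per_day: float
    diversity: float
    feasible: bool


@dataclass
class BenchmarkRow:
    metric: str
    model_estimate: float | None
    reference_value: str
    comparison: str
    threshold_pct: float
    deviation_pct: float | None
    passed: bool | None
    evaluable: bool = True
    source: str = ""


def percent_change(scenario_value: float, baseline_value: float) -> float:
    """Signed percent change of a scenario metric relative to baseline."""
    if baseline_value == 0:
        raise ValueError("baseline value must be non-zero")
    return 100.0 * (scenario_value - baseline_value) / baseline_value


def scenario_feasible(energy_kcal: float, protein_energy_ratio: float) -> bool:
    """Energy within 2000-3500 kcal/day and protein at 10-35% of energy."""
    return (ENERGY_BOUNDS[0] <= energy_kcal <= ENERGY_BOUNDS[1]
            and PROTEIN_ENERGY_BOUNDS[0] <= protein_energy_ratio <= PROTEIN_ENERGY_BOUNDS[1])


def round_reported(value: float, dp: int = 1) -> float:
    """Reporting convention for printed percentages.

    Half-away-from-zero rounding applied at two decimals first and then at
    the final precision, matching the reference tables' printed convention
    (e.g. -4.547 -> -4.55 -> -4.6).
    """
    d = Decimal(repr(float(value)))
    d = d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(d.quantize(Decimal(f"1e-{dp}"), rounding=ROUND_HALF_UP))


def percentage_deviation(model_estimate: float, reference: float,
                         signed: bool = False) -> float:
    """Deviation of a model estimate from a reference value, in percent.

    Absolute by default; ``signed=True`` keeps the direction (positive means
    the model overestimates).
    """
    if reference == 0:
        raise ValueError("reference value must be non-zero")
    dev = 100.0 * (model_estimate - reference) / reference
    return dev if signed else abs(dev)


def _target_shares(name: str, specs=None) -> np.ndarray:
    specs = specs or default_pattern_specs()
    if name == "mediterranean_shift":
        return np.asarray(specs["Mediterranean"].base_shares, float)
    if name == "plant_forward":
        # plant-forward target: the Plant-based composition with animal and
        # dairy removed, renormalized, so a full shift eliminates animal foods
        x = np.asarray(specs["Plant-based"].base_shares, float).copy()
        x[FOOD_GROUPS.index("Animal")] = 0.0
        x[FOOD_GROUPS.index("Dairy")] = 0.0
        return x / x.sum()
    raise ValueError(f"no target composition for scenario {name!r}")


def load_seasonal_rotation(path: str | Path | None = None) -> pd.DataFrame:
    """Season x food-group additive share deltas (rows sum to zero)."""
    if path is None:
        path = Path(str(resources.files("dietsim").joinpath("data", "seasonal_rotation.csv")))
    df = pd.read_csv(path).set_index("season")
    df.columns = [c.capitalize() for c in df.columns]
    return df[list(FOOD_GROUPS)]


def build_scenario(
    pop: PopulationTable,
    name: str,
    db: Sequence[FoodGroupProfile],
    lambda_shift: float = 0.5,
    requirements: RequirementSet | None = None,
    rotation: pd.DataFrame | None = None,
    grid_step: float = 0.05,
    ratio_cap: float = 50.0,
) -> PopulationTable:
    """Transform a baseline population into a scenario population.

    Each person keeps their total daily mass; shares are transformed by the
    scenario rule and all derived quantities recomputed.  Deterministic.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    if not 0.0 <= lambda_shift <= 1.0:
        raise ValueError("lambda_shift must lie in [0, 1]")
    df = pop.df.copy()
    cons = df[list(CONSUMPTION_COLUMNS)].to_numpy()
    mass = cons.sum(axis=1)
    shares = np.divide(cons, mass[:, None], out=np.zeros_like(cons), where=mass[:, None] > 0)

    if name == "baseline":
        new_shares = shares
    elif name in ("mediterranean_shift", "plant_forward"):
        target = _target_shares(name)
        new_shares = (1.0 - lambda_shift) * shares + lambda_shift * target
    elif name == "seasonal":
        rot = rotation if rotation is not None else load_seasonal_rotation()
        deltas = rot.loc[df["season"].to_numpy()].to_numpy()
        new_shares = np.maximum(shares + deltas, 0.0)
        new_shares /= new_shares.sum(axis=1, keepdims=True)
    elif name == "affordability":
        req = requirements or default_requirements()
        oracle = grid_oracle(db, requirements=req, weights=(0.0, 0.0, 1.0),
                             grid_step=grid_step)
        if oracle.feasible_region_empty:
            raise RuntimeError("affordability scenario: no feasible diet on the grid")
        cheap = np.asarray(oracle.diet.shares, float)
        new_shares = (1.0 - lambda_shift) * shares + lambda_shift * cheap

    new_cons = new_shares * mass[:, None]
    derived = derive_all(new_cons, db)
    df[list(CONSUMPTION_COLUMNS)] = new_cons
    for col in derived.columns:
        df[col] = derived[col].to_numpy()
    df["plant_animal_ratio"] = plant_animal_ratio(new_cons, cap=ratio_cap)
    meta = dict(pop.meta)
    meta.update({"scenario": name, "lambda_shift": lambda_shift})
    return PopulationTable(df=df, meta=meta)


def summarize_scenario(
    pop: PopulationTable,
    name: str,
    baseline: PopulationTable,
    requirements: RequirementSet | None = None,
) -> ScenarioResult:
    """Adequacy prevalences, footprint percentages of baseline, cost,
    diversity and the feasibility flag of one scenario population."""
    from .stats import adequacy_prevalence  # local import avoids cycle

    req = requirements or default_requirements()
    df = pop.df
    iron = adequacy_prevalence(df["iron_mg"], req.per_person("iron_mg", df["sex"]))
    calcium = adequacy_prevalence(df["calcium_mg"], req.per_person("calcium_mg", df["sex"]))
    mean_energy = float(df["energy_kcal"].mean())
    pe_ratio = float(df["protein_g"].mean() * KCAL_PER_G_PROTEIN / mean_energy)
    return ScenarioResult(
        name=name,
        iron_adequacy_pct=iron,
        calcium_adequacy_pct=calcium,
        ghg_pct_of_baseline=100.0 + percent_change(
            float(df["ghg_kgco2e"].mean()), float(baseline.df["ghg_kgco2e"].mean())),
        water_pct_of_baseline=100.0 + percent_change(
            float(df["water_l"].mean()), float(baseline.df["water_l"].mean())),
        cost_usd_per_day=float(df["cost_usd"].mean()),
        diversity=float(df["diversity_score"].mean()),
        feasible=scenario_feasible(mean_energy, pe_ratio),
    )


def run_scenarios(
    pop: PopulationTable,
    db: Sequence[FoodGroupProfile],
    lambdas: Mapping[str, float] | None = None,
    requirements: RequirementSet | None = None,
    grid_step: float = 0.05,
) -> pd.DataFrame:
    """Build and summarize all five scenarios; one row per scenario."""
    lambdas = dict(lambdas or {})
    rows = []
    baseline = build_scenario(pop, "baseline", db)
    for name in SCENARIO_NAMES:
        lam = lambdas.get(name, 0.5)
        scen = (baseline if name == "baseline"
                else build_scenario(pop, name, db, lambda_shift=lam,
                                    requirements=requirements, grid_step=grid_step))
        rows.append(vars(summarize_scenario(scen, name, baseline, requirements)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# benchmark validation
# ---------------------------------------------------------------------------

def _fixture(name: str) -> Path:
    return Path(str(resources.files("dietsim").joinpath("data", name)))


def load_sustainability_benchmarks(path: str | Path | None = None) -> pd.DataFrame:
    return pd.read_csv(path or _fixture("benchmarks_sustainability.csv"))


def load_reference_intakes(path: str | Path | None = None) -> pd.DataFrame:
    """Reference population intake distributions (survey means and IQRs)."""
    return pd.read_csv(path or _fixture("benchmarks_reference_intakes.csv"))


def validate_against_benchmarks(
    summary: Mapping[str, float],
    benchmarks: pd.DataFrame | None = None,
    threshold_pct: float = 20.0,
) -> list[BenchmarkRow]:
    """Check a population summary against sustainability benchmark rules.

    Comparison rules: ``lt`` / ``gt`` (strict threshold) and ``range``
    (``reference`` formatted ``low:high``).  Metrics missing from the summary
    yield a not-evaluable row rather than being dropped.  The percentage
    deviation from the reference is reported where the reference is non-zero.
    """
    bench = benchmarks if benchmarks is not None else load_sustainability_benchmarks()
    rows: list[BenchmarkRow] = []
    for _, b in bench.iterrows():
        metric = b["metric"]
        cmp_rule = b["comparison"]
        ref = str(b["reference"])
        src = b.get("source", "")
        if metric not in summary:
            rows.append(BenchmarkRow(metric=metric, model_estimate=None,
                                     reference_value=ref, comparison=cmp_rule,
                                     threshold_pct=threshold_pct, deviation_pct=None,
                                     passed=None, evaluable=False, source=src))
            continue
        value = float(summary[metric])
        if cmp_rule == "range":
            lo, hi = (float(v) for v in ref.split(":"))
            passed = lo <= value <= hi
            mid = 0.5 * (lo + hi)
            dev = percentage_deviation(value, mid) if mid != 0 else None
        elif cmp_rule in ("lt", "gt"):
            ref_val = float(ref)
            passed = value < ref_val if cmp_rule == "lt" else value > ref_val
            dev = percentage_deviation(value, ref_val) if ref_val != 0 else None
        else:
            raise ValueError(f"unknown comparison rule {cmp_rule!r}")
        rows.append(BenchmarkRow(metric=metric, model_estimate=value,
                                 reference_value=ref, comparison=cmp_rule,
                                 threshold_pct=threshold_pct, deviation_pct=dev,
                                 passed=bool(passed), source=src))
    return rows


def validate_against_reference_intakes(
    summary: Mapping[str, float],
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Signed percentage deviation from survey reference means plus IQR check.

    ``summary`` maps metric names (e.g. ``energy_kcal``) to simulated means.
    Deviations are rounded with the printed-table convention.
    """
    ref = reference if reference is not None else load_reference_intakes()
    rows = []
    for _, r in ref.iterrows():
        metric = r["metric"]
        if metric not in summary:
            rows.append({"metric": metric, "simulated_mean": None,
                         "reference_mean": r["reference_mean"],
                         "deviation_pct": None, "within_reference_iqr": None})
            continue
        value = float(summary[metric])
        dev = round_reported(
            percentage_deviation(value, float(r["reference_mean"]), signed=True))
        rows.append({
            "metric": metric,
            "simulated_mean": value,
            "reference_mean": float(r["reference_mean"]),
            "deviation_pct": dev,
            "within_reference_iqr": bool(r["iqr_low"] <= value <= r["iqr_high"]),
        })
    return pd.DataFrame(rows)
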