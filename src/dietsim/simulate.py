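"""Synthetic population generator.

Each simulated person belongs to one of four dietary patterns and receives
demographics, Dirichlet-distributed food-group shares, a total daily food
mass drawn from a truncated normal, and derived quantities: nutrient intakes
(weighted sum of consumption x density), greenhouse-gas and water footprints,
daily cost, a dietary diversity score and a plant-to-animal mass ratio.

The shipped pattern specifications (``data/pattern_specs.json``) are
calibrated so the pattern-level means of every derived metric land on the
target values; see ``docs/methods.md`` for the calibration procedure and
``scripts/calibrate_defaults.py`` to regenerate them.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .food_db import FOOD_GROUPS, FoodGroupProfile, density_matrix

log = logging.getLogger(__name__)

PATTERNS: tuple[str, ...] = ("Mediterranean", "Western", "Plant-based", "Mixed")

AGE_BOUNDS = (18.0, 80.0)
BMI_BOUNDS = (15.0, 50.0)

CONSUMPTION_COLUMNS = tuple(f"cons_{g.lower()}_kg" for g in FOOD_GROUPS)
NUTRIENT_FIELDS = ("energy_kcal", "protein_g", "iron_mg", "calcium_mg",
                   "zinc_mg", "vitd_ug", "b12_ug")
DERIVED_FIELDS = NUTRIENT_FIELDS + ("ghg_kgco2e", "water_l", "cost_usd")
POPULATION_COLUMNS = (
    ("person_id", "pattern", "age_years", "sex", "bmi_kg_m2", "income_quintile",
     "education_tertiary", "season")
    + CONSUMPTION_COLUMNS + DERIVED_FIELDS
    + ("diversity_score", "plant_animal_ratio")
)


class ConfigError(ValueError):
    """Raised for invalid simulation configuration."""


@dataclass(frozen=True)
class PatternSpec:
    """Generator parameters for one dietary pattern.

    ``base_shares`` is the expected food-group composition (simplex vector in
    canonical group order) and ``concentration`` the Dirichlet concentration
    alpha0; draws follow Dirichlet(concentration x base_shares).  The daily
    food mass is a truncated normal on ``mass_bounds_kg`` parameterized by
    ``mass_loc_kg`` / ``mass_scale_kg`` (pre-truncation location and scale).
    """

    pattern_name: str
    base_shares: tuple[float, ...]
    concentration: float
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    female_fraction: float
    income_mean: float
    income_sd: float
    tertiary_fraction: float
    mass_loc_kg: float = 2.0
    mass_scale_kg: float = 0.5
    mass_bounds_kg: tuple[float, float] = (0.5, 6.0)

    def __post_init__(self) -> None:
        shares = np.asarray(self.base_shares, float)
        if shares.shape != (len(FOOD_GROUPS),):
            raise ConfigError(f"base_shares must have {len(FOOD_GROUPS)} components")
        if (shares < 0).any():
            raise ConfigError("base_shares must be non-negative")
        if abs(shares.sum() - 1.0) > 1e-9:
            raise ConfigError(f"base_shares must sum to 1, got {shares.sum():.12f}")
        if self.concentration <= 0:
            raise ConfigError("concentration must be positive")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction must be in [0, 1]")


@dataclass(frozen=True)
class DiversityModel:
    """Dietary diversity score: distinct foods per day.

    Sampled from a discretized normal clipped to ``bounds`` — an attribute of
    the person, not derived from the consumption vector (no derivation is
    defined for it at the food-group level)."""

    mean: float = 11.1
    sd: float = 2.0
    bounds: tuple[int, int] = (4, 20)


@dataclass
class PopulationTable:
    """A simulated population: one row per person-day plus run metadata."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.df.empty:
            raise ConfigError("population table is empty")
        missing = [c for c in POPULATION_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigError(f"population table missing column(s): {missing}")
        if self.df["person_id"].duplicated().any() and int(self.meta.get("days_per_person", 1)) == 1:
            raise ConfigError("person_id values are not unique")

    def pattern_counts(self) -> pd.Series:
        return self.df["pattern"].value_counts()

    def consumption_matrix(self) -> np.ndarray:
        return self.df[list(CONSUMPTION_COLUMNS)].to_numpy()

    def write(self, path: str | Path) -> None:
        """CSV with a JSON metadata sidecar (``<path>.meta.json``)."""
        path = Path(path)
        self.df.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(self.meta, indent=1, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "PopulationTable":
        path = Path(path)
        df = pd.read_csv(path)
        if df.empty:
            raise ConfigError(f"{path}: empty population file")
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(df=df, meta=meta)


def default_pattern_specs() -> dict[str, PatternSpec]:
    """The four shipped pattern specifications (calibrated defaults)."""
    raw = json.loads(
        Path(str(resources.files("dietsim").joinpath("data", "pattern_specs.json"))).read_text()
    )
    bounds = tuple(raw["mass_bounds_kg"])
    specs = {}
    for name, p in raw["patterns"].items():
        specs[name] = PatternSpec(
            pattern_name=name,
            base_shares=tuple(p["base_shares"]),
            concentration=p["concentration"],
            age_mean=p["age_mean"], age_sd=p["age_sd"],
            bmi_mean=p["bmi_mean"], bmi_sd=p["bmi_sd"],
            female_fraction=p["female_fraction"],
            income_mean=p["income_mean"], income_sd=p["income_sd"],
            tertiary_fraction=p["tertiary_fraction"],
            mass_loc_kg=p["mass_loc_kg"], mass_scale_kg=p["mass_scale_kg"],
            mass_bounds_kg=bounds,
        )
    return specs


def default_diversity_model() -> DiversityModel:
    raw = json.loads(
        Path(str(resources.files("dietsim").joinpath("data", "pattern_specs.json"))).read_text()
    )
    d = raw["diversity"]
    return DiversityModel(mean=d["mean"], sd=d["sd"], bounds=tuple(d["bounds"]))


def sample_shares(spec: PatternSpec, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
    """Dirichlet draw(s) of food-group shares for one pattern."""
    alpha = spec.concentration * np.asarray(spec.base_shares, float)
    if (alpha <= 0).any():
        raise ConfigError("Dirichlet concentrations must all be positive; "
                          "base_shares may not contain zeros")
    return rng.dirichlet(alpha, size) if size is not None else rng.dirichlet(alpha)


def _truncated_normal(rng: np.random.Generator, loc: float, scale: float,
                      low: float, high: float, size: int) -> np.ndarray:
    a, b = (low - loc) / scale, (high - loc) / scale
    return truncnorm(a, b, loc=loc, scale=scale).rvs(size=size, random_state=rng)


def sample_demographics(spec: PatternSpec, rng: np.random.Generator, size: int) -> pd.DataFrame:
    """Demographic draws: age/BMI truncated normals, sex/education Bernoulli,
    income quintile a discretized clipped normal, season uniform on 1-4."""
    age = _truncated_normal(rng, spec.age_mean, spec.age_sd, *AGE_BOUNDS, size=size)
    bmi = _truncated_normal(rng, spec.bmi_mean, spec.bmi_sd, *BMI_BOUNDS, size=size)
    sex = np.where(rng.random(size) < spec.female_fraction, "female", "male")
    income = np.clip(np.rint(rng.normal(spec.income_mean, spec.income_sd, size)), 1, 5).astype(int)
    education = rng.random(size) < spec.tertiary_fraction
    season = rng.integers(1, 5, size)
    return pd.DataFrame({
        "age_years": age, "sex": sex, "bmi_kg_m2": bmi,
        "income_quintile": income, "education_tertiary": education, "season": season,
    })


def _as_matrix(consumption_kg: np.ndarray) -> tuple[np.ndarray, bool]:
    arr = np.asarray(consumption_kg, float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != len(FOOD_GROUPS):
        raise ValueError(f"consumption vector must have {len(FOOD_GROUPS)} components")
    if (arr < 0).any():
        raise ValueError("consumption must be non-negative")
    return arr, single


def compute_intakes(consumption_kg: np.ndarray,
                    db: Sequence[FoodGroupProfile]) -> pd.DataFrame:
    """Nutrient intakes as the weighted sum consumption x per-kg density.

    Accepts a single 8-vector or an (n, 8) matrix of kg/day consumptions;
    returns a DataFrame with one row per person and the seven nutrient
    columns.  Deterministic and order-independent.
    """
    arr, _ = _as_matrix(consumption_kg)
    dm = density_matrix(db)
    nutr_cols = [c.replace("_per_100g", "_per_kg") for c in
                 ("energy_kcal_per_100g", "protein_g_per_100g", "iron_mg_per_100g",
                  "calcium_mg_per_100g", "zinc_mg_per_100g", "vitd_ug_per_100g",
                  "b12_ug_per_100g")]
    values = arr @ dm[nutr_cols].to_numpy()
    return pd.DataFrame(values, columns=list(NUTRIENT_FIELDS))


def compute_footprints(consumption_kg: np.ndarray,
                       db: Sequence[FoodGroupProfile]) -> pd.DataFrame:
    """GHG (kg CO2e), water (L) and cost (USD) of daily consumption."""
    arr, _ = _as_matrix(consumption_kg)
    dm = density_matrix(db)
    values = arr @ dm[["ghg_kgco2e_per_kg", "water_l_per_kg", "price_usd_per_kg"]].to_numpy()
    return pd.DataFrame(values, columns=["ghg_kgco2e", "water_l", "cost_usd"])


def derive_all(consumption_kg: np.ndarray, db: Sequence[FoodGroupProfile]) -> pd.DataFrame:
    """All derived per-person quantities (nutrients + footprints + cost)."""
    return pd.concat(
        [compute_intakes(consumption_kg, db), compute_footprints(consumption_kg, db)],
        axis=1,
    )


def plant_animal_ratio(consumption_kg: np.ndarray, cap: float = 50.0) -> np.ndarray:
    """Plant-to-animal mass ratio: (non-animal, non-dairy) / (animal + dairy).

    Capped at ``cap`` to keep zero-denominator diets finite."""
    arr, single = _as_matrix(consumption_kg)
    animal_ix = [FOOD_GROUPS.index("Animal"), FOOD_GROUPS.index("Dairy")]
    plant_ix = [i for i in range(len(FOOD_GROUPS)) if i not in animal_ix]
    denom = arr[:, animal_ix].sum(axis=1)
    numer = arr[:, plant_ix].sum(axis=1)
    with np.errstate(divide="ignore"):
        ratio = np.where(denom > 0, numer / np.maximum(denom, 1e-300), cap)
    ratio = np.minimum(ratio, cap)
    return ratio[0] if single else ratio


def config_hash(payload: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def simulate_population(
    db: Sequence[FoodGroupProfile],
    specs: Mapping[str, PatternSpec] | None = None,
    n_per_pattern: int = 375,
    days_per_person: int = 1,
    seed: int = 42,
    diversity: DiversityModel | None = None,
    ratio_cap: float = 50.0,
    n_total: int | None = None,
) -> PopulationTable:
    """Generate the simulated population (default 375 persons x 4 patterns).

    Deterministic given ``seed``.  Rows are person-days: with
    ``days_per_person > 1`` each person contributes several rows sharing
    demographics but with independent consumption draws.  ``n_total`` may be
    given instead of ``n_per_pattern``; it must divide evenly across patterns.
    """
    specs = specs or default_pattern_specs()
    diversity = diversity or default_diversity_model()
    if n_total is not None:
        if n_total % len(specs):
            raise ConfigError(
                f"n_total={n_total} is not divisible by the {len(specs)} patterns"
            )
        n_per_pattern = n_total // len(specs)
    if n_per_pattern <= 0:
        raise ConfigError("n_per_pattern must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    next_id = 0
    for name in specs:
        spec = specs[name]
        n_days = n_per_pattern * days_per_person
        demo = sample_demographics(spec, rng, n_per_pattern)
        demo = demo.loc[demo.index.repeat(days_per_person)].reset_index(drop=True)
        shares = sample_shares(spec, rng, size=n_days)
        lo, hi = spec.mass_bounds_kg
        mass = _truncated_normal(rng, spec.mass_loc_kg, spec.mass_scale_kg, lo, hi, n_days)
        consumption = shares * mass[:, None]
        derived = derive_all(consumption, db)
        div = np.clip(
            np.rint(rng.normal(diversity.mean, diversity.sd, n_days)),
            *diversity.bounds,
        ).astype(int)
        frame = pd.DataFrame({
            "person_id": np.repeat(np.arange(n_per_pattern), days_per_person) + next_id,
            "pattern": name,
        })
        next_id += n_per_pattern
        frame = pd.concat([frame, demo], axis=1)
        cons_df = pd.DataFrame(consumption, columns=list(CONSUMPTION_COLUMNS))
        frame = pd.concat([frame, cons_df, derived], axis=1)
        frame["diversity_score"] = div
        frame["plant_animal_ratio"] = plant_animal_ratio(consumption, cap=ratio_cap)
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)
    meta = {
        "seed": int(seed),
        "n_per_pattern": int(n_per_pattern),
        "days_per_person": int(days_per_person),
        "patterns": list(specs),
        "config_hash": config_hash({
            "n_per_pattern": n_per_pattern, "days_per_person": days_per_person,
            "seed": seed, "specs": {k: vars(v) for k, v in specs.items()},
        }),
    }
    log.info("simulated %d person-days across %d patterns (seed=%d)",
             len(df), len(specs), seed)
    return PopulationTable(df=df, meta=meta)
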