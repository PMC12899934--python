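"""Food-group composition database: nutrient densities, footprints, prices.

The database is represented at the level of eight food groups (not individual
foods) because every downstream aggregation sums over the eight groups.
Per-100 g nutrient densities follow food-composition-table convention;
greenhouse-gas, water and price factors are per kilogram.

Zinc, vitamin D and B12 group densities are calibrated stand-ins (no
group-level reference values are available for them); they are solved so that
the simulated population means land on the target pattern means, see
``scripts/calibrate_defaults.py`` and ``docs/methods.md``.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FOOD_GROUPS: tuple[str, ...] = (
    "Animal", "Dairy", "Fruit", "Grain", "Legume", "Nuts", "Oil", "Vegetable",
)

#: nutrients measured per 100 g in the database, in canonical column order
NUTRIENT_COLUMNS: tuple[str, ...] = (
    "energy_kcal_per_100g",
    "protein_g_per_100g",
    "iron_mg_per_100g",
    "calcium_mg_per_100g",
    "zinc_mg_per_100g",
    "vitd_ug_per_100g",
    "b12_ug_per_100g",
)
#: calibrated extension nutrients absent from the core reference table
EXTENSION_COLUMNS: tuple[str, ...] = (
    "zinc_mg_per_100g", "vitd_ug_per_100g", "b12_ug_per_100g",
)
FOOTPRINT_COLUMNS: tuple[str, ...] = (
    "ghg_kgco2e_per_kg", "water_l_per_kg", "price_usd_per_kg",
)
MEAN_COLUMNS: tuple[str, ...] = NUTRIENT_COLUMNS + FOOTPRINT_COLUMNS


class FoodTableError(ValueError):
    """Raised when a food-group table violates the documented schema."""


@dataclass(frozen=True)
class FoodGroupProfile:
    """Composition, footprint and price profile of one food group.

    Nutrient densities are per 100 g; footprint and price factors per kg.
    Every mean has a matching ``<name>_sd`` within-group standard deviation,
    and ``n_foods`` records how many representative foods the group averages.
    """

    group_name: str
    energy_kcal_per_100g: float
    protein_g_per_100g: float
    iron_mg_per_100g: float
    calcium_mg_per_100g: float
    zinc_mg_per_100g: float
    vitd_ug_per_100g: float
    b12_ug_per_100g: float
    ghg_kgco2e_per_kg: float
    water_l_per_kg: float
    price_usd_per_kg: float
    energy_kcal_per_100g_sd: float = 0.0
    protein_g_per_100g_sd: float = 0.0
    iron_mg_per_100g_sd: float = 0.0
    calcium_mg_per_100g_sd: float = 0.0
    zinc_mg_per_100g_sd: float = 0.0
    vitd_ug_per_100g_sd: float = 0.0
    b12_ug_per_100g_sd: float = 0.0
    ghg_kgco2e_per_kg_sd: float = 0.0
    water_l_per_kg_sd: float = 0.0
    price_usd_per_kg_sd: float = 0.0
    n_foods: int = 1

    def __post_init__(self) -> None:
        if self.group_name not in FOOD_GROUPS:
            raise FoodTableError(
                f"unknown food group {self.group_name!r}; expected one of {FOOD_GROUPS}"
            )
        for f in fields(self):
            if f.name == "group_name":
                continue
            value = getattr(self, f.name)
            if value < 0:
                raise FoodTableError(
                    f"{self.group_name}: {f.name} must be non-negative, got {value}"
                )
        if self.n_foods < 1:
            raise FoodTableError(f"{self.group_name}: n_foods must be positive")


# Core reference values: per-100g energy/protein/iron/calcium (mean, sd),
# per-kg GHG/water/price (mean, sd), and number of representative foods.
_CORE_TABLE: dict[str, tuple] = {
    #           energy        protein      iron          calcium         ghg           water         price         n
    "Animal":    ((189.4, 68.8), (24.2, 5.6), (1.06, 0.89), (13.6, 3.4),   (10.58, 9.22), (6678, 4964), (11.50, 3.87), 5),
    "Dairy":     ((275.0, 285.9), (10.5, 9.5), (0.54, 0.76), (204.8, 291.0), (6.90, 5.52), (3293, 2280), (6.14, 5.62), 5),
    "Fruit":     ((62.8, 16.8), (0.7, 0.3),  (0.24, 0.13), (15.4, 14.4),  (0.92, 0.67),  (633, 179),   (3.46, 1.43), 5),
    "Grain":     ((248.8, 122.8), (9.0, 5.3), (2.72, 1.56), (54.7, 64.6),  (2.07, 0.69),  (2496, 1394), (3.52, 1.60), 10),
    "Legume":    ((197.0, 140.3), (14.4, 12.4), (5.54, 5.68), (83.8, 108.7), (1.24, 0.44), (4460, 1427), (4.08, 0.82), 5),
    "Nuts":      ((574.0, 59.8), (20.0, 4.2), (4.84, 1.84), (233.6, 235.5), (2.08, 0.58), (5371, 3488), (17.10, 6.84), 5),
    "Oil":       ((701.4, 310.6), (0.4, 0.9), (0.30, 0.28), (6.6, 9.0),    (3.44, 1.61),  (6348, 4969), (8.60, 4.63), 5),
    "Vegetable": ((39.0, 24.1), (1.6, 0.8),  (0.73, 0.73), (33.7, 26.6),  (1.03, 0.65),  (276, 74),    (2.78, 0.96), 10),
}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("dietsim").joinpath("data", name)))


def _extension_densities() -> dict[str, dict[str, float]]:
    """Calibrated per-100g zinc / vitamin D / B12 densities, keyed by group."""
    spec = json.loads(_data_path("pattern_specs.json").read_text())
    ext = spec["extension_densities_per_100g"]
    groups = ext["groups"]
    out: dict[str, dict[str, float]] = {g: {} for g in groups}
    for key, col in (("zinc_mg", "zinc_mg_per_100g"),
                     ("vitd_ug", "vitd_ug_per_100g"),
                     ("b12_ug", "b12_ug_per_100g")):
        for g, v in zip(groups, ext[key]):
            out[g][col] = float(v)
    return out


def default_food_table() -> list[FoodGroupProfile]:
    """The shipped eight-group database.

    Core columns carry the reference means/SDs; extension nutrient densities
    come from the calibration fixture, with synthetic within-group SDs set to
    half the mean (no reference spread exists for them).
    """
    ext = _extension_densities()
    profiles = []
    for g, row in _CORE_TABLE.items():
        (e, p, fe, ca, ghg, wat, pr, n) = row
        kw: dict = {"group_name": g, "n_foods": n}
        for col, (mean, sd) in zip(
            ("energy_kcal_per_100g", "protein_g_per_100g", "iron_mg_per_100g",
             "calcium_mg_per_100g", "ghg_kgco2e_per_kg", "water_l_per_kg",
             "price_usd_per_kg"),
            (e, p, fe, ca, ghg, wat, pr),
        ):
            kw[col] = float(mean)
            kw[col + "_sd"] = float(sd)
        for col, mean in ext[g].items():
            kw[col] = mean
            kw[col + "_sd"] = round(0.5 * mean, 4)  # synthetic spread
        profiles.append(FoodGroupProfile(**kw))
    return profiles


def _validate_profiles(profiles: Iterable[FoodGroupProfile]) -> list[FoodGroupProfile]:
    profiles = list(profiles)
    names = [p.group_name for p in profiles]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise FoodTableError(f"duplicate food group name(s): {sorted(dupes)}")
    missing = [g for g in FOOD_GROUPS if g not in names]
    if missing:
        raise FoodTableError(f"incomplete database, missing group(s): {missing}")
    return sorted(profiles, key=lambda p: FOOD_GROUPS.index(p.group_name))


def load_food_table(path: str | Path) -> list[FoodGroupProfile]:
    """Load and validate a food-group table from CSV.

    Missing extension nutrient columns (zinc / vitamin D / B12) are filled
    from the shipped calibration fixture with a logged warning.  Raises
    :class:`FoodTableError` on schema violations (duplicate or missing
    groups, negative values, unknown group names).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if "group_name" not in df.columns:
        raise FoodTableError("missing required column 'group_name'")
    missing_core = [c for c in MEAN_COLUMNS
                    if c not in df.columns and c not in EXTENSION_COLUMNS]
    if missing_core:
        raise FoodTableError(f"missing required column(s): {missing_core}")

    filled = [c for c in EXTENSION_COLUMNS if c not in df.columns]
    if filled:
        log.warning(
            "food table %s lacks extension column(s) %s; "
            "filling from the shipped calibration fixture", path, filled
        )
        ext = _extension_densities()
        for col in filled:
            df[col] = [ext.get(g, {}).get(col, 0.0) for g in df["group_name"]]
            df[col + "_sd"] = [round(0.5 * v, 4) for v in df[col]]

    field_names = {f.name for f in fields(FoodGroupProfile)}
    profiles = []
    for _, row in df.iterrows():
        kw = {}
        for col in df.columns:
            if col not in field_names:
                continue
            value = row[col]
            if col != "group_name" and pd.notna(value) and value < 0:
                raise FoodTableError(
                    f"negative value in row {row['group_name']!r}, column {col!r}: {value}"
                )
            kw[col] = value if col == "group_name" else (
                int(value) if col == "n_foods" else float(value)
            )
        for col in field_names - set(kw):
            if col.endswith("_sd"):
                kw[col] = 0.0
        profiles.append(FoodGroupProfile(**kw))
    return _validate_profiles(profiles)


def write_food_table(profiles: Iterable[FoodGroupProfile], path: str | Path) -> None:
    """Write a complete eight-group table to CSV (lossless round-trip)."""
    profiles = list(profiles)
    if not profiles:
        raise FoodTableError("refusing to write an empty food table")
    profiles = _validate_profiles(profiles)
    cols = [f.name for f in fields(FoodGroupProfile)]
    df = pd.DataFrame([{c: getattr(p, c) for c in cols} for p in profiles])
    df.to_csv(path, index=False)


def density_matrix(profiles: Iterable[FoodGroupProfile]) -> pd.DataFrame:
    """Per-kg coefficient matrix, rows = food groups in canonical order.

    Nutrient densities are converted from per-100 g to per-kg here, exactly
    once; footprint/price factors are already per kg.
    """
    profiles = _validate_profiles(profiles)
    rows = {}
    for p in profiles:
        rows[p.group_name] = (
            [getattr(p, c) * 10.0 for c in NUTRIENT_COLUMNS]
            + [getattr(p, c) for c in FOOTPRINT_COLUMNS]
        )
    cols = [c.replace("_per_100g", "_per_kg") for c in NUTRIENT_COLUMNS] + list(FOOTPRINT_COLUMNS)
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).loc[list(FOOD_GROUPS)]


@dataclass(frozen=True)
class RequirementSet:
    """Per-nutrient, per-sex intake thresholds.

    ``thresholds[nutrient][sex]`` is the daily requirement; ``kinds`` records
    whether each is an estimated average requirement (EAR, the cut-point used
    for adequacy prevalence) or a recommended dietary allowance (RDA).
    Protein is expressed per kg body mass (``protein_g_per_kg``).
    """

    thresholds: Mapping[str, Mapping[str, float]]
    kinds: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for nutrient, by_sex in self.thresholds.items():
            for sex in ("male", "female"):
                if sex not in by_sex:
                    raise ValueError(f"{nutrient}: missing threshold for sex {sex!r}")
                if by_sex[sex] <= 0:
                    raise ValueError(f"{nutrient}/{sex}: threshold must be positive")

    def threshold(self, nutrient: str, sex: str) -> float:
        return float(self.thresholds[nutrient][sex])

    def per_person(self, nutrient: str, sexes: "np.ndarray | pd.Series") -> np.ndarray:
        """Vector of thresholds matching a per-person sex array."""
        male = self.threshold(nutrient, "male")
        female = self.threshold(nutrient, "female")
        return np.where(np.asarray(sexes) == "female", female, male)

    def with_overrides(self, overrides: Mapping[str, Mapping[str, float]]) -> "RequirementSet":
        merged = {k: dict(v) for k, v in self.thresholds.items()}
        for nutrient, by_sex in overrides.items():
            merged.setdefault(nutrient, {}).update(by_sex)
        return replace(self, thresholds=merged)


def default_requirements() -> RequirementSet:
    """Default adult thresholds used throughout the package.

    Iron 8 mg/day (male) and 18 mg/day (female), calcium 1000 mg/day, zinc
    11/8 mg/day, vitamin D 20 ug/day, B12 6 ug/day, protein 0.8 g per kg body
    mass; all configurable via :meth:`RequirementSet.with_overrides`.
    """
    both = lambda v: {"male": v, "female": v}  # noqa: E731
    return RequirementSet(
        thresholds={
            "iron_mg": {"male": 8.0, "female": 18.0},
            "calcium_mg": both(1000.0),
            "zinc_mg": {"male": 11.0, "female": 8.0},
            "vitd_ug": both(20.0),
            "b12_ug": both(6.0),
            "protein_g_per_kg": both(0.8),
        },
        kinds={
            "iron_mg": "EAR", "calcium_mg": "EAR", "zinc_mg": "EAR",
            "vitd_ug": "RDA", "b12_ug": "RDA", "protein_g_per_kg": "RDA",
        },
    )
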