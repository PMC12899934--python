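"""Constrained tri-objective diet optimization.

A diet is an 8-component food-group share vector on the simplex (each share
capped at 40%) plus a total daily mass.  Three objectives are evaluated:

* f1 — micronutrient adequacy: the mean of four requirement ratios
  (iron/EAR, calcium/EAR, zinc/EAR, protein/RDA), maximized;
* f2 — environmental impact: the mean of GHG and water footprints, each
  normalized by its observed maximum (3.96 kg CO2e/day, 4175 L/day), minimized;
* f3 — daily cost normalized by a configured maximum, minimized.

Feasible diets keep energy within 2000-3500 kcal/day and protein within
10-35% of energy (4 kcal/g).  Search uses an NSGA-II implementation with
simulated-binary crossover, polynomial mutation, share repair for the cap
constraint and feasibility-first domination; a weighted-sum rule then picks
single diets from the Pareto set, cross-checked by an exhaustive grid oracle.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import gamma as sps_gamma

from .food_db import (FOOD_GROUPS, FoodGroupProfile, RequirementSet,
                      default_requirements, density_matrix)

log = logging.getLogger(__name__)

SHARE_CAP = 0.4
ENERGY_BOUNDS = (2000.0, 3500.0)
PROTEIN_ENERGY_BOUNDS = (0.10, 0.35)
KCAL_PER_G_PROTEIN = 4.0
#: observed maximum daily footprints used to normalize f2
DEFAULT_GHG_MAX = 3.96
DEFAULT_WATER_MAX = 4175.0

#: weighted-sum schemes (w_adequacy, w_environment, w_cost)
WEIGHTING_SCHEMES: dict[str, tuple[float, float, float]] = {
    "nutrient": (0.70, 0.15, 0.15),
    "sustainability": (0.15, 0.70, 0.15),
    "balanced": (0.33, 0.33, 0.33),
}


@dataclass(frozen=True)
class DietVector:
    """Food-group shares on the capped simplex plus total daily mass (kg).

    ``share_cap`` defaults to the 40% diversity cap; toy problems may relax it.
    """

    shares: tuple[float, ...]
    total_mass_kg: float
    share_cap: float = SHARE_CAP

    def __post_init__(self) -> None:
        x = np.asarray(self.shares, float)
        if x.shape != (len(FOOD_GROUPS),):
            raise ValueError(f"shares must have {len(FOOD_GROUPS)} components")
        if (x < -1e-12).any() or (x > self.share_cap + 1e-9).any():
            raise ValueError(f"shares must lie in [0, {self.share_cap}]")
        if abs(x.sum() - 1.0) > 1e-9:
            raise ValueError("shares must sum to 1")
        if self.total_mass_kg <= 0:
            raise ValueError("total_mass_kg must be positive")

    def consumption_kg(self) -> np.ndarray:
        return np.asarray(self.shares, float) * self.total_mass_kg


@dataclass(frozen=True)
class ObjectiveTriple:
    f1_adequacy: float
    f2_environment: float
    f3_cost: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f1_adequacy, self.f2_environment, self.f3_cost])


@dataclass(frozen=True)
class FeasibilityRecord:
    energy_ok: bool
    protein_ratio_ok: bool
    shares_ok: bool

    @property
    def feasible(self) -> bool:
        return self.energy_ok and self.protein_ratio_ok and self.shares_ok


@dataclass(frozen=True)
class OptimizationNorms:
    """Normalization constants for f2 and f3.

    ``cost_max`` has no printed reference value; by convention it is the
    maximum observed daily cost of the simulated population (see
    :func:`norms_from_population`).
    """

    ghg_max: float = DEFAULT_GHG_MAX
    water_max: float = DEFAULT_WATER_MAX
    cost_max: float = 30.0

    def __post_init__(self) -> None:
        if min(self.ghg_max, self.water_max, self.cost_max) <= 0:
            raise ValueError("normalization constants must be positive")


def norms_from_population(pop, ghg_max: float = DEFAULT_GHG_MAX,
                          water_max: float = DEFAULT_WATER_MAX) -> OptimizationNorms:
    """Norms with cost_max taken from the population's maximum daily cost."""
    return OptimizationNorms(ghg_max=ghg_max, water_max=water_max,
                             cost_max=float(pop.df["cost_usd"].max()))


@dataclass(frozen=True)
class ReferencePerson:
    """Whose requirements f1 is evaluated against.

    Defaults to female thresholds (the stricter iron case) and a 70 kg body
    mass for the protein RDA.
    """

    sex: str = "female"
    body_mass_kg: float = 70.0


def _per_kg_matrix(db: Sequence[FoodGroupProfile]) -> np.ndarray:
    """columns: energy, protein, iron, calcium, zinc, ghg, water, cost per kg."""
    dm = density_matrix(db)
    cols = ["energy_kcal_per_kg", "protein_g_per_kg", "iron_mg_per_kg",
            "calcium_mg_per_kg", "zinc_mg_per_kg", "ghg_kgco2e_per_kg",
            "water_l_per_kg", "price_usd_per_kg"]
    return dm[cols].to_numpy()


def _requirement_vector(requirements: RequirementSet, ref: ReferencePerson) -> np.ndarray:
    protein_g = requirements.threshold("protein_g_per_kg", ref.sex) * ref.body_mass_kg
    return np.array([
        requirements.threshold("iron_mg", ref.sex),
        requirements.threshold("calcium_mg", ref.sex),
        requirements.threshold("zinc_mg", ref.sex),
        protein_g,
    ])


def _evaluate_batch(consumption: np.ndarray, per_kg: np.ndarray,
                    req: np.ndarray, norms: OptimizationNorms) -> np.ndarray:
    """(n, 8) consumption -> (n, 3) objective values."""
    q = consumption @ per_kg  # energy, protein, iron, calcium, zinc, ghg, water, cost
    adequacy = (q[:, 2] / req[0] + q[:, 3] / req[1] + q[:, 4] / req[2]
                + q[:, 1] / req[3]) / 4.0
    env = 0.5 * (q[:, 5] / norms.ghg_max + q[:, 6] / norms.water_max)
    cost = q[:, 7] / norms.cost_max
    return np.column_stack([adequacy, env, cost])


def evaluate_objectives(diet: DietVector, db: Sequence[FoodGroupProfile],
                        requirements: RequirementSet | None = None,
                        norms: OptimizationNorms | None = None,
                        reference: ReferencePerson = ReferencePerson(),
                        ) -> ObjectiveTriple:
    """Objective triple (adequacy, environment, cost) of a single diet."""
    requirements = requirements or default_requirements()
    norms = norms or OptimizationNorms()
    req = _requirement_vector(requirements, reference)
    vals = _evaluate_batch(diet.consumption_kg()[None, :], _per_kg_matrix(db), req, norms)[0]
    return ObjectiveTriple(*map(float, vals))


def check_constraints(diet: DietVector, db: Sequence[FoodGroupProfile]) -> FeasibilityRecord:
    """Energy window, protein-to-energy ratio and share-cap checks."""
    cons = diet.consumption_kg()
    per_kg = _per_kg_matrix(db)
    energy = float(cons @ per_kg[:, 0])
    protein = float(cons @ per_kg[:, 1])
    ratio = protein * KCAL_PER_G_PROTEIN / energy if energy > 0 else np.inf
    shares = np.asarray(diet.shares)
    return FeasibilityRecord(
        energy_ok=ENERGY_BOUNDS[0] <= energy <= ENERGY_BOUNDS[1],
        protein_ratio_ok=PROTEIN_ENERGY_BOUNDS[0] <= ratio <= PROTEIN_ENERGY_BOUNDS[1],
        shares_ok=bool((shares >= -1e-12).all() and (shares <= SHARE_CAP + 1e-9).all()
                       and abs(shares.sum() - 1.0) <= 1e-9),
    )


def repair_shares(raw: np.ndarray, cap: float = SHARE_CAP) -> np.ndarray:
    """Project non-negative weights onto the capped simplex.

    Normalizes, then iteratively clips components above the cap and
    redistributes the excess over the unclipped ones.  With 8 groups and a
    0.4 cap the iteration always converges (the cap is never binding for all
    components simultaneously since 8 x 0.4 > 1).
    """
    x = np.maximum(np.asarray(raw, float), 0.0)
    rows = np.atleast_2d(x)
    out = np.empty_like(rows)
    for i, row in enumerate(rows):
        s = row.sum()
        row = row / s if s > 0 else np.full_like(row, 1.0 / row.size)
        locked = np.zeros(row.size, bool)
        for _ in range(row.size):
            over = (row > cap) & ~locked
            if not over.any():
                break
            locked |= over
            excess = (row[over] - cap).sum()
            row[over] = cap
            free = ~locked
            if not free.any():
                break
            if row[free].sum() > 0:
                row[free] += excess * row[free] / row[free].sum()
            else:
                row[free] += excess / free.sum()
        out[i] = np.minimum(row, cap)
    return out[0] if x.ndim == 1 else out


# ---------------------------------------------------------------------------
# generic NSGA-II engine
# ---------------------------------------------------------------------------

def _fast_nondominated_sort(F: np.ndarray) -> np.ndarray:
    """Rank (0 = best front) of each row for minimization of all columns."""
    n = len(F)
    # dominated[i, j]: i dominates j
    le = (F[:, None, :] <= F[None, :, :]).all(axis=2)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=2)
    dom = le & lt
    ranks = np.full(n, -1)
    remaining = np.ones(n, bool)
    rank = 0
    while remaining.any():
        dominated_count = (dom & remaining[:, None]).sum(axis=0)
        front = remaining & (dominated_count == 0)
        if not front.any():  # numerical safeguard
            front = remaining
        ranks[front] = rank
        remaining &= ~front
        rank += 1
    return ranks


def _crowding_distance(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        fj = F[order, j]
        span = fj[-1] - fj[0]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0:
            dist[order[1:-1]] += (fj[2:] - fj[:-2]) / span
    return dist


def _rank_with_feasibility(F: np.ndarray, violation: np.ndarray) -> np.ndarray:
    """Feasibility-first ranking: feasible fronts first, then infeasible by
    total constraint violation."""
    ranks = np.full(len(F), np.iinfo(np.int64).max, dtype=np.int64)
    feas = violation <= 0
    if feas.any():
        ranks[feas] = _fast_nondominated_sort(F[feas])
    max_feas_rank = ranks[feas].max() + 1 if feas.any() else 0
    if (~feas).any():
        order = np.argsort(violation[~feas], kind="stable")
        infeasible_ranks = np.empty(order.size, dtype=np.int64)
        infeasible_ranks[order] = np.arange(order.size)
        ranks[~feas] = max_feas_rank + infeasible_ranks
    return ranks


def _sbx_crossover(rng, parents_a, parents_b, prob, eta=15.0):
    u = rng.random(parents_a.shape)
    beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta + 1)),
                    (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
    do = rng.random((len(parents_a), 1)) < prob
    c1 = 0.5 * ((1 + beta) * parents_a + (1 - beta) * parents_b)
    c2 = 0.5 * ((1 - beta) * parents_a + (1 + beta) * parents_b)
    c1 = np.where(do, c1, parents_a)
    c2 = np.where(do, c2, parents_b)
    return np.clip(c1, 0, 1), np.clip(c2, 0, 1)


def _poly_mutation(rng, pop, prob, eta=20.0):
    u = rng.random(pop.shape)
    delta = np.where(u < 0.5, (2 * u) ** (1 / (eta + 1)) - 1,
                     1 - (2 * (1 - u)) ** (1 / (eta + 1)))
    mask = rng.random(pop.shape) < prob
    return np.clip(pop + np.where(mask, delta, 0.0), 0, 1)


def nsga2(
    evaluate: Callable[[np.ndarray], np.ndarray],
    n_var: int,
    pop_size: int = 200,
    generations: int = 100,
    crossover_prob: float = 0.9,
    mutation_prob: float = 0.1,
    seed: int = 42,
    violation: Callable[[np.ndarray], np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generic NSGA-II over genomes in [0, 1]^n_var, minimizing all objectives.

    ``evaluate`` maps an (n, n_var) genome batch to (n, m) objective values;
    ``violation`` (optional) maps it to total constraint violations (<= 0
    means feasible) used for feasibility-first domination.  Returns the
    genomes and objectives of the final first front (feasible when any
    feasible solution exists).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    X = rng.random((pop_size, n_var))
    F = evaluate(X)
    V = violation(X) if violation else np.zeros(len(X))
    for _ in range(generations):
        ranks = _rank_with_feasibility(F, V)
        crowd = np.zeros(pop_size)
        for r in np.unique(ranks):
            m = ranks == r
            crowd[m] = _crowding_distance(F[m])
        # binary tournament selection on (rank, -crowding)
        cand = rng.integers(0, pop_size, size=(2, pop_size))
        a, b = cand
        better = (ranks[a] < ranks[b]) | ((ranks[a] == ranks[b]) & (crowd[a] > crowd[b]))
        parents = np.where(better, a, b)
        pa = X[parents[0::2]]
        pb = X[parents[1::2]]
        c1, c2 = _sbx_crossover(rng, pa, pb, crossover_prob)
        offspring = np.vstack([c1, c2])[:pop_size]
        offspring = _poly_mutation(rng, offspring, mutation_prob)
        Fo = evaluate(offspring)
        Vo = violation(offspring) if violation else np.zeros(len(offspring))
        X = np.vstack([X, offspring])
        F = np.vstack([F, Fo])
        V = np.concatenate([V, Vo])
        ranks = _rank_with_feasibility(F, V)
        crowd = np.zeros(len(X))
        for r in np.unique(ranks):
            m = ranks == r
            crowd[m] = _crowding_distance(F[m])
        order = np.lexsort((-crowd, ranks))[:pop_size]
        X, F, V = X[order], F[order], V[order]
    ranks = _rank_with_feasibility(F, V)
    front = ranks == ranks.min()
    # drop duplicates for a clean front
    _, uniq = np.unique(np.round(F[front], 12), axis=0, return_index=True)
    idx = np.flatnonzero(front)[np.sort(uniq)]
    return X[idx], F[idx]


# ---------------------------------------------------------------------------
# diet-specific search
# ---------------------------------------------------------------------------

@dataclass
class ParetoSet:
    """Non-dominated feasible diets with their objective triples."""

    entries: list[tuple[DietVector, ObjectiveTriple]]
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def objectives_array(self) -> np.ndarray:
        return np.array([o.as_array() for _, o in self.entries])


#: gamma-quantile gene mapping concentration; small values spread the search
#: toward sparse (few-group-dominant) compositions like Dirichlet(0.3) draws
GENE_GAMMA_SHAPE = 0.3


def _decode(genomes: np.ndarray, mass_bounds: tuple[float, float],
            energy_per_kg: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Genomes in [0,1]^9 -> (shares on the capped simplex, daily mass).

    Share genes pass through an inverse-gamma quantile map before simplex
    repair, so the uniform genome space covers sparse compositions.  When the
    database's energy densities are supplied, the mass gene is additionally
    projected into the interval where the energy constraint can hold (the
    energy window is monotone in mass at fixed shares, so this is an exact
    repair of that constraint whenever it is satisfiable).
    """
    g = np.clip(genomes[:, :-1], 1e-12, 1.0 - 1e-12)
    shares = repair_shares(sps_gamma.ppf(g, GENE_GAMMA_SHAPE))
    lo, hi = mass_bounds
    mass = lo + genomes[:, -1] * (hi - lo)
    if energy_per_kg is not None:
        e1 = np.maximum(shares @ energy_per_kg, 1e-9)
        m_lo = np.maximum(lo, ENERGY_BOUNDS[0] / e1)
        m_hi = np.minimum(hi, ENERGY_BOUNDS[1] / e1)
        ok = m_lo <= m_hi
        mass = np.where(ok, np.clip(mass, m_lo, np.maximum(m_hi, m_lo)), mass)
    return shares, mass


def nsga2_search(
    db: Sequence[FoodGroupProfile],
    requirements: RequirementSet | None = None,
    norms: OptimizationNorms | None = None,
    reference: ReferencePerson = ReferencePerson(),
    pop_size: int = 200,
    generations: int = 100,
    crossover_prob: float = 0.9,
    mutation_prob: float = 0.1,
    seed: int = 42,
    mass_bounds: tuple[float, float] = (0.5, 6.0),
) -> ParetoSet:
    """NSGA-II search for the Pareto set of feasible diets.

    Maximizes adequacy while minimizing environment and cost (internally all
    minimized via -f1).  Share-cap violations are repaired; the energy and
    protein-ratio constraints enter through feasibility-first domination.
    Raises if the final front contains no feasible diet.
    """
    requirements = requirements or default_requirements()
    norms = norms or OptimizationNorms()
    per_kg = _per_kg_matrix(db)
    req = _requirement_vector(requirements, reference)

    energy_per_kg = per_kg[:, 0]

    def evaluate(genomes: np.ndarray) -> np.ndarray:
        shares, mass = _decode(genomes, mass_bounds, energy_per_kg)
        cons = shares * mass[:, None]
        obj = _evaluate_batch(cons, per_kg, req, norms)
        return np.column_stack([-obj[:, 0], obj[:, 1], obj[:, 2]])

    def violation(genomes: np.ndarray) -> np.ndarray:
        shares, mass = _decode(genomes, mass_bounds, energy_per_kg)
        cons = shares * mass[:, None]
        energy = cons @ per_kg[:, 0]
        protein = cons @ per_kg[:, 1]
        ratio = np.where(energy > 0, protein * KCAL_PER_G_PROTEIN / energy, np.inf)
        v = (np.maximum(ENERGY_BOUNDS[0] - energy, 0) / ENERGY_BOUNDS[0]
             + np.maximum(energy - ENERGY_BOUNDS[1], 0) / ENERGY_BOUNDS[1]
             + np.maximum(PROTEIN_ENERGY_BOUNDS[0] - ratio, 0)
             + np.maximum(ratio - PROTEIN_ENERGY_BOUNDS[1], 0))
        return v

    genomes, F = nsga2(evaluate, n_var=len(FOOD_GROUPS) + 1, pop_size=pop_size,
                       generations=generations, crossover_prob=crossover_prob,
                       mutation_prob=mutation_prob, seed=seed, violation=violation)
    shares, mass = _decode(genomes, mass_bounds, energy_per_kg)
    entries = []
    for s, m, f in zip(shares, mass, F):
        diet = DietVector(shares=tuple(np.round(s, 12)), total_mass_kg=float(m))
        if not check_constraints(diet, db).feasible:
            continue
        entries.append((diet, ObjectiveTriple(float(-f[0]), float(f[1]), float(f[2]))))
    if not entries:
        raise RuntimeError(
            "NSGA-II found no feasible diet: the feasible region may be empty "
            "under this database and constraint set")
    return ParetoSet(entries=entries, params={
        "pop_size": pop_size, "generations": generations,
        "crossover_prob": crossover_prob, "mutation_prob": mutation_prob,
        "seed": seed, "mass_bounds": mass_bounds,
    })


def weighted_score(objectives: ObjectiveTriple | np.ndarray,
                   weights: tuple[float, float, float]) -> float | np.ndarray:
    """w1*f1 - w2*f2 - w3*f3 (adequacy rewarded, impact and cost penalized)."""
    arr = objectives.as_array() if isinstance(objectives, ObjectiveTriple) else np.asarray(objectives)
    w = np.asarray(weights, float)
    scores = arr @ (w * np.array([1.0, -1.0, -1.0]))
    return float(scores) if arr.ndim == 1 else scores


def weighted_scenario_select(pareto: ParetoSet,
                             weights: tuple[float, float, float],
                             ) -> tuple[DietVector, ObjectiveTriple]:
    """Best Pareto member under a weighted-sum score.

    Ties are broken by lower environmental impact, then lower cost.
    """
    w = np.asarray(weights, float)
    if (w < 0).any() or not 0.9 <= w.sum() <= 1.1:
        raise ValueError("weights must be non-negative and sum to ~1")
    if not pareto.entries:
        raise ValueError("empty Pareto set")
    F = pareto.objectives_array()
    scores = weighted_score(F, tuple(w))
    key = np.lexsort((F[:, 2], F[:, 1], -scores))
    return pareto.entries[int(key[0])]


@dataclass
class GridOracleResult:
    diet: DietVector | None
    objectives: ObjectiveTriple | None
    score: float
    n_feasible: int

    @property
    def feasible_region_empty(self) -> bool:
        return self.n_feasible == 0


def _simplex_grid(n_groups: int, steps: int, max_units: int) -> np.ndarray:
    """All compositions of ``steps`` units over ``n_groups`` parts, each part
    at most ``max_units``.  Vectorized stars-and-bars enumeration."""
    if n_groups == 1:
        if steps > max_units:
            return np.empty((0, 1), dtype=np.int16)
        return np.array([[steps]], dtype=np.int16)
    grids = np.meshgrid(*[np.arange(max_units + 1, dtype=np.int16)] * (n_groups - 1),
                        indexing="ij")
    parts = np.stack([g.ravel() for g in grids], axis=1)
    total = parts.sum(axis=1)
    keep = (total <= steps) & (total >= steps - max_units)
    parts = parts[keep]
    last = (steps - parts.sum(axis=1)).astype(np.int16)
    return np.column_stack([parts, last])


def grid_oracle(
    db: Sequence[FoodGroupProfile],
    requirements: RequirementSet | None = None,
    norms: OptimizationNorms | None = None,
    weights: tuple[float, float, float] = WEIGHTING_SCHEMES["balanced"],
    grid_step: float = 0.05,
    mass_grid: np.ndarray | None = None,
    reference: ReferencePerson = ReferencePerson(),
    n_groups: int | None = None,
    share_cap: float = SHARE_CAP,
) -> GridOracleResult:
    """Exhaustive weighted-objective optimum over a capped-simplex grid.

    Enumerates every share vector on the ``grid_step`` lattice (components up
    to the 40% cap) crossed with a mass grid, keeps feasible combinations and
    returns the best weighted score.  A verification oracle for the NSGA-II
    search, exact up to grid resolution.
    """
    requirements = requirements or default_requirements()
    norms = norms or OptimizationNorms()
    n_groups = n_groups or len(FOOD_GROUPS)
    steps = round(1.0 / grid_step)
    if abs(steps * grid_step - 1.0) > 1e-9:
        raise ValueError("grid_step must divide 1")
    max_units = min(int(np.floor(share_cap / grid_step + 1e-9)), steps)
    shares = _simplex_grid(n_groups, steps, max_units).astype(float) * grid_step
    if mass_grid is None:
        mass_grid = np.arange(0.5, 6.0 + 1e-9, 0.25)
    per_kg = _per_kg_matrix(db)[:n_groups]
    req = _requirement_vector(requirements, reference)
    unit = shares @ per_kg  # per-kg quantities of each grid composition
    unit_energy = unit[:, 0]
    unit_protein = unit[:, 1]
    ratio = np.where(unit_energy > 0,
                     unit_protein * KCAL_PER_G_PROTEIN / unit_energy, np.inf)
    ratio_ok = (ratio >= PROTEIN_ENERGY_BOUNDS[0]) & (ratio <= PROTEIN_ENERGY_BOUNDS[1])
    best_score = -np.inf
    best: tuple | None = None
    n_feasible = 0
    for mass in np.asarray(mass_grid, float):
        energy = unit_energy * mass
        ok = ratio_ok & (energy >= ENERGY_BOUNDS[0]) & (energy <= ENERGY_BOUNDS[1])
        if not ok.any():
            continue
        n_feasible += int(ok.sum())
        obj = _evaluate_batch(shares[ok] * mass, per_kg, req, norms)
        scores = weighted_score(obj, weights)
        i = int(np.argmax(scores))
        if scores[i] > best_score:
            best_score = float(scores[i])
            best = (shares[ok][i], mass, obj[i])
    if best is None:
        log.warning("grid oracle: feasible region empty at this resolution")
        return GridOracleResult(diet=None, objectives=None,
                                score=float("-inf"), n_feasible=0)
    s, mass, obj = best
    pad = np.zeros(len(FOOD_GROUPS))
    pad[:n_groups] = s
    return GridOracleResult(
        diet=DietVector(shares=tuple(pad), total_mass_kg=float(mass), share_cap=share_cap),
        objectives=ObjectiveTriple(*map(float, obj)),
        score=best_score, n_feasible=n_feasible,
    )
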