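"""End-to-end orchestration of the five-stage analysis.

simulate -> classify -> reduce -> optimize -> scenarios/validate, with a
summary JSON aggregating the headline numbers of every stage.  One global
seed fans out to per-stage child seeds through a stable stage-name hash, so
any stage can be re-run independently and reproducibly.
"""
from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import optimize as _optimize
from . import reduce as _reduce
from . import scenarios as _scenarios
from . import stats as _stats
from .food_db import default_food_table, default_requirements, load_food_table
from .simulate import PopulationTable, config_hash, simulate_population

log = logging.getLogger(__name__)

BOOTSTRAP_METRICS = ("energy_kcal", "protein_g", "iron_mg", "calcium_mg",
                     "ghg_kgco2e", "water_l")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (fully serializable)."""

    out_dir: str = "dietsim_run"
    db_path: str | None = None  # None -> shipped default database
    seed: int = 42
    n_per_pattern: int = 375
    days_per_person: int = 1
    bootstrap_B: int = 1000
    classifier_features: list[str] = field(
        default_factory=lambda: list(_classify.DEFAULT_CLASSIFIER_FEATURES))
    reduce_features: list[str] = field(
        default_factory=lambda: list(_reduce.DEFAULT_REDUCE_FEATURES))
    tsne_iterations: int = 1000
    tsne_perplexity: float = 30.0
    reduce_subsample: int | None = None  # None -> full population
    optimizer_pop_size: int = 200
    optimizer_generations: int = 100
    optimizer_crossover: float = 0.9
    optimizer_mutation: float = 0.1
    scenario_lambda: float = 0.5
    scenario_grid_step: float = 0.05
    requirement_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        # out_dir does not affect results, so it is excluded from identity
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return config_hash(payload)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed: global seed combined with a
    CRC32 hash of the stage name, folded below 2**31."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Every artifact records the seed and config hash; ``summary.json``
    aggregates the headline numbers.  A stage failure aborts with the stage
    name while retaining earlier artifacts.
    """
    out = Path(config.out_dir)
    if config.db_path is not None and not Path(config.db_path).exists():
        raise FileNotFoundError(f"database path does not exist: {config.db_path}")
    out.mkdir(parents=True, exist_ok=True)
    db = load_food_table(config.db_path) if config.db_path else default_food_table()
    req = default_requirements().with_overrides(config.requirement_overrides)
    summary: dict = {"seed": config.seed, "config_hash": config.hash,
                     "package": "dietsim"}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        pop = simulate_population(db, n_per_pattern=config.n_per_pattern,
                                  days_per_person=config.days_per_person,
                                  seed=stage_seed(config.seed, stage))
        pop.meta["config_hash"] = config.hash
        pop.write(out / "population.csv")
        pattern_means = (pop.df.groupby("pattern")
                         [["energy_kcal", "protein_g", "iron_mg", "calcium_mg",
                           "zinc_mg", "vitd_ug", "b12_ug", "ghg_kgco2e",
                           "water_l", "cost_usd", "diversity_score"]]
                         .mean().round(4))
        pattern_means.to_csv(out / "pattern_means.csv")
        summary["simulate"] = {
            "n_rows": int(len(pop.df)),
            "pattern_means": {p: row.to_dict() for p, row in pattern_means.iterrows()},
        }
        log.info("stage %s done in %.1fs (%d rows)", stage,
                 time.perf_counter() - t0, len(pop.df))

        stage = "classify"
        t0 = time.perf_counter()
        report = _classify.train_pattern_classifier(
            pop, features=config.classifier_features,
            seed=stage_seed(config.seed, stage))
        _dump_json(report.to_dict(), out / "classifier_report.json")
        reg = _classify.fit_adequacy_regression(
            pop, requirements=req, seed=stage_seed(config.seed, stage))
        _dump_json(reg.to_dict(), out / "regression_report.json")
        summary["classify"] = {"accuracy": report.accuracy,
                               "macro_f1": report.macro_f1,
                               "weighted_f1": report.weighted_f1,
                               "regression_r2": reg.r2,
                               "regression_rmse": reg.rmse}
        log.info("stage %s done in %.1fs (accuracy %.3f)", stage,
                 time.perf_counter() - t0, report.accuracy)

        stage = "reduce"
        t0 = time.perf_counter()
        df_red = pop.df
        if config.reduce_subsample and config.reduce_subsample < len(df_red):
            rng = np.random.default_rng(stage_seed(config.seed, stage))
            df_red = df_red.iloc[np.sort(rng.choice(len(df_red), config.reduce_subsample,
                                                    replace=False))]
        pca = _reduce.run_pca(df_red, config.reduce_features)
        pca.loadings_frame().round(6).to_csv(out / "pca_loadings.csv")
        tsne_summary = None
        if config.tsne_iterations > 0:
            emb = _reduce.run_tsne(df_red, config.reduce_features,
                                   perplexity=config.tsne_perplexity,
                                   iterations=config.tsne_iterations,
                                   seed=stage_seed(config.seed, stage))
            coords = pd.DataFrame(emb.coords, columns=["tsne1", "tsne2"])
            coords["pattern"] = df_red["pattern"].to_numpy()
            coords.round(6).to_csv(out / "tsne_coords.csv", index=False)
            tsne_summary = {"final_kl": emb.final_kl, "params": emb.params}
        summary["reduce"] = {
            "explained_pct": [float(v) for v in pca.explained_pct[:3]],
            "cumulative_pct_pc2": float(pca.cumulative_pct[1]),
            "cumulative_pct_pc3": float(pca.cumulative_pct[2]),
            "tsne": tsne_summary,
        }
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "stats"
        t0 = time.perf_counter()
        boot_rows = {}
        for i, metric in enumerate(BOOTSTRAP_METRICS):
            bs = _stats.bootstrap_summary(pop.df[metric].to_numpy(),
                                          B=config.bootstrap_B,
                                          seed=stage_seed(config.seed, stage) + i)
            boot_rows[metric] = {"mean": bs.point_mean, "se": bs.se,
                                 "ci_low": bs.ci_low, "ci_high": bs.ci_high,
                                 "cv_pct": bs.cv_pct}
        anova = _stats.one_way_anova(
            [g["energy_kcal"].to_numpy() for _, g in pop.df.groupby("pattern")])
        trade = _stats.tradeoff_regression(pop.df["ghg_kgco2e"], pop.df["cost_usd"])
        prevalences = {
            n: _stats.adequacy_prevalence(pop.df[n], req.per_person(n, pop.df["sex"]))
            for n in ("iron_mg", "calcium_mg", "zinc_mg", "vitd_ug", "b12_ug")
        }
        summary["stats"] = {
            "bootstrap": boot_rows,
            "anova_energy": {"F": anova.statistic, "df": list(anova.df),
                             "p": anova.p_value},
            "tradeoff": vars(trade),
            "adequacy_prevalence_pct": prevalences,
        }
        _dump_json(summary["stats"], out / "stats.json")
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)

        stage = "optimize"
        t0 = time.perf_counter()
        norms = _optimize.norms_from_population(pop)
        pareto = _optimize.nsga2_search(
            db, requirements=req, norms=norms,
            pop_size=config.optimizer_pop_size,
            generations=config.optimizer_generations,
            crossover_prob=config.optimizer_crossover,
            mutation_prob=config.optimizer_mutation,
            seed=stage_seed(config.seed, stage))
        rows = []
        for diet, obj in pareto.entries:
            row = {f"share_{g.lower()}": s for g, s in zip(
                _optimize.FOOD_GROUPS, diet.shares)}
            row.update(total_mass_kg=diet.total_mass_kg,
                       f1_adequacy=obj.f1_adequacy,
                       f2_environment=obj.f2_environment, f3_cost=obj.f3_cost)
            rows.append(row)
        pd.DataFrame(rows).round(6).to_csv(out / "pareto.csv", index=False)
        selections = {}
        for scheme, w in _optimize.WEIGHTING_SCHEMES.items():
            diet, obj = _optimize.weighted_scenario_select(pareto, w)
            selections[scheme] = {
                "weights": list(w), "shares": list(diet.shares),
                "total_mass_kg": diet.total_mass_kg, "objectives": vars(obj),
                "score": _optimize.weighted_score(obj, w),
            }
        _dump_json(selections, out / "selections.json")
        summary["optimize"] = {"pareto_size": len(pareto),
                               "cost_max": norms.cost_max,
                               "selections": selections}
        log.info("stage %s done in %.1fs (front size %d)", stage,
                 time.perf_counter() - t0, len(pareto))

        stage = "scenarios"
        t0 = time.perf_counter()
        scen = _scenarios.run_scenarios(
            pop, db, lambdas={n: config.scenario_lambda
                              for n in _scenarios.SCENARIO_NAMES},
            requirements=req, grid_step=config.scenario_grid_step)
        scen.round(6).to_csv(out / "scenarios.csv", index=False)
        by_pattern = pop.df.groupby("pattern")["ghg_kgco2e"].mean()
        val_summary = {
            "ghg_kgco2e": float(pop.df["ghg_kgco2e"].mean()),
            "water_l": float(pop.df["water_l"].mean()),
            "iron_adequacy_pct": prevalences["iron_mg"],
            "calcium_adequacy_pct": prevalences["calcium_mg"],
            "mediterranean_minus_western_ghg": float(
                by_pattern["Mediterranean"] - by_pattern["Western"]),
            "diversity_score": float(pop.df["diversity_score"].mean()),
            "energy_kcal": float(pop.df["energy_kcal"].mean()),
            "protein_g": float(pop.df["protein_g"].mean()),
            "calcium_mg": float(pop.df["calcium_mg"].mean()),
            "iron_mg": float(pop.df["iron_mg"].mean()),
        }
        bench = _scenarios.validate_against_benchmarks(val_summary)
        ref = _scenarios.validate_against_reference_intakes(val_summary)
        pd.DataFrame([vars(b) for b in bench]).to_csv(out / "validation.csv", index=False)
        ref.to_csv(out / "validation_reference_intakes.csv", index=False)
        summary["scenarios"] = {r["name"]: {k: v for k, v in r.items() if k != "name"}
                                for r in scen.to_dict("records")}
        summary["validation"] = {
            "benchmarks": [vars(b) for b in bench],
            "reference_intakes": ref.to_dict("records"),
        }
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)
    except Exception:
        log.error("pipeline aborted in stage %r; partial outputs kept in %s",
                  stage, out)
        raise
    _dump_json(summary, out / "summary.json")
    return out


REPORT_ARTIFACTS = ("summary.json", "population.csv", "pattern_means.csv",
                    "classifier_report.json", "pareto.csv", "scenarios.csv",
                    "validation.csv")


def make_report(run_dir: str | Path) -> str:
    """Render a deterministic plain-text report from a completed run."""
    run_dir = Path(run_dir)
    missing = [a for a in REPORT_ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        raise FileNotFoundError(
            f"incomplete run directory {run_dir}; missing artifact(s): {missing}")
    summary = json.loads((run_dir / "summary.json").read_text())
    lines = ["# dietsim run report",
             f"seed: {summary['seed']}   config: {summary['config_hash']}", ""]
    lines.append("## Pattern means")
    means = pd.read_csv(run_dir / "pattern_means.csv", index_col=0)
    lines.append(means.to_string())
    lines.append("")
    c = summary["classify"]
    lines.append("## Classification")
    lines.append(f"accuracy {c['accuracy']:.3f}  macro F1 {c['macro_f1']:.3f}  "
                 f"weighted F1 {c['weighted_f1']:.3f}  "
                 f"adequacy regression R2 {c['regression_r2']:.3f}")
    lines.append("")
    lines.append("## Bootstrap uncertainty (mean, SE, CV%)")
    for metric, row in summary["stats"]["bootstrap"].items():
        lines.append(f"{metric:>12}: {row['mean']:.1f}  SE {row['se']:.3f}  "
                     f"CV {row['cv_pct']:.2f}%")
    lines.append("")
    lines.append("## Optimization selections")
    for scheme, sel in summary["optimize"]["selections"].items():
        o = sel["objectives"]
        lines.append(f"{scheme:>15}: f1 {o['f1_adequacy']:.3f}  "
                     f"f2 {o['f2_environment']:.3f}  f3 {o['f3_cost']:.3f}")
    lines.append("")
    lines.append("## Scenarios")
    scen = pd.read_csv(run_dir / "scenarios.csv")
    lines.append(scen.to_string(index=False))
    lines.append("")
    lines.append("## Benchmark validation")
    val = pd.read_csv(run_dir / "validation.csv")
    lines.append(val.to_string(index=False))
    return "\n".join(lines) + "\n"
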