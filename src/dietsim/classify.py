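"""Dietary-pattern classification and nutrient-adequacy regression.

A 500-tree random forest classifies pattern membership from demographic,
nutritional, environmental and economic features; performance is summarized
by confusion-matrix metrics (per-class precision/recall/F1, macro and
support-weighted aggregates) and normalized Gini feature importances with
across-tree standard errors.  An OLS regression predicts the per-person iron
adequacy ratio and is scored by R2, RMSE and MAPE on a held-out split.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LinearRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import train_test_split

from .food_db import RequirementSet, default_requirements
from .simulate import PopulationTable


def _frame(pop: "PopulationTable | pd.DataFrame") -> pd.DataFrame:
    return pop.df if isinstance(pop, PopulationTable) else pop

log = logging.getLogger(__name__)

#: default classifier feature set (12 features)
DEFAULT_CLASSIFIER_FEATURES: tuple[str, ...] = (
    "age_years", "sex", "bmi_kg_m2", "income_quintile", "season",
    "energy_kcal", "protein_g", "ghg_kgco2e", "water_l", "cost_usd",
    "diversity_score", "plant_animal_ratio",
)
#: default adequacy-regression predictors
DEFAULT_REGRESSION_FEATURES: tuple[str, ...] = (
    "age_years", "sex", "bmi_kg_m2", "income_quintile", "education_tertiary",
    "season", "energy_kcal", "protein_g", "calcium_mg", "zinc_mg",
    "ghg_kgco2e", "water_l", "cost_usd", "diversity_score", "plant_animal_ratio",
)

_CATEGORICAL_CODES = {"sex": {"male": 0.0, "female": 1.0}}


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class ClassifierReport:
    """Confusion counts plus derived metrics and feature importances."""

    labels: list[str]
    confusion_counts: np.ndarray
    per_class: dict[str, ClassMetrics]
    accuracy: float
    macro_f1: float
    weighted_f1: float
    importances: pd.DataFrame | None = None  # index=feature, cols mean/se
    split_seed: int | None = None

    def to_dict(self) -> dict:
        out = {
            "labels": self.labels,
            "confusion_counts": self.confusion_counts.tolist(),
            "per_class": {k: vars(v) for k, v in self.per_class.items()},
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "split_seed": self.split_seed,
        }
        if self.importances is not None:
            out["importances"] = {
                f: {"mean": float(r["mean"]), "se": float(r["se"])}
                for f, r in self.importances.iterrows()
            }
        return out


@dataclass
class RegressionReport:
    """Held-out diagnostics of the nutrient-adequacy OLS model."""

    intercept: float
    coefficients: dict[str, float]
    r2: float
    rmse: float
    mape_pct: float
    per_pattern_r2: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept, "coefficients": self.coefficients,
            "r2": self.r2, "rmse": self.rmse, "mape_pct": self.mape_pct,
            "per_pattern_r2": self.per_pattern_r2,
        }


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def summary_from_class_rates(precisions: Sequence[float], recalls: Sequence[float],
                             supports: Sequence[int]) -> dict:
    """Aggregate metrics from per-class precision/recall/support alone.

    Macro F1 is the unweighted mean of per-class F1; the support-weighted
    mean recall equals overall accuracy (each class's recall counts its true
    members once).
    """
    p = np.asarray(precisions, float)
    r = np.asarray(recalls, float)
    s = np.asarray(supports, float)
    f1 = np.array([f1_from_precision_recall(pi, ri) for pi, ri in zip(p, r)])
    return {
        "per_class_f1": f1.tolist(),
        "macro_f1": float(f1.mean()),
        "weighted_f1": float((f1 * s).sum() / s.sum()),
        "accuracy": float((r * s).sum() / s.sum()),
        "weighted_precision": float((p * s).sum() / s.sum()),
        "weighted_recall": float((r * s).sum() / s.sum()),
    }


def confusion_metrics(true_labels: Sequence, predicted_labels: Sequence,
                      labels: Sequence[str] | None = None) -> ClassifierReport:
    """Confusion matrix (rows = true, cols = predicted) and derived metrics.

    Per-class precision, recall and F1; accuracy; macro F1 (unweighted mean)
    and support-weighted F1.  Classes with an undefined precision or recall
    (zero denominator) score 0, with a logged note.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.size == 0:
        raise ValueError("confusion_metrics: empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    labels = list(labels)
    counts = _sk_confusion(y_true, y_pred, labels=labels)
    per_class: dict[str, ClassMetrics] = {}
    f1s, supports = [], []
    for i, lab in enumerate(labels):
        tp = counts[i, i]
        fp = counts[:, i].sum() - tp
        fn = counts[i, :].sum() - tp
        support = int(counts[i, :].sum())
        if tp + fp == 0 or tp + fn == 0:
            log.info("class %r has an empty prediction or truth set; "
                     "its precision/recall/F1 default to 0", lab)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = f1_from_precision_recall(precision, recall)
        per_class[lab] = ClassMetrics(float(precision), float(recall), float(f1), support)
        f1s.append(f1)
        supports.append(support)
    supports_arr = np.asarray(supports, float)
    total = supports_arr.sum()
    return ClassifierReport(
        labels=labels,
        confusion_counts=counts,
        per_class=per_class,
        accuracy=float(np.trace(counts) / total),
        macro_f1=float(np.mean(f1s)),
        weighted_f1=float((np.asarray(f1s) * supports_arr).sum() / total),
    )


def feature_matrix(df: pd.DataFrame, features: Sequence[str]) -> pd.DataFrame:
    """Numeric design matrix; categorical columns are code-mapped."""
    unknown = [f for f in features if f not in df.columns]
    if unknown:
        raise KeyError(f"unknown feature name(s): {unknown}")
    X = df[list(features)].copy()
    for col, codes in _CATEGORICAL_CODES.items():
        if col in X.columns:
            X[col] = X[col].map(codes)
    if "education_tertiary" in X.columns:
        X["education_tertiary"] = X["education_tertiary"].astype(float)
    return X.astype(float)


def train_pattern_classifier(
    pop: PopulationTable | pd.DataFrame,
    features: Sequence[str] | None = None,
    seed: int = 42,
    n_estimators: int = 500,
    max_depth: int = 20,
    min_samples_leaf: int = 5,
    max_features: int = 4,
    test_size: float = 0.3,
) -> ClassifierReport:
    """Train the random forest and evaluate on a stratified held-out split.

    Forest settings default to 500 trees, depth 20, 5 samples per leaf and 4
    candidate features per split; the split is 70/30 stratified by pattern
    and controlled by ``seed``.  Importance standard errors come from the
    dispersion of normalized per-tree importances across the forest.
    """
    features = tuple(features or DEFAULT_CLASSIFIER_FEATURES)
    df = _frame(pop)
    y = df["pattern"].to_numpy()
    if len(set(y)) < 2:
        raise ValueError("need at least two dietary patterns to classify")
    X = feature_matrix(df, features)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed)
    forest = RandomForestClassifier(
        n_estimators=n_estimators, max_depth=max_depth,
        min_samples_leaf=min_samples_leaf, max_features=max_features,
        random_state=seed, n_jobs=1)
    forest.fit(X_tr, y_tr)
    report = confusion_metrics(y_te, forest.predict(X_te), labels=sorted(set(y)))

    per_tree = np.array([t.feature_importances_ for t in forest.estimators_])
    sums = per_tree.sum(axis=1, keepdims=True)
    per_tree = np.divide(per_tree, sums, out=np.zeros_like(per_tree), where=sums > 0)
    mean_imp = forest.feature_importances_  # already normalized to sum 1
    se = per_tree.std(axis=0, ddof=1) / np.sqrt(len(forest.estimators_))
    report.importances = pd.DataFrame(
        {"mean": mean_imp, "se": se}, index=list(features))
    report.split_seed = seed
    return report


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy()])
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify columns involved in the collinearity via QR pivoting
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i - 1] for i in range(1, arr.shape[1])
               if diag[i] < 1e-8 * diag.max()]
        raise ValueError(f"rank-deficient design; collinear column(s): {bad or 'intercept'}")


def iron_adequacy_ratio(pop: "PopulationTable | pd.DataFrame",
                        requirements: RequirementSet | None = None) -> np.ndarray:
    """Per-person iron intake divided by the sex-specific requirement."""
    req = requirements or default_requirements()
    df = _frame(pop)
    thr = req.per_person("iron_mg", df["sex"])
    return df["iron_mg"].to_numpy() / thr


def fit_adequacy_regression(
    pop: PopulationTable | pd.DataFrame,
    response: np.ndarray | str = "iron_adequacy",
    predictors: Sequence[str] | None = None,
    requirements: RequirementSet | None = None,
    seed: int = 42,
    test_size: float = 0.3,
) -> RegressionReport:
    """OLS prediction of a nutrient adequacy ratio, scored out of sample.

    ``response`` is either the string ``"iron_adequacy"`` (iron intake over
    the sex-specific requirement) or an explicit per-row response vector.
    Metrics (R2, RMSE, MAPE) are computed on a 30% held-out split stratified
    by pattern; per-pattern R2 is computed within the test-set subsets.
    Rows with a zero response are excluded from MAPE with a logged count.
    """
    predictors = tuple(predictors or DEFAULT_REGRESSION_FEATURES)
    df = _frame(pop)
    if isinstance(response, str):
        if response != "iron_adequacy":
            raise ValueError(f"unknown response {response!r}")
        y = iron_adequacy_ratio(df, requirements)
    else:
        y = np.asarray(response, float)
    if y.shape[0] != len(df):
        raise ValueError("response length does not match population")
    if np.var(y) == 0:
        raise ValueError("response is constant")
    X = feature_matrix(df, predictors)
    if len(X) < len(predictors) + 2:
        raise ValueError("need at least p + 2 rows")
    _check_rank(X)
    patterns = df["pattern"].to_numpy()
    X_tr, X_te, y_tr, y_te, _, pat_te = train_test_split(
        X, y, patterns, test_size=test_size, stratify=patterns, random_state=seed)
    model = LinearRegression()
    model.fit(X_tr, y_tr)
    y_hat = model.predict(X_te)
    r2 = r_squared(y_te, y_hat)
    rmse_val = rmse(y_te, y_hat)
    mape_val = mape_pct(y_te, y_hat)
    per_pattern = {}
    for pat in sorted(set(pat_te)):
        m = pat_te == pat
        per_pattern[pat] = r_squared(y_te[m], y_hat[m])
    return RegressionReport(
        intercept=float(model.intercept_),
        coefficients={f: float(c) for f, c in zip(predictors, model.coef_)},
        r2=r2, rmse=rmse_val, mape_pct=mape_val, per_pattern_r2=per_pattern,
    )


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination: 1 - SS_res / SS_tot."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValueError("R2 undefined for a constant response")
    return float(1.0 - ((y - y_hat) ** 2).sum() / ss_tot)


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def mape_pct(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean absolute percentage error; zero-valued targets are excluded."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    nz = y != 0
    dropped = int((~nz).sum())
    if dropped:
        log.info("MAPE: excluded %d zero-valued response row(s)", dropped)
    if not nz.any():
        raise ValueError("MAPE undefined: all response values are zero")
    return float(np.mean(np.abs((y[nz] - y_hat[nz]) / y[nz])) * 100.0)
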