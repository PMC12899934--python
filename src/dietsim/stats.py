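"""Statistical inference toolkit.

EAR cut-point adequacy prevalence, chi-square independence tests, percentile
bootstrap with Bessel-corrected standard errors, bivariate trade-off
regression with elasticity, one-way ANOVA, and Bonferroni-adjusted pairwise
post hoc testing (Tukey HSD behind a flag).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StatTestResult:
    statistic: float
    df: float | tuple
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class BootstrapSummary:
    """Percentile-bootstrap summary of a statistic (default: the mean)."""

    point_mean: float
    se: float
    ci_low: float
    ci_high: float
    cv_pct: float
    B: int
    seed: int


@dataclass(frozen=True)
class TradeoffResult:
    """OLS trade-off fit y = alpha + beta*x with elasticity at sample means."""

    intercept: float
    slope: float
    elasticity: float
    r2: float


def adequacy_prevalence(intakes: Sequence[float],
                        threshold: float | Sequence[float]) -> float:
    """Percentage of individuals whose intake/threshold ratio is >= 1.

    ``threshold`` may be a scalar or a per-person vector (e.g. sex-specific
    requirements from :meth:`RequirementSet.per_person`).  This is the EAR
    cut-point estimator of population adequacy prevalence.
    """
    x = np.asarray(intakes, float)
    if x.size == 0:
        raise ValueError("adequacy_prevalence: empty input")
    thr = np.broadcast_to(np.asarray(threshold, float), x.shape)
    if (thr <= 0).any():
        raise ValueError("thresholds must be positive")
    return float(100.0 * np.mean(x / thr >= 1.0))


def prevalence_se(prevalence_pct: float, n: int) -> float:
    """Binomial standard error of a prevalence estimate, in percentage points."""
    p = prevalence_pct / 100.0
    return float(100.0 * np.sqrt(p * (1.0 - p) / n))


def chi_square_independence(table: np.ndarray) -> StatTestResult:
    """Pearson chi-square test of independence on an r x c count table.

    Expected counts from the product of marginals; no continuity correction.
    """
    obs = np.asarray(table, float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any() or total == 0:
        raise ValueError("all row and column marginals must be positive")
    expected = row @ col / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return StatTestResult(statistic=stat, df=df, p_value=p,
                          test_name="chi-square independence")


def bootstrap_summary(values: Sequence[float], B: int = 1000, seed: int = 42,
                      statistic: Callable[[np.ndarray], float] | None = None,
                      ) -> BootstrapSummary:
    """Non-parametric bootstrap of a statistic over ``B`` resamples.

    The standard error is the Bessel-corrected standard deviation of the
    bootstrap distribution.  The 95% interval uses the literal order
    statistics at ranks 0.025*B and 0.975*B of the sorted bootstrap
    estimates (no interpolation), matching the percentile-rule convention.
    """
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("bootstrap requires at least 2 values")
    if B <= 0:
        raise ValueError("B must be positive")
    if B < 100:
        log.warning("bootstrap with B=%d resamples is unstable; consider B>=1000", B)
    rng = np.random.default_rng(seed)
    stat = statistic or (lambda a: float(np.mean(a)))
    if statistic is None:
        # vectorized resampling for the default mean statistic
        idx = rng.integers(0, x.size, size=(B, x.size))
        boots = x[idx].mean(axis=1)
    else:
        boots = np.array([stat(x[rng.integers(0, x.size, size=x.size)]) for _ in range(B)])
    se = float(np.std(boots, ddof=1))
    order = np.sort(boots)
    lo_ix = max(int(0.025 * B) - 1, 0)
    hi_ix = min(int(0.975 * B) - 1, B - 1)
    point = float(stat(x))
    return BootstrapSummary(
        point_mean=point, se=se,
        ci_low=float(order[lo_ix]), ci_high=float(order[hi_ix]),
        cv_pct=float(se / abs(point) * 100.0) if point != 0 else float("inf"),
        B=B, seed=seed,
    )


def tradeoff_regression(x: Sequence[float], y: Sequence[float]) -> TradeoffResult:
    """OLS fit of y on x with the cost-emissions elasticity beta*mean(x)/mean(y)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("tradeoff regression requires >= 3 paired values")
    if np.var(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sps.linregress(x, y)
    ybar = y.mean()
    elasticity = float(res.slope * x.mean() / ybar) if ybar != 0 else float("inf")
    return TradeoffResult(intercept=float(res.intercept), slope=float(res.slope),
                          elasticity=elasticity, r2=float(res.rvalue ** 2))


def one_way_anova(groups: Sequence[Sequence[float]]) -> StatTestResult:
    """One-way ANOVA: F = between-group over within-group mean square."""
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("ANOVA requires >= 2 groups with >= 2 values each")
    N = sum(g.size for g in gs)
    K = len(gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    if ss_within == 0:
        raise ValueError("zero within-group variance; F undefined")
    ms_between = ss_between / (K - 1)
    ms_within = ss_within / (N - K)
    F = float(ms_between / ms_within)
    p = float(sps.f.sf(F, K - 1, N - K))
    return StatTestResult(statistic=F, df=(K - 1, N - K), p_value=p,
                          test_name="one-way ANOVA")


def bonferroni_alpha(alpha: float, k_groups: int) -> tuple[float, int]:
    """Family-wise-adjusted significance level for all pairwise comparisons.

    Returns ``(alpha / m, m)`` with ``m = k(k-1)/2`` pairwise comparisons.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if k_groups < 2:
        raise ValueError("need at least 2 groups")
    m = k_groups * (k_groups - 1) // 2
    return alpha / m, m


def pairwise_posthoc(groups: Sequence[Sequence[float]],
                     labels: Sequence[str] | None = None,
                     alpha: float = 0.05,
                     method: str = "bonferroni") -> list[dict]:
    """Pairwise post hoc comparisons after ANOVA.

    Default: Welch t-tests at the Bonferroni-adjusted level.  ``method="tukey"``
    switches to Tukey's HSD.  Returns one record per pair with the statistic,
    p-value, adjusted level and significance flag.
    """
    gs = [np.asarray(g, float) for g in groups]
    labels = list(labels) if labels is not None else [f"group{i}" for i in range(len(gs))]
    adj, m = bonferroni_alpha(alpha, len(gs))
    out = []
    if method == "tukey":
        res = sps.tukey_hsd(*gs)
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                p = float(res.pvalue[i, j])
                out.append({"pair": (labels[i], labels[j]),
                            "statistic": float(res.statistic[i, j]),
                            "p_value": p, "alpha": alpha,
                            "significant": p < alpha, "method": "tukey_hsd"})
        return out
    if method != "bonferroni":
        raise ValueError(f"unknown post hoc method {method!r}")
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            t = sps.ttest_ind(gs[i], gs[j], equal_var=False)
            out.append({"pair": (labels[i], labels[j]),
                        "statistic": float(t.statistic),
                        "p_value": float(t.pvalue), "alpha": adj,
                        "significant": bool(t.pvalue < adj),
                        "method": f"welch_bonferroni(m={m})"})
    return out


def draw_truncated_normal(rng: np.random.Generator, loc: float, scale: float,
                          size: int, low: float = 0.0,
                          high: float = np.inf) -> np.ndarray:
    """Truncated-normal draws (default: truncated below at zero).

    Convenience for resampling experiments where intakes are generated at a
    stated mean/SD but cannot be negative.
    """
    a, b = (low - loc) / scale, (high - loc) / scale
    return sps.truncnorm(a, b, loc=loc, scale=scale).rvs(size=size, random_state=rng)
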