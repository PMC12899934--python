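"""Latent-structure analysis: PCA, t-SNE embedding, convex-hull summaries.

PCA operates on the z-scored feature matrix via SVD; component signs are
fixed by forcing the largest-magnitude loading of each component positive so
results are comparable across runs.  t-SNE delegates to scikit-learn with the
embedding hyperparameters exposed (perplexity 30, learning rate 200, 1000
iterations by default) and reports the final Kullback-Leibler divergence.
Cost is excluded from the default feature list so the latent structure
reflects nutritional and environmental composition rather than pricing.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError
from sklearn.manifold import TSNE

from .classify import feature_matrix
from .simulate import PopulationTable

#: default reduction feature list (cost deliberately excluded)
DEFAULT_REDUCE_FEATURES: tuple[str, ...] = (
    "age_years", "sex", "bmi_kg_m2", "income_quintile", "season",
    "energy_kcal", "protein_g", "iron_mg", "calcium_mg", "zinc_mg",
    "diversity_score", "plant_animal_ratio", "ghg_kgco2e", "water_l",
)


@dataclass
class PCAResult:
    """SVD-based PCA of the standardized feature matrix.

    ``components`` holds loadings column-wise (p x p, orthonormal);
    ``scores`` are the sample coordinates; percentages are of total variance.
    """

    features: list[str]
    components: np.ndarray
    singular_values: np.ndarray
    scores: np.ndarray
    explained_pct: np.ndarray
    cumulative_pct: np.ndarray

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.components.shape[1])]
        return pd.DataFrame(self.components, index=self.features, columns=cols)


@dataclass
class EmbeddingResult:
    coords: np.ndarray
    final_kl: float
    params: dict

    def __post_init__(self) -> None:
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding coordinates must be finite")
        if self.final_kl < 0:
            raise ValueError("KL divergence cannot be negative")


def _standardize(X: np.ndarray, feature_names: Sequence[str]) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = [feature_names[i] for i in np.flatnonzero(sd == 0)]
    if constant:
        raise ValueError(f"constant feature(s) cannot be standardized: {constant}")
    return (X - mu) / sd


def run_pca(pop: PopulationTable | pd.DataFrame,
            features: Sequence[str] | None = None) -> PCAResult:
    """PCA with deterministic sign convention and cumulative variance.

    Requires n > p.  Variance percentages always refer to all p components,
    so ``cumulative_pct[-1]`` is 100.
    """
    df = pop.df if isinstance(pop, PopulationTable) else pop
    features = list(features or DEFAULT_REDUCE_FEATURES)
    X = feature_matrix(df, features).to_numpy()
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than features ({p})")
    Z = _standardize(X, features)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    V = Vt.T
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    V = V * flip
    U = U * flip
    var = S**2
    explained = var / var.sum() * 100.0
    return PCAResult(
        features=features,
        components=V,
        singular_values=S,
        scores=U * S,
        explained_pct=explained,
        cumulative_pct=np.cumsum(explained),
    )


def run_tsne(pop: PopulationTable | pd.DataFrame,
             features: Sequence[str] | None = None,
             perplexity: float = 30.0,
             learning_rate: float = 200.0,
             iterations: int = 1000,
             seed: int = 42) -> EmbeddingResult:
    """2-D t-SNE embedding; deterministic given ``seed``."""
    df = pop.df if isinstance(pop, PopulationTable) else pop
    features = list(features or DEFAULT_REDUCE_FEATURES)
    X = feature_matrix(df, features).to_numpy()
    if len(X) <= 3 * perplexity:
        raise ValueError(
            f"n={len(X)} too small for perplexity {perplexity} (need n > 3x)")
    Z = _standardize(X, features)
    tsne = TSNE(n_components=2, perplexity=perplexity, learning_rate=learning_rate,
                max_iter=iterations, random_state=seed, init="pca")
    coords = tsne.fit_transform(Z)
    return EmbeddingResult(
        coords=np.asarray(coords, float),
        final_kl=float(tsne.kl_divergence_),
        params={"perplexity": perplexity, "learning_rate": learning_rate,
                "iterations": iterations, "seed": seed},
    )


def _hull(points: np.ndarray) -> ConvexHull | None:
    try:
        return ConvexHull(points)
    except QhullError:
        return None  # degenerate (collinear / too few distinct points)


def convex_hull_summary(coords: np.ndarray, labels: Sequence,
                        n_samples: int = 20000, seed: int = 0) -> dict:
    """Per-label hull areas and pairwise overlap fractions.

    ``overlap[(a, b)]`` is the fraction of label a's hull area lying inside
    label b's hull, estimated by Monte-Carlo point-in-hull sampling with a
    fixed seed.  Degenerate (collinear) label sets get area 0 and overlap 0.
    """
    coords = np.asarray(coords, float)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    rng = np.random.default_rng(seed)
    hulls: dict = {}
    areas: dict = {}
    for lab in uniq:
        pts = coords[labels == lab]
        if len(pts) < 3:
            raise ValueError(f"label {lab!r} has fewer than 3 points")
        h = _hull(pts)
        hulls[lab] = (pts, h)
        areas[lab] = float(h.volume) if h is not None else 0.0
    overlap: dict = {}
    for a in uniq:
        pts_a, h_a = hulls[a]
        for b in uniq:
            if a == b:
                continue
            _, h_b = hulls[b]
            if h_a is None or h_b is None:
                overlap[(a, b)] = 0.0
                continue
            lo = pts_a.min(axis=0)
            hi = pts_a.max(axis=0)
            samples = rng.uniform(lo, hi, size=(n_samples, 2))
            tri_a = Delaunay(pts_a[h_a.vertices])
            tri_b = Delaunay(hulls[b][0][h_b.vertices])
            in_a = tri_a.find_simplex(samples) >= 0
            if not in_a.any():
                overlap[(a, b)] = 0.0
                continue
            in_b = tri_b.find_simplex(samples[in_a]) >= 0
            overlap[(a, b)] = float(in_b.mean())
    return {"areas": areas, "overlap": overlap}
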