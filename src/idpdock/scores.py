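"""Docking-score statistics: min–max normalization, bootstrap uncertainty,
relative-affinity ranking, and score–structure correlation.

Raw scores from different engines live on incomparable scales, so each
docking method's scores are min–max normalized to [0, 1] with *one* scale
fitted over the pooled scores of all ligands compared with that method:

    x_scaled = (x − x_min) / (x_max − x_min)

where x_max is the most favorable and x_min the least favorable raw score
under the declared polarity; the best pooled score maps to exactly 1 and
the worst to exactly 0.  Relative affinities divide each ligand's mean
normalized score by the best ligand's mean, so the tightest binder is 1.0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .clustering import ClusterModel, ClusterSummary, cluster_weighted_average
from .interactions import ComparisonStats

__all__ = [
    "NormalizationScale",
    "fit_normalization",
    "normalize",
    "bootstrap_mean_ci",
    "affinity_table",
    "ranking_null_probability",
    "score_structure_correlation",
]


@dataclass(frozen=True)
class NormalizationScale:
    """Joint min–max scale: x_min = worst, x_max = best raw score."""

    x_min: float
    x_max: float
    method_tag: str = ""

    def __post_init__(self) -> None:
        if self.x_min == self.x_max:
            raise ValueError("degenerate scale: x_min == x_max")


def fit_normalization(all_scores: Sequence[float] | np.ndarray,
                      polarity: str, method_tag: str = "") -> NormalizationScale:
    """Fit one scale over the pooled raw scores of all ligands of a method.

    Under ``lower_is_better`` the minimum raw score is the best (x_max);
    under ``higher_is_better`` the maximum is.
    """
    scores = np.asarray(all_scores, dtype=float)
    if scores.size < 2 or np.unique(scores).size < 2:
        raise ValueError("need at least two distinct scores to fit a scale")
    lo, hi = float(scores.min()), float(scores.max())
    if polarity == "lower_is_better":
        return NormalizationScale(x_min=hi, x_max=lo, method_tag=method_tag)
    if polarity == "higher_is_better":
        return NormalizationScale(x_min=lo, x_max=hi, method_tag=method_tag)
    raise ValueError(f"unknown polarity {polarity!r}")


def normalize(x: float | np.ndarray, scale: NormalizationScale) -> float | np.ndarray:
    """Min–max normalized score(s) in [0, 1]; out-of-range values clip with
    a warning (they lie outside the scores the scale was fitted on)."""
    arr = np.asarray(x, dtype=float)
    scaled = (arr - scale.x_min) / (scale.x_max - scale.x_min)
    if np.any(scaled < -1e-12) or np.any(scaled > 1 + 1e-12):
        warnings.warn("scores outside the fitted scale were clipped to [0, 1]")
    scaled = np.clip(scaled, 0.0, 1.0)
    return float(scaled) if np.isscalar(x) or np.ndim(x) == 0 else scaled


def bootstrap_mean_ci(values: Sequence[float] | np.ndarray, n_boot: int = 10_000,
                      seed: int = 0) -> tuple[float, float, float, float]:
    """Percentile bootstrap of the mean.

    Returns ``(mean, ci_low, ci_high, error)`` where the CI is the
    2.5/97.5 bootstrap percentile interval and ``error`` is the mean of the
    upper and lower deviations, ((mean − ci_low) + (ci_high − mean)) / 2.
    Deterministic given the seed.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to bootstrap")
    rng = np.random.default_rng(seed)
    n = values.size
    idx = rng.integers(0, n, size=(n_boot, n))
    means = values[idx].mean(axis=1)
    mean = float(values.mean())
    ci_low, ci_high = np.percentile(means, [2.5, 97.5])
    error = ((mean - ci_low) + (ci_high - mean)) / 2.0
    return mean, float(ci_low), float(ci_high), float(error)


def affinity_table(normalized_scores: dict[str, np.ndarray],
                   cluster_model: Optional[ClusterModel] = None,
                   cluster_labels: Optional[dict[str, np.ndarray]] = None,
                   n_boot: int = 10_000, seed: int = 0,
                   cross_docking: bool = False):
    """Relative-affinity table over ligands sharing one normalization scale.

    ``normalized_scores`` maps ligand tag → per-frame normalized scores.
    With a cluster model (and per-ligand frame labels), each ligand's mean
    is the cluster-population-weighted mean of its per-cluster means;
    otherwise the plain mean.  Relative affinity divides by the best mean,
    so exactly one ligand gets 1.0; ligands rank by descending mean.
    Cross-docked score sets are annotated as such — scores obtained on a
    mismatched holo ensemble may not support reliable affinity comparison.
    """
    import pandas as pd

    rows = []
    for i, (tag, scores) in enumerate(normalized_scores.items()):
        scores = np.asarray(scores, dtype=float)
        if scores.size == 0:
            warnings.warn(f"ligand {tag!r} has no scores; excluded")
            continue
        if cluster_model is not None and cluster_labels is not None and tag in cluster_labels:
            labels = np.asarray(cluster_labels[tag])
            per_cluster = {}
            for c in np.unique(labels):
                per_cluster[int(c)] = float(scores[labels == c].mean())
            pops = {int(c): float(cluster_model.populations[c]) for c in per_cluster}
            total = sum(pops.values())
            mean = cluster_weighted_average(per_cluster,
                                            {c: p / total for c, p in pops.items()})
        else:
            mean = float(scores.mean())
        _, _, _, err = bootstrap_mean_ci(scores, n_boot=n_boot,
                                         seed=int(np.random.SeedSequence((seed, i)).generate_state(1)[0] % 2**31))
        rows.append({"ligand": tag, "mean_normalized_score": mean, "bootstrap_error": err})
    if not rows:
        raise ValueError("no ligands with scores")
    df = pd.DataFrame(rows)
    best = df["mean_normalized_score"].max()
    df["relative_affinity"] = df["mean_normalized_score"] / best
    df = df.sort_values("mean_normalized_score", ascending=False).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs["cross_docking"] = cross_docking
    if cross_docking:
        df.attrs["caveat"] = (
            "scores derive from a mismatched holo ensemble (cross docking); "
            "relative affinities may not be reliable"
        )
    return df


def ranking_null_probability(n_ligands: int) -> float:
    """Probability that a uniformly random strict ordering of ``n`` ligands
    matches the reference ordering: 1/n!."""
    if n_ligands < 1:
        raise ValueError("need at least one ligand")
    return 1.0 / math.factorial(n_ligands)


def score_structure_correlation(summaries: Sequence[ClusterSummary]) -> ComparisonStats:
    """Pearson r between per-cluster mean bend angle and mean normalized score."""
    from scipy import stats

    if len(summaries) < 3:
        raise ValueError("need at least 3 clusters")
    angles = np.array([s.mean_bend_angle for s in summaries])
    scores = np.array([s.mean_normalized_score for s in summaries])
    rmse = float(np.sqrt(np.mean((angles - scores) ** 2)))
    if np.std(angles) == 0 or np.std(scores) == 0:
        warnings.warn("zero variance: correlation undefined")
        return ComparisonStats(pearson_r=None, rmse=rmse)
    r, _ = stats.pearsonr(angles, scores)
    return ComparisonStats(pearson_r=float(r), rmse=rmse)
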