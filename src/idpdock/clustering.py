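"""Conformational clustering of IDP ensembles.

Frames are featurized as all pairwise Cα–Cα distances (rigid-motion
invariant), embedded in 2-D with t-SNE over a grid of perplexities, and
partitioned with k-means on the embedding.  The perplexity is chosen by
the highest silhouette score, computed in embedding space.  Clusters are
summarized by their population (fraction of the source ensemble), mean
bend angle — the interior angle at the middle of three anchor Cα atoms,
a compactness descriptor — and, when scores are supplied, their mean
normalized docking score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import ConformationEnsemble, ProteinConformation

__all__ = [
    "ClusterModel",
    "ClusterSummary",
    "featurize_ensemble",
    "cluster_ensemble",
    "bend_angle",
    "cluster_weighted_average",
    "summarize_clusters",
]

DEFAULT_K = 20
DEFAULT_PERPLEXITY_GRID = (1100, 1200, 1800)  # bracketing published usage; data-dependent


@dataclass
class ClusterModel:
    """Frame→cluster assignment with the embedding and selection diagnostics."""

    labels: np.ndarray
    k: int
    embedding: np.ndarray
    chosen_perplexity: float
    silhouette_by_perplexity: dict[float, float]
    populations: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.populations = np.asarray(self.populations, dtype=float)
        if abs(self.populations.sum() - 1.0) > 1e-9:
            raise ValueError("cluster populations must sum to 1")
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("labels must lie in 0..k-1")

    def save(self, labels_path: str | Path, meta_path: str | Path,
             frame_ids: Optional[Sequence[int]] = None) -> None:
        ids = frame_ids if frame_ids is not None else range(len(self.labels))
        rows = ["frame_id\tcluster"]
        rows += [f"{fid}\t{lab}" for fid, lab in zip(ids, self.labels)]
        Path(labels_path).write_text("\n".join(rows) + "\n")
        meta = {
            "k": self.k,
            "chosen_perplexity": self.chosen_perplexity,
            "silhouette_by_perplexity": {str(p): s for p, s in
                                         self.silhouette_by_perplexity.items()},
            "populations": self.populations.tolist(),
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2) + "\n")


@dataclass
class ClusterSummary:
    cluster_id: int
    mean_bend_angle: float
    mean_normalized_score: float
    n_frames: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_bend_angle <= 180.0:
            raise ValueError("bend angle must lie in [0, 180] degrees")


def featurize_ensemble(ensemble: ConformationEnsemble) -> np.ndarray:
    """Frame × feature matrix of all pairwise Cα–Cα distances (n(n-1)/2 cols)."""
    from scipy.spatial.distance import pdist

    n_res = ensemble.conformations[0].n_residues
    if n_res < 4:
        raise ValueError("need at least 4 residues to featurize")
    rows = [pdist(conf.ca_coords()) for conf in ensemble]
    return np.array(rows)


def cluster_ensemble(features: np.ndarray, k: int = DEFAULT_K,
                     perplexity_grid: Sequence[float] = DEFAULT_PERPLEXITY_GRID,
                     seed: int = 0) -> ClusterModel:
    """t-SNE + k-means clustering with silhouette-driven perplexity selection.

    For each perplexity in the grid the features are embedded in 2-D,
    partitioned into ``k`` clusters by k-means on the embedding, and scored
    by the silhouette in embedding space; the winning perplexity's labels
    and embedding are returned.  Deterministic given the seed.
    """
    from sklearn.cluster import KMeans
    from sklearn.manifold import TSNE
    from sklearn.metrics import silhouette_score

    features = np.asarray(features, dtype=float)
    n_frames = features.shape[0]
    grid = [p for p in perplexity_grid]
    if not grid:
        raise ValueError("perplexity grid is empty")
    if n_frames < k:
        raise ValueError(f"cannot form {k} clusters from {n_frames} frames")
    if np.allclose(features.var(axis=0), 0.0):
        raise ValueError("zero-variance features")
    usable = [p for p in grid if p < n_frames]
    if not usable:
        raise ValueError("all perplexities >= number of frames")

    best = None
    silhouettes: dict[float, float] = {}
    for perplexity in usable:
        emb = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                   init="pca").fit_transform(features)
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(emb)
        sil = float(silhouette_score(emb, labels)) if k > 1 else 0.0
        silhouettes[perplexity] = sil
        if best is None or sil > best[0]:
            best = (sil, perplexity, labels, emb)

    _, chosen, labels, emb = best
    populations = np.bincount(labels, minlength=k) / n_frames
    return ClusterModel(labels=labels, k=k, embedding=emb, chosen_perplexity=chosen,
                        silhouette_by_perplexity=silhouettes, populations=populations)


def bend_angle(conf: ProteinConformation, first_res: Optional[int] = None,
               middle_res: Optional[int] = None, last_res: Optional[int] = None) -> float:
    """Interior angle (degrees, in [0, 180]) at the middle anchor Cα.

    Default anchors are the first, middle and last residues of the chain;
    indices are 1-based.
    """
    n = conf.n_residues
    first = first_res if first_res is not None else 1
    last = last_res if last_res is not None else n
    middle = middle_res if middle_res is not None else (first + last) // 2
    pts = []
    for idx in (first, middle, last):
        res = conf.residues[idx - 1]
        if res.ca is None:
            raise ValueError(f"residue {idx} has no CA atom")
        pts.append(res.ca.coords)
    a, b, c = pts
    v1, v2 = a - b, c - b
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise ValueError("coincident anchor points")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def cluster_weighted_average(per_cluster_values: dict[int, float] | Sequence[float],
                             populations: dict[int, float] | Sequence[float]) -> float:
    """Population-weighted average of per-cluster values, Σ pop_c · value_c."""
    if isinstance(per_cluster_values, dict) or isinstance(populations, dict):
        vals = dict(enumerate(per_cluster_values)) if not isinstance(per_cluster_values, dict) \
            else per_cluster_values
        pops = dict(enumerate(populations)) if not isinstance(populations, dict) else populations
        if set(vals) != set(pops):
            raise ValueError("cluster ids of values and populations do not match")
        keys = sorted(vals)
        v = np.array([vals[c] for c in keys], dtype=float)
        p = np.array([pops[c] for c in keys], dtype=float)
    else:
        v = np.asarray(per_cluster_values, dtype=float)
        p = np.asarray(populations, dtype=float)
        if v.shape != p.shape:
            raise ValueError("cluster ids of values and populations do not match")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("populations must sum to 1")
    return float(np.sum(p * v))


def summarize_clusters(model: ClusterModel, ensemble: ConformationEnsemble,
                       normalized_scores: Optional[np.ndarray] = None,
                       anchors: Optional[tuple[int, int, int]] = None
                       ) -> list[ClusterSummary]:
    """Per-cluster mean bend angle (and mean normalized score when given)."""
    angles = np.array([
        bend_angle(conf, *(anchors or (None, None, None))) for conf in ensemble
    ])
    scores = np.asarray(normalized_scores, dtype=float) if normalized_scores is not None else None
    summaries = []
    for cluster in range(model.k):
        mask = model.labels == cluster
        if not mask.any():
            warnings.warn(f"cluster {cluster} has no frames; skipped in summary")
            continue
        mean_score = float(scores[mask].mean()) if scores is not None else float("nan")
        summaries.append(ClusterSummary(
            cluster_id=cluster,
            mean_bend_angle=float(angles[mask].mean()),
            mean_normalized_score=mean_score,
            n_frames=int(mask.sum()),
        ))
    return summaries
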