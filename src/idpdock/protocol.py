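"""Ensemble docking orchestration.

Apo, holo and cross docking are the same computation on different inputs:
the backend only ever sees protein coordinates.  Holo docking strips the
ligand from a bound ensemble first (``extract_bound_frames``); cross
docking pairs the protein frames of one ligand's bound ensemble with a
different ligand.  Frames are processed independently with per-frame seeds
derived from one master seed, so serial and parallel execution agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .backends import BackendError, DockRequest, whole_conformation_box
from .boxes import DEFAULT_EDGE_SCALE, build_residue_box, radius_of_gyration
from .core import (
    BoundEnsemble,
    ConformationEnsemble,
    DockedEnsemble,
    LigandModel,
    Pose,
)

__all__ = [
    "BoundFrameFilter",
    "extract_bound_frames",
    "sample_cluster_frames",
    "per_residue_ensemble_dock",
    "whole_conformation_ensemble_dock",
    "frame_seed",
]


@dataclass
class BoundFrameFilter:
    """A frame is *bound* when any heavy protein atom is within ``cutoff`` Å
    of any heavy ligand atom (default 6 Å, heavy atoms only)."""

    cutoff: float = 6.0
    heavy_only: bool = True

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")


def frame_seed(master_seed: int, frame_id: int) -> int:
    """Deterministic per-frame seed keyed by (master seed, frame id)."""
    ss = np.random.SeedSequence((int(master_seed), int(frame_id)))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def extract_bound_frames(bound: BoundEnsemble,
                         filt: BoundFrameFilter = BoundFrameFilter()
                         ) -> tuple[ConformationEnsemble, float]:
    """Filter a ligand-bound ensemble to its bound frames.

    Returns protein-only conformations of the frames passing the filter
    (the ligand is stripped, as for holo docking inputs) and the bound
    fraction kept/total.
    """
    if len(bound) == 0:
        raise ValueError("no frames in bound ensemble")
    if filt.heavy_only:
        lig_idx = bound.ligand.heavy_indices()
    else:
        lig_idx = np.arange(bound.ligand.n_atoms)
    kept_ids = []
    for conf, lig_xyz in zip(bound.protein, bound.ligand_coords):
        prot = conf.heavy_coords() if filt.heavy_only else conf.coords()
        lig = lig_xyz[lig_idx]
        d2 = np.sum((prot[:, None, :] - lig[None, :, :]) ** 2, axis=-1)
        if d2.min() <= filt.cutoff ** 2:
            kept_ids.append(conf.frame_id)
    fraction = len(kept_ids) / len(bound)
    if not kept_ids:
        raise ValueError("no bound frames under the filter")
    tag = bound.protein.source_tag
    if not tag.startswith("holo"):
        tag = f"holo:{bound.ligand.name}"
    return bound.protein.subset(kept_ids, source_tag=tag), fraction


def sample_cluster_frames(ensemble: ConformationEnsemble, labels: np.ndarray,
                          n_per_cluster: int = 1000, seed: int = 0
                          ) -> ConformationEnsemble:
    """Sample up to ``n_per_cluster`` frames without replacement per cluster.

    Clusters with fewer frames contribute all of them (with a warning);
    empty clusters are skipped with a warning.  Deterministic given the
    seed; frame order in the output follows the input ensemble.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != len(ensemble):
        raise ValueError("labels must cover all frames")
    frame_ids = np.array([c.frame_id for c in ensemble])
    chosen: list[int] = []
    for cluster in np.unique(labels):
        members = frame_ids[labels == cluster]
        if members.size == 0:
            warnings.warn(f"cluster {cluster} is empty; skipped")
            continue
        if members.size <= n_per_cluster:
            if members.size < n_per_cluster:
                warnings.warn(
                    f"cluster {cluster} has only {members.size} frames "
                    f"(< {n_per_cluster}); taking all of them"
                )
            chosen.extend(members.tolist())
        else:
            rng = np.random.default_rng(np.random.SeedSequence((int(seed), int(cluster))))
            pick = rng.choice(members, size=n_per_cluster, replace=False)
            chosen.extend(pick.tolist())
    return ensemble.subset(chosen)


def _select_best(candidates: list[Pose], polarity: str) -> Pose:
    """Best pose under the declared polarity; ties break by lowest origin
    residue index (whole-conformation candidates tie-break by list order)."""
    sign = 1.0 if polarity == "lower_is_better" else -1.0

    def key(item):
        idx, pose = item
        origin = pose.origin_residue if pose.origin_residue is not None else idx
        return (sign * pose.raw_score, origin)

    return min(enumerate(candidates), key=key)[1]


def per_residue_ensemble_dock(ensemble: ConformationEnsemble, ligand: LigandModel,
                              backend, edge_scale: float = DEFAULT_EDGE_SCALE,
                              seed: int = 0) -> DockedEnsemble:
    """Per-residue ensemble docking.

    For every frame, one docking call per residue restricted to a cubic box
    on that residue's centre of mass (edge = edge_scale × ligand Rg); the
    best-scoring candidate under the backend's polarity becomes the frame's
    selected pose.  Failed boxes are excluded; a frame whose boxes all fail
    is flagged and excluded from the selected poses with a warning.
    """
    if backend.spec.mode != "boxed":
        raise ValueError("per-residue docking requires a boxed backend")
    rg = radius_of_gyration(ligand)
    selected: list[Pose] = []
    candidates: dict[int, list[Pose]] = {}
    failed_frames: list[int] = []
    for conf in ensemble:
        frame_cands: list[Pose] = []
        for res_idx in range(1, conf.n_residues + 1):
            box = build_residue_box(conf, res_idx, rg, edge_scale)
            req = DockRequest(conf, ligand, box=box, n_poses=1,
                              seed=frame_seed(seed, conf.frame_id))
            try:
                results = backend.dock(req, frame_id=conf.frame_id)
            except BackendError:
                continue  # failed box: excluded, not scored worst
            if not results:
                continue
            pose, score = results[0]
            frame_cands.append(Pose(pose.ligand_coords, score, conf.frame_id,
                                    origin_residue=res_idx))
        candidates[conf.frame_id] = frame_cands
        if not frame_cands:
            failed_frames.append(conf.frame_id)
            warnings.warn(f"frame {conf.frame_id}: all residue boxes failed; excluded")
            continue
        selected.append(_select_best(frame_cands, backend.spec.polarity))
    return DockedEnsemble(selected, candidates, backend.spec.name,
                          backend.spec.polarity, ensemble=ensemble, ligand=ligand,
                          failed_frames=failed_frames)


def whole_conformation_ensemble_dock(ensemble: ConformationEnsemble,
                                     ligand: LigandModel, backend,
                                     n_poses: int = 10, seed: int = 0
                                     ) -> DockedEnsemble:
    """Whole-conformation ensemble docking: one unrestricted docking call per
    frame requesting ``n_poses`` candidates; the best under the backend's
    polarity is selected (one pose per frame)."""
    if backend.spec.mode != "whole_conformation":
        raise ValueError("backend must support whole_conformation mode")
    selected: list[Pose] = []
    candidates: dict[int, list[Pose]] = {}
    failed_frames: list[int] = []
    for conf in ensemble:
        req = DockRequest(conf, ligand, box=None, n_poses=n_poses,
                          seed=frame_seed(seed, conf.frame_id))
        try:
            results = backend.dock(req, frame_id=conf.frame_id)
        except BackendError:
            results = []
        frame_cands = [Pose(p.ligand_coords, s, conf.frame_id) for p, s in results]
        candidates[conf.frame_id] = frame_cands
        if not frame_cands:
            failed_frames.append(conf.frame_id)
            warnings.warn(f"frame {conf.frame_id}: docking failed; excluded")
            continue
        selected.append(_select_best(frame_cands, backend.spec.polarity))
    return DockedEnsemble(selected, candidates, backend.spec.name,
                          backend.spec.polarity, ensemble=ensemble, ligand=ligand,
                          failed_frames=failed_frames)
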