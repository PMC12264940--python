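"""Ligand pose-accuracy metrics.

Two RMSD flavours compare a docked pose with the bound poses observed in
a reference (MD-style) ensemble, always over heavy ligand atoms with the
input atom-index correspondence (no symmetry correction):

* frame-matched RMSD — docked pose vs the bound pose of the *identical*
  protein conformation; the protein coordinates already coincide, so no
  superposition is applied;
* best-matched RMSD — the minimum RMSD against every bound pose in the
  matching conformational cluster, after superposing each reference
  frame's Cα trace onto the docked conformation and carrying its ligand
  along.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import BoundEnsemble, LigandModel, Pose, ProteinConformation

__all__ = [
    "RmsdRecord",
    "superpose",
    "apply_transform",
    "frame_matched_rmsd",
    "best_matched_rmsd",
    "threshold_fractions",
]


@dataclass
class RmsdRecord:
    frame_id: int
    metric: str  # frame_matched | best_matched
    value: float
    matched_frame_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("RMSD must be non-negative")
        if self.metric not in ("frame_matched", "best_matched"):
            raise ValueError(f"unknown metric {self.metric!r}")


def superpose(mobile: np.ndarray, reference: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of mobile onto reference.

    Returns (rotation, translation, rmsd) with a proper rotation
    (det = +1); ``rotation @ x + translation`` maps mobile points onto the
    reference frame.  Fewer than 3 points or a collinear point set raise.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to superpose")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    x, y = mobile - mc, reference - rc
    cov = x.T @ y
    u, s, vt = np.linalg.svd(cov)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = rc - rotation @ mc
    moved = (rotation @ mobile.T).T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rotation, translation, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray,
                    translation: np.ndarray) -> np.ndarray:
    return (rotation @ np.asarray(coords, dtype=float).T).T + translation


def _heavy_rmsd(a: np.ndarray, b: np.ndarray, ligand: LigandModel) -> float:
    idx = ligand.heavy_indices()
    if a.shape != b.shape:
        raise ValueError("ligand atom counts differ")
    diff = a[idx] - b[idx]
    return float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))


def frame_matched_rmsd(docked: Pose, md_coords: np.ndarray, ligand: LigandModel) -> float:
    """Heavy-atom ligand RMSD against the bound pose of the same frame.

    Holo docking guarantees identical protein coordinates, so the protein
    alignment is the identity and the RMSD is computed directly.
    """
    return _heavy_rmsd(np.asarray(docked.ligand_coords), np.asarray(md_coords), ligand)


def best_matched_rmsd(docked: Pose, docked_conf: ProteinConformation,
                      reference: BoundEnsemble,
                      cluster_frame_ids: Optional[Sequence[int]] = None) -> RmsdRecord:
    """Minimum ligand RMSD over the reference cluster after Cα superposition.

    Each candidate reference frame's Cα trace is superposed onto the docked
    conformation's Cα trace; the transform carries the reference ligand, and
    the heavy-atom RMSD to the docked pose is evaluated.  Restricting to
    ``cluster_frame_ids`` follows the usual protocol of searching only the
    docked frame's conformational cluster; omit it to scan the full ensemble.
    """
    target_ca = docked_conf.ca_coords()
    wanted = set(cluster_frame_ids) if cluster_frame_ids is not None else None
    best: Optional[tuple[float, int]] = None
    for conf, lig_xyz in zip(reference.protein, reference.ligand_coords):
        if wanted is not None and conf.frame_id not in wanted:
            continue
        rot, trans, _ = superpose(conf.ca_coords(), target_ca)
        moved_lig = apply_transform(lig_xyz, rot, trans)
        rmsd = _heavy_rmsd(np.asarray(docked.ligand_coords), moved_lig, reference.ligand)
        if best is None or rmsd < best[0]:
            best = (rmsd, conf.frame_id)
    if best is None:
        raise ValueError("empty reference cluster")
    return RmsdRecord(frame_id=docked.frame_id, metric="best_matched",
                      value=best[0], matched_frame_id=best[1])


def threshold_fractions(records: Sequence[RmsdRecord] | Sequence[float],
                        thresholds: Sequence[float] = (3.0, 5.0)) -> dict[float, float]:
    """Percentage (0–100) of records strictly below each RMSD threshold."""
    values = np.array([r.value if isinstance(r, RmsdRecord) else float(r)
                       for r in records])
    if values.size == 0:
        raise ValueError("no RMSD records")
    return {float(t): float(100.0 * np.mean(values < t)) for t in thresholds}
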