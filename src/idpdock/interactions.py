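"""Geometric classification of protein–ligand interactions.

Per frame, each residue is tested independently for five interaction
classes, each with its own geometric criterion:

* contact — any heavy ligand atom within 6.0 Å of a heavy residue atom;
* hydrophobic — any ligand carbon within 5 Å of a residue carbon,
  excluding the backbone Cα;
* charge — any two atoms of opposite formal charge within 5 Å;
* hydrogen bond — a donor hydrogen (H on N/O/S, either partner) within
  3.5 Å of a heavy N/O/S acceptor on the other partner, with a
  donor–hydrogen–acceptor angle above 150°;
* aromatic stacking — for a protein-ring/ligand-ring pair, the centroid
  separation vector R (ligand minus protein centroid) shorter than 5 Å
  and making an angle below 45° with *both* ring normals (each angle
  folded to [0°, 90°] to remove the normal's sign ambiguity).

Classes are computed independently; a specific interaction does not imply
the 6 Å contact flag.  Frame fingerprints aggregate into per-residue
populations and dual-residue simultaneous-contact matrices.

Protein formal charges and aromatic rings come from residue-name
templates at neutral pH (Asp/Glu carboxylate oxygens −1, Lys Nζ and Arg
guanidinium NH +1, His neutral; Phe/Tyr/Trp/His rings); atoms that
already carry an explicit formal charge keep it.  Ligand charges, rings
and donors come from the ligand model (i.e., from the input file).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .clustering import cluster_weighted_average
from .core import LigandModel, ProteinConformation, Residue

__all__ = [
    "InteractionCriteria",
    "RingGeometry",
    "FrameFingerprint",
    "InteractionProfile",
    "DualContactMatrix",
    "ComparisonStats",
    "pairs_within",
    "ring_geometry",
    "fingerprint_frame",
    "fingerprint_docked_ensemble",
    "fingerprint_bound_ensemble",
    "aggregate_profiles",
    "dual_contact_matrix",
    "compare_profiles",
]

INTERACTION_CLASSES = ("contact", "hydrophobic", "aromatic_stack", "charge", "hbond")

# Residue-template formal charges at neutral pH (termini not charged by default).
RESIDUE_CHARGES: dict[str, dict[str, int]] = {
    "ASP": {"OD1": -1, "OD2": -1},
    "GLU": {"OE1": -1, "OE2": -1},
    "LYS": {"NZ": 1},
    "ARG": {"NH1": 1, "NH2": 1},
}

# Aromatic side-chain rings by atom name; Trp contributes both rings.
RESIDUE_RINGS: dict[str, list[tuple[str, ...]]] = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [("CG", "CD1", "CD2", "NE1", "CE2"),
            ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
}

DONOR_BOND_MAX = 1.3  # Å: an H is assigned to the nearest N/O/S within this


@dataclass
class InteractionCriteria:
    """Distance/angle cutoffs for the five interaction classes (Å, degrees)."""

    contact_cutoff: float = 6.0
    hydrophobic_cutoff: float = 5.0
    charge_cutoff: float = 5.0
    hbond_ha_cutoff: float = 3.5
    hbond_angle_min: float = 150.0
    stack_centroid_cutoff: float = 5.0
    stack_angle_max: float = 45.0
    include_his_aromatic: bool = True

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "hydrophobic_cutoff", "charge_cutoff",
                     "hbond_ha_cutoff", "stack_centroid_cutoff"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hbond_angle_min", "stack_angle_max"):
            if not 0 < getattr(self, name) < 180:
                raise ValueError(f"{name} must lie in (0, 180) degrees")


@dataclass(frozen=True)
class RingGeometry:
    """An aromatic ring reduced to its centroid and unit plane normal."""

    centroid: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-6:
            raise ValueError("ring normal must be a unit vector")


def ring_geometry(coords: np.ndarray) -> RingGeometry:
    """Centroid + least-squares plane normal (smallest right-singular vector)."""
    coords = np.asarray(coords, dtype=float)
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    normal = vt[-1]
    return RingGeometry(centroid=centroid, normal=normal / np.linalg.norm(normal))


def pairs_within(coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float) -> np.ndarray:
    """Index pairs (i, j) with ‖a_i − b_j‖ ≤ cutoff, via a KD-tree.

    Guaranteed identical to the all-pairs double loop (which the test suite
    enforces); empty input yields an empty (0, 2) array.
    """
    from scipy.spatial import cKDTree

    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        return np.empty((0, 2), dtype=int)
    tree_a, tree_b = cKDTree(a), cKDTree(b)
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff)
    out = [(i, j) for i, js in enumerate(pairs) for j in js]
    return np.array(out, dtype=int).reshape(-1, 2)


@dataclass
class FrameFingerprint:
    """Per-residue boolean flags for each interaction class in one frame."""

    contact: np.ndarray
    hydrophobic: np.ndarray
    aromatic_stack: np.ndarray
    charge: np.ndarray
    hbond: np.ndarray
    frame_id: int = -1

    @property
    def contacted_residues(self) -> frozenset[int]:
        """1-based indices of residues with the 6 Å contact flag set."""
        return frozenset(int(i) + 1 for i in np.flatnonzero(self.contact))

    def flags(self, cls: str) -> np.ndarray:
        return getattr(self, cls)


@dataclass
class InteractionProfile:
    """Per-residue, per-class populations (fractions of frames) in [0, 1]."""

    populations: dict[str, np.ndarray]
    n_frames: int

    def __post_init__(self) -> None:
        for cls, pop in self.populations.items():
            pop = np.asarray(pop, dtype=float)
            if pop.min() < 0 or pop.max() > 1:
                raise ValueError(f"{cls}: populations must lie in [0, 1]")
            self.populations[cls] = pop

    def to_dataframe(self, pdb_numbers: Optional[Sequence[int]] = None):
        import pandas as pd

        df = pd.DataFrame(self.populations)
        df.insert(0, "pdb_number",
                  list(pdb_numbers) if pdb_numbers is not None else range(1, len(df) + 1))
        return df


@dataclass
class DualContactMatrix:
    """Pairwise simultaneous-contact probabilities; diagonal = per-residue."""

    matrix: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T):
            raise ValueError("dual-contact matrix must be symmetric")
        self.matrix = m


@dataclass
class ComparisonStats:
    """Pearson r and RMSE between two paired profiles/matrices."""

    pearson_r: Optional[float]
    rmse: float

    def __post_init__(self) -> None:
        if self.pearson_r is not None and not -1.0 - 1e-9 <= self.pearson_r <= 1.0 + 1e-9:
            raise ValueError("Pearson r out of [-1, 1]")
        if self.rmse < 0:
            raise ValueError("RMSE must be non-negative")


# ---------------------------------------------------------------------------
# Template helpers
# ---------------------------------------------------------------------------


def _protein_atom_charge(res: Residue, atom) -> int:
    if atom.formal_charge != 0:
        return atom.formal_charge
    return RESIDUE_CHARGES.get(res.name, {}).get(atom.name, 0)


def _residue_rings(res: Residue, include_his: bool) -> list[np.ndarray]:
    templates = RESIDUE_RINGS.get(res.name, [])
    if res.name == "HIS" and not include_his:
        return []
    by_name = {a.name: a.coords for a in res.atoms}
    rings = []
    for names in templates:
        if all(n in by_name for n in names):
            rings.append(np.array([by_name[n] for n in names]))
    return rings


def _residue_donors(res: Residue) -> list[tuple[np.ndarray, np.ndarray]]:
    """(heavy, H) coordinate pairs for hydrogens bonded to N/O/S."""
    heavies = [(a.name, a.coords) for a in res.atoms if a.element.upper() in ("N", "O", "S")]
    donors = []
    for a in res.atoms:
        if a.element.upper() != "H" or not heavies:
            continue
        dists = [np.linalg.norm(a.coords - hxyz) for _, hxyz in heavies]
        j = int(np.argmin(dists))
        if dists[j] <= DONOR_BOND_MAX:
            donors.append((heavies[j][1], a.coords))
    return donors


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        return 0.0
    return float(np.degrees(np.arccos(np.clip(np.dot(v1, v2) / (n1 * n2), -1, 1))))


def _fold_angle(angle: float) -> float:
    """Fold an angle to [0, 90] to cancel ring-normal sign ambiguity."""
    return min(angle, 180.0 - angle)


def _hbond_hit(donors, acceptors, criteria: InteractionCriteria) -> bool:
    for heavy, h in donors:
        for acc in acceptors:
            if np.linalg.norm(h - acc) <= criteria.hbond_ha_cutoff:
                if _angle_deg(heavy - h, acc - h) > criteria.hbond_angle_min:
                    return True
    return False


# ---------------------------------------------------------------------------
# Frame fingerprinting
# ---------------------------------------------------------------------------


def fingerprint_frame(conf: ProteinConformation, ligand: LigandModel,
                      pose_coords: np.ndarray,
                      criteria: InteractionCriteria = InteractionCriteria()
                      ) -> FrameFingerprint:
    """Classify every residue's interactions with one ligand pose.

    ``pose_coords`` follows the ligand atom ordering.  A residue lacking
    the atoms a class needs simply scores False for that class.
    """
    pose = np.asarray(pose_coords, dtype=float)
    if pose.shape != (ligand.n_atoms, 3):
        raise ValueError("pose coordinates do not match ligand atom count")
    n_res = conf.n_residues
    flags = {cls: np.zeros(n_res, dtype=bool) for cls in INTERACTION_CLASSES}

    lig_heavy = pose[ligand.heavy_indices()]
    lig_carbon = np.array([pose[i] for i, a in enumerate(ligand.atoms)
                           if a.element.upper() == "C"]).reshape(-1, 3)
    lig_charges = [(pose[i], a.formal_charge) for i, a in enumerate(ligand.atoms)
                   if a.formal_charge != 0]
    lig_acceptors = [pose[i] for i in ligand.acceptors]
    lig_donors = [(pose[d], pose[h]) for d, h in ligand.donors]
    lig_rings = [ring_geometry(pose[sorted(ring)]) for ring in ligand.aromatic_rings]

    for ri, res in enumerate(conf.residues):
        res_heavy = res.heavy_coords()
        if res_heavy.size and lig_heavy.size:
            flags["contact"][ri] = bool(
                pairs_within(res_heavy, lig_heavy, criteria.contact_cutoff).size
            )
        res_carbon = np.array([a.coords for a in res.atoms
                               if a.element.upper() == "C" and a.name != "CA"]
                              ).reshape(-1, 3)
        if res_carbon.size and lig_carbon.size:
            flags["hydrophobic"][ri] = bool(
                pairs_within(res_carbon, lig_carbon, criteria.hydrophobic_cutoff).size
            )
        res_charges = [(a.coords, _protein_atom_charge(res, a)) for a in res.atoms]
        res_charges = [(xyz, q) for xyz, q in res_charges if q != 0]
        hit = False
        for pxyz, pq in res_charges:
            for lxyz, lq in lig_charges:
                if pq * lq < 0 and np.linalg.norm(pxyz - lxyz) <= criteria.charge_cutoff:
                    hit = True
                    break
            if hit:
                break
        flags["charge"][ri] = hit

        res_acceptors = [a.coords for a in res.atoms
                         if a.is_heavy and a.element.upper() in ("N", "O", "S")]
        res_donors = _residue_donors(res)
        flags["hbond"][ri] = (
            _hbond_hit(res_donors, lig_acceptors, criteria)
            or _hbond_hit(lig_donors, res_acceptors, criteria)
        )

        stacked = False
        for prot_ring in (_residue_rings(res, criteria.include_his_aromatic)):
            pg = ring_geometry(prot_ring)
            for lg in lig_rings:
                r_vec = lg.centroid - pg.centroid
                if np.linalg.norm(r_vec) >= criteria.stack_centroid_cutoff:
                    continue
                ang_p = _fold_angle(_angle_deg(r_vec, pg.normal))
                ang_l = _fold_angle(_angle_deg(r_vec, lg.normal))
                if ang_p < criteria.stack_angle_max and ang_l < criteria.stack_angle_max:
                    stacked = True
                    break
            if stacked:
                break
        flags["aromatic_stack"][ri] = stacked

    return FrameFingerprint(frame_id=conf.frame_id, **flags)


def fingerprint_docked_ensemble(docked, criteria: InteractionCriteria = InteractionCriteria()
                                ) -> list[FrameFingerprint]:
    """Fingerprint every selected pose of a docked ensemble."""
    out = []
    for pose in docked.selected:
        conf = docked.ensemble.frame(pose.frame_id)
        out.append(fingerprint_frame(conf, docked.ligand, pose.ligand_coords, criteria))
    return out


def fingerprint_bound_ensemble(bound, criteria: InteractionCriteria = InteractionCriteria()
                               ) -> list[FrameFingerprint]:
    """Fingerprint every frame of a ligand-bound (MD-style) ensemble."""
    return [fingerprint_frame(conf, bound.ligand, xyz, criteria)
            for conf, xyz in zip(bound.protein, bound.ligand_coords)]


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def aggregate_profiles(fingerprints: Sequence[FrameFingerprint],
                       labels: Optional[np.ndarray] = None,
                       populations: Optional[np.ndarray] = None
                       ):
    """Aggregate frame fingerprints into per-residue class populations.

    Without labels: one overall :class:`InteractionProfile`.  With labels:
    ``(overall, per_cluster)`` where ``per_cluster`` maps cluster id to its
    profile; when cluster ``populations`` are also given the overall profile
    is the population-weighted combination of the per-cluster profiles.
    """
    if not fingerprints:
        raise ValueError("no fingerprints to aggregate")
    n_frames = len(fingerprints)
    stacks = {cls: np.array([fp.flags(cls) for fp in fingerprints]) for cls in INTERACTION_CLASSES}

    def profile_of(mask: np.ndarray) -> InteractionProfile:
        return InteractionProfile(
            populations={cls: stacks[cls][mask].mean(axis=0) for cls in INTERACTION_CLASSES},
            n_frames=int(mask.sum()),
        )

    overall = profile_of(np.ones(n_frames, dtype=bool))
    if labels is None:
        return overall
    labels = np.asarray(labels)
    per_cluster = {int(c): profile_of(labels == c) for c in np.unique(labels)}
    if populations is not None:
        populations = np.asarray(populations, dtype=float)
        clusters = sorted(per_cluster)
        weighted = {}
        for cls in INTERACTION_CLASSES:
            per_res = np.stack([per_cluster[c].populations[cls] for c in clusters])
            pops = np.array([populations[c] for c in clusters])
            weighted[cls] = np.array([
                cluster_weighted_average(per_res[:, j], pops / pops.sum())
                for j in range(per_res.shape[1])
            ])
        overall = InteractionProfile(populations=weighted, n_frames=n_frames)
    return overall, per_cluster


def dual_contact_matrix(fingerprints: Sequence[FrameFingerprint]) -> DualContactMatrix:
    """P(residues i and j are both ligand-contacted in the same frame).

    Symmetric; the diagonal is the single-residue contact probability and
    every off-diagonal entry is bounded by the smaller of its two diagonal
    entries.
    """
    if not fingerprints:
        raise ValueError("no fingerprints")
    contacts = np.array([fp.contact for fp in fingerprints], dtype=float)
    matrix = contacts.T @ contacts / len(fingerprints)
    return DualContactMatrix(matrix=matrix, n_frames=len(fingerprints))


def compare_profiles(a: np.ndarray, b: np.ndarray) -> ComparisonStats:
    """Pearson r and RMSE between two paired profiles or square matrices.

    Square matrices are compared over the upper triangle plus diagonal.
    Zero variance in either vector leaves r undefined (None, with a
    warning); RMSE is always returned.
    """
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share a residue axis")
    if a.ndim == 2 and a.shape[0] == a.shape[1]:
        iu = np.triu_indices(a.shape[0])
        a, b = a[iu], b[iu]
    else:
        a, b = a.ravel(), b.ravel()
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero variance: Pearson r undefined")
        return ComparisonStats(pearson_r=None, rmse=rmse)
    r, _ = stats.pearsonr(a, b)
    return ComparisonStats(pearson_r=float(r), rmse=rmse)
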