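"""Synthetic disordered-peptide ensembles, toy ligands, and planted
ligand-bound ensembles with known statistical structure.

The generator emulates a short IDP fragment as a self-avoiding Cα trace
with fixed 3.8 Å virtual bonds and templated pseudo side chains (a
carboxylate O⁻ pair for acidic residues, an ammonium N⁺ for basic ones, a
planar six-membered ring for aromatics, aliphatic carbons otherwise).
The end-to-end bend angle — the compactness descriptor used to
characterize conformational clusters — is drawn per frame from a target
normal distribution and imposed exactly by rigidly rotating the second
chain half about the middle Cα.  Ligand-bound ensembles are planted with
known per-residue contact probabilities so that fingerprinting and
docking stages can be tested for parameter recovery.

These fixtures exercise geometry, statistics and I/O, not protein
physics: there are no rotamers, no excluded volume beyond a 3.0 Å Cα
self-avoidance radius, and no energetics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    Atom,
    BoundEnsemble,
    ConformationEnsemble,
    LigandModel,
    ProteinConformation,
    Residue,
)

__all__ = [
    "FixtureSpec",
    "generate_peptide_ensemble",
    "generate_ligand",
    "plant_bound_poses",
]

BOND_LENGTH = 3.8  # Å, Cα(i)–Cα(i+1) virtual bond
SELF_AVOID = 3.0  # Å, minimum non-bonded Cα–Cα distance
MAX_RETRIES = 200

RESIDUE_NAMES = {
    "charged-": "ASP",
    "charged+": "LYS",
    "aromatic": "PHE",
    "hydrophobic": "LEU",
    "polar": "SER",
}


@dataclass
class FixtureSpec:
    """Parameters of a synthetic peptide ensemble.

    ``bend_angle_mean``/``bend_angle_sd`` set the target distribution of the
    end-bend angle in degrees (the interior angle at the middle Cα between
    the two chain ends); smaller angles give more compact, hairpin-like
    frames.  ``aromatic_stalk`` is the Cα→ring-centroid distance of aromatic
    pseudo side chains; the default approximates a phenylalanine, while
    larger values displace the ring from the backbone to create an isolated,
    strongly attractive site for docking-recovery fixtures.
    """

    n_res: int = 20
    residue_classes: Optional[Sequence[str]] = None
    n_frames: int = 100
    bend_angle_mean: float = 148.0
    bend_angle_sd: float = 10.0
    aromatic_stalk: float = 3.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_res < 3:
            raise ValueError("need at least 3 residues")
        if self.n_frames < 1:
            raise ValueError("need at least 1 frame")
        if self.residue_classes is None:
            self.residue_classes = ["hydrophobic"] * self.n_res
        if len(self.residue_classes) != self.n_res:
            raise ValueError("residue_classes must have one tag per residue")
        unknown = set(self.residue_classes) - set(RESIDUE_NAMES)
        if unknown:
            raise ValueError(f"unknown residue classes: {sorted(unknown)}")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    probe = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, probe))


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(_unit(axis) * angle_rad).as_matrix()


def _build_ca_trace(rng: np.random.Generator, n_res: int, theta_deg: float) -> np.ndarray:
    """Jittered two-segment Cα walk with the exact bend angle imposed at the
    middle residue by rigid rotation of the second segment."""
    mid = (n_res - 1) // 2
    jitter = 0.25

    def walk(start: np.ndarray, direction: np.ndarray, steps: int) -> list[np.ndarray]:
        pos, d = start.copy(), direction.copy()
        out = []
        for _ in range(steps):
            d = _unit(d + jitter * rng.normal(size=3))
            pos = pos + BOND_LENGTH * d
            out.append(pos.copy())
        return out

    d1 = _unit(rng.normal(size=3))
    first = walk(np.zeros(3), d1, mid)  # steps walking away from the middle
    ca = np.zeros((n_res, 3))
    for i, p in enumerate(first):
        ca[mid - 1 - i] = p
    ca[mid] = 0.0
    d2 = _unit(rng.normal(size=3))
    second = walk(np.zeros(3), d2, n_res - 1 - mid)
    for i, p in enumerate(second, start=mid + 1):
        ca[i] = p

    v1, v2 = ca[0] - ca[mid], ca[-1] - ca[mid]
    current = np.degrees(np.arccos(np.clip(np.dot(_unit(v1), _unit(v2)), -1, 1)))
    axis = np.cross(v2, v1)
    if np.linalg.norm(axis) < 1e-9:
        axis = _any_perpendicular(v1)
    phi = np.radians(theta_deg - current)
    for sign in (1.0, -1.0):
        rot = _rotation_about(axis, sign * phi)
        cand = ca.copy()
        cand[mid + 1:] = (rot @ (ca[mid + 1:] - ca[mid]).T).T + ca[mid]
        w2 = cand[-1] - cand[mid]
        ach = np.degrees(np.arccos(np.clip(np.dot(_unit(v1), _unit(w2)), -1, 1)))
        if abs(ach - theta_deg) < 1e-6:
            return cand
    return cand  # fall back to last candidate (numerically closest)


def _self_avoiding(ca: np.ndarray) -> bool:
    n = ca.shape[0]
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    iu = np.triu_indices(n, k=2)  # non-bonded pairs only
    return bool(np.all(d[iu] >= SELF_AVOID))


def _side_chain_atoms(cls: str, ca: np.ndarray, outward: np.ndarray,
                      perp: np.ndarray, aromatic_stalk: float = 3.3) -> list[Atom]:
    cb = ca + 1.53 * outward
    atoms = [Atom("CB", "C", cb)]
    if cls == "charged-":
        atoms += [
            Atom("OD1", "O", ca + 2.6 * outward + 0.9 * perp, formal_charge=-1),
            Atom("OD2", "O", ca + 2.6 * outward - 0.9 * perp, formal_charge=-1),
        ]
    elif cls == "charged+":
        atoms.append(Atom("NZ", "N", ca + 3.0 * outward, formal_charge=1))
    elif cls == "aromatic":
        center = ca + aromatic_stalk * outward
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        for k, name in enumerate(names):
            ang = 2 * np.pi * k / 6
            xyz = center + 1.39 * (np.cos(ang) * outward + np.sin(ang) * perp)
            atoms.append(Atom(name, "C", xyz))
    elif cls == "hydrophobic":
        atoms.append(Atom("CG", "C", ca + 2.9 * outward))
    elif cls == "polar":
        atoms.append(Atom("OG", "O", ca + 2.4 * outward))
    return atoms


def generate_peptide_ensemble(spec: FixtureSpec) -> ConformationEnsemble:
    """Generate a synthetic disordered-peptide ensemble per the spec.

    Deterministic given ``spec.seed``: frame k always receives the same
    coordinates regardless of how many frames are requested after it.
    Raises after bounded retries if the self-avoidance constraint cannot
    be satisfied at the requested compactness.
    """
    conformations = []
    for fi in range(spec.n_frames):
        rng = np.random.default_rng(np.random.SeedSequence((int(spec.seed), fi)))
        ca = None
        for _ in range(MAX_RETRIES):
            theta = float(np.clip(rng.normal(spec.bend_angle_mean, spec.bend_angle_sd),
                                  5.0, 179.0))
            cand = _build_ca_trace(rng, spec.n_res, theta)
            if _self_avoiding(cand):
                ca = cand
                break
        if ca is None:
            raise RuntimeError(
                f"frame {fi}: could not build a self-avoiding chain at bend angle "
                f"~{spec.bend_angle_mean}° after {MAX_RETRIES} retries"
            )
        residues = []
        for i in range(spec.n_res):
            prev_ca = ca[i - 1] if i > 0 else None
            next_ca = ca[i + 1] if i < spec.n_res - 1 else None
            if prev_ca is not None and next_ca is not None:
                bisector = ca[i] - (prev_ca + next_ca) / 2.0
                bond = next_ca - prev_ca
            else:
                bond = (next_ca - ca[i]) if next_ca is not None else (ca[i] - prev_ca)
                bisector = _any_perpendicular(bond)
            if np.linalg.norm(bisector) < 1e-6:
                bisector = _any_perpendicular(bond)
            outward = _unit(bisector)
            perp_raw = np.cross(outward, bond)
            perp = (_any_perpendicular(outward) if np.linalg.norm(perp_raw) < 1e-6
                    else _unit(perp_raw))
            cls = spec.residue_classes[i]
            atoms = [Atom("CA", "C", ca[i])] + _side_chain_atoms(
                cls, ca[i], outward, perp, aromatic_stalk=spec.aromatic_stalk)
            residues.append(Residue(i + 1, i + 1, RESIDUE_NAMES[cls], atoms))
        conformations.append(ProteinConformation(residues, frame_id=fi + 1))
    return ConformationEnsemble(conformations, source_tag="synthetic")


def generate_ligand(ring: bool = False, amine: bool = False,
                    hbond_donor: bool = False, n_heavy: int = 3,
                    name: str = "LIG") -> LigandModel:
    """Build a toy ligand with the requested pharmacophore features.

    ``n_heavy`` counts heavy atoms; a ring consumes 6, an amine nitrogen 1,
    a hydroxyl donor oxygen 1, and the remainder becomes an aliphatic
    carbon chain.  The amine is protonated (+1 net charge) with three
    hydrogens, mirroring the positively charged amines common in IDP
    binders; the hydroxyl contributes one donor and one acceptor.
    """
    if n_heavy < 1:
        raise ValueError("need at least one heavy atom")
    required = (6 if ring else 0) + (1 if amine else 0) + (1 if hbond_donor else 0)
    if n_heavy < required:
        raise ValueError(
            f"contradictory spec: features require {required} heavy atoms, "
            f"n_heavy={n_heavy}"
        )

    atoms: list[Atom] = []
    bonds: list[tuple[int, int, float]] = []
    rings: list[frozenset[int]] = []
    donors: list[tuple[int, int]] = []
    acceptors: list[int] = []
    cursor = np.zeros(3)
    attach: Optional[int] = None  # index to bond the next group to

    if ring:
        ring_idx = []
        for k in range(6):
            ang = 2 * np.pi * k / 6
            xyz = np.array([1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0])
            atoms.append(Atom(f"C{len(atoms) + 1}", "C", xyz))
            ring_idx.append(len(atoms) - 1)
        for k in range(6):
            bonds.append((ring_idx[k], ring_idx[(k + 1) % 6], 1.5))
        rings.append(frozenset(ring_idx))
        attach = ring_idx[0]
        cursor = atoms[attach].coords + np.array([1.5, 0.0, 0.5])

    n_chain = n_heavy - required
    for k in range(n_chain):
        atoms.append(Atom(f"C{len(atoms) + 1}", "C", cursor))
        if attach is not None:
            bonds.append((attach, len(atoms) - 1, 1.0))
        attach = len(atoms) - 1
        cursor = cursor + np.array([1.3, 0.8 if k % 2 == 0 else -0.8, 0.0])

    if hbond_donor:
        atoms.append(Atom(f"O{len(atoms) + 1}", "O", cursor))
        o_idx = len(atoms) - 1
        parent = attach
        if parent is not None:
            bonds.append((parent, o_idx, 1.0))
        acceptors.append(o_idx)
        atoms.append(Atom(f"H{len(atoms) + 1}", "H", cursor + np.array([0.6, 0.75, 0.0])))
        bonds.append((o_idx, len(atoms) - 1, 1.0))
        donors.append((o_idx, len(atoms) - 1))
        # a following group bonds to the parent carbon, keeping the hydroxyl terminal
        attach = parent if parent is not None else o_idx
        cursor = cursor + np.array([1.4, -1.4, 0.0])

    if amine:
        atoms.append(Atom(f"N{len(atoms) + 1}", "N", cursor, formal_charge=1))
        n_idx = len(atoms) - 1
        if attach is not None:
            bonds.append((attach, n_idx, 1.0))
        acceptors.append(n_idx)
        for k in range(3):
            ang = 2 * np.pi * k / 3
            hxyz = cursor + np.array([0.5, 0.87 * np.cos(ang), 0.87 * np.sin(ang)])
            atoms.append(Atom(f"H{len(atoms) + 1}", "H", hxyz))
            bonds.append((n_idx, len(atoms) - 1, 1.0))
            donors.append((n_idx, len(atoms) - 1))

    return LigandModel(atoms, bonds, rings, donors, acceptors,
                       rotatable_bonds=max(0, n_chain - 1), name=name)


def _side_chain_centroid(res: Residue) -> np.ndarray:
    side = [a.coords for a in res.atoms if a.name != "CA"]
    if not side:
        return res.atoms[res.ca_index].coords
    return np.mean(side, axis=0)


def plant_bound_poses(ensemble: ConformationEnsemble, ligand: LigandModel,
                      contact_probs: Sequence[float], noise_sd: float = 0.0,
                      seed: int = 0) -> BoundEnsemble:
    """Plant ligand poses with known per-residue targeting probabilities.

    Per frame a target residue is drawn with probability ``contact_probs[i]``
    (the residual 1 − Σp leaves the frame unbound); the ligand is rigidly
    rotated at random and its centroid placed 4 Å from the target residue's
    side-chain centroid (plus isotropic Gaussian noise of ``noise_sd`` Å).
    Unbound frames park the ligand ~50 Å outside the protein bounding box.
    Realized per-residue contact frequencies converge to ``contact_probs``
    as the frame count grows.  The planted target residue of each frame
    (1-based, or 0 for unbound) is stored as ``planted_targets``.
    """
    probs = np.asarray(contact_probs, dtype=float)
    n_res = ensemble.conformations[0].n_residues
    if probs.shape != (n_res,):
        raise ValueError("contact_probs must have one entry per residue")
    if probs.min() < 0 or probs.sum() > 1 + 1e-9:
        raise ValueError("contact_probs must be non-negative and sum to <= 1")
    if probs.sum() == 0:
        warnings.warn("all contact probabilities are zero: every frame unbound")
    cumulative = np.cumsum(probs)

    base = ligand.coords() - ligand.coords().mean(axis=0)
    coords_per_frame = []
    targets = []
    for fi, conf in enumerate(ensemble):
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), fi, 7)))
        quat = rng.normal(size=4)
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
        placed = base @ rot.T
        u = rng.random()
        hit = int(np.searchsorted(cumulative, u, side="right"))
        if hit < n_res:
            res = conf.residues[hit]
            sc = _side_chain_centroid(res)
            ca = res.atoms[res.ca_index].coords
            outward = sc - ca
            outward = (_any_perpendicular(np.array([0.0, 0.0, 1.0]))
                       if np.linalg.norm(outward) < 1e-9 else _unit(outward))
            center = sc + 4.0 * outward
            if noise_sd > 0:
                center = center + rng.normal(scale=noise_sd, size=3)
            targets.append(hit + 1)
        else:
            hi = conf.coords().max(axis=0)
            center = hi + 50.0
            targets.append(0)
        coords_per_frame.append(placed + center)

    bound = BoundEnsemble(ensemble, ligand, coords_per_frame)
    bound.planted_targets = targets
    return bound
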