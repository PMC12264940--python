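"""Domain types and structure I/O shared by all pipeline stages.

The unit every stage operates over is a :class:`ConformationEnsemble`: an
ordered list of protein conformations (frames) sharing one topology, as
produced by an MD trajectory or the synthetic generator.  Ligands are held
as :class:`LigandModel` with explicit bonds, formal charges, aromatic rings
and hydrogen-bond donor/acceptor annotations, and docking results as a
:class:`DockedEnsemble` carrying one selected pose per frame plus the full
per-residue candidate lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ProteinConformation",
    "ConformationEnsemble",
    "LigandModel",
    "Pose",
    "DockedEnsemble",
    "BoundEnsemble",
    "StructureError",
    "read_ensemble",
    "write_ensemble",
    "read_ligand",
    "write_ligand_sdf",
    "write_docked_ensemble",
    "read_score_table",
]

# Standard atomic masses (u) for the elements that occur in protein/ligand
# structures handled here.  Unknown elements fall back to RDKit's table.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "SE": 78.971, "B": 10.81,
}


class StructureError(ValueError):
    """Structured error for malformed or inconsistent structure input."""


def element_mass(element: str) -> float:
    key = element.upper()
    if key in ATOMIC_MASSES:
        return ATOMIC_MASSES[key]
    from rdkit import Chem

    pt = Chem.GetPeriodicTable()
    mass = pt.GetAtomicWeight(element.capitalize())
    if mass <= 0:
        raise StructureError(f"unknown element {element!r}")
    return mass


@dataclass
class Atom:
    """One atom: name label, element, coordinates in Å, formal charge, mass."""

    name: str
    element: str
    coords: np.ndarray
    formal_charge: int = 0
    mass: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if self.mass == 0.0:
            self.mass = element_mass(self.element)
        if self.mass <= 0:
            raise StructureError(f"atom {self.name!r}: mass must be positive")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    """A protein residue: 1-based index, author PDB number, atoms in order."""

    index: int
    pdb_number: int
    name: str
    atoms: list[Atom]
    ca_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"residue {self.name} {self.pdb_number}: no atoms")
        if self.ca_index is None:
            for i, a in enumerate(self.atoms):
                if a.name == "CA":
                    self.ca_index = i
                    break
        elif self.atoms[self.ca_index].name != "CA":
            raise StructureError(
                f"residue {self.name} {self.pdb_number}: ca_index does not point at CA"
            )

    @property
    def ca(self) -> Optional[Atom]:
        return None if self.ca_index is None else self.atoms[self.ca_index]

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy]).reshape(-1, 3)


@dataclass
class ProteinConformation:
    """One frame of an ensemble: ordered residues plus a unique frame id."""

    residues: list[Residue]
    frame_id: int

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms()])

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms() if a.is_heavy]).reshape(-1, 3)

    def ca_coords(self) -> np.ndarray:
        cas = [r.ca for r in self.residues]
        if any(c is None for c in cas):
            missing = [r.index for r, c in zip(self.residues, cas) if c is None]
            raise StructureError(f"residues without CA: {missing}")
        return np.array([c.coords for c in cas])

    def topology_signature(self) -> tuple:
        return tuple(
            (r.name, r.pdb_number, tuple((a.name, a.element) for a in r.atoms))
            for r in self.residues
        )


@dataclass
class ConformationEnsemble:
    """Ordered conformations sharing one topology; the docking unit."""

    conformations: list[ProteinConformation]
    source_tag: str = "apo"

    def __post_init__(self) -> None:
        if not self.conformations:
            raise StructureError("ensemble is empty")
        ids = [c.frame_id for c in self.conformations]
        if len(set(ids)) != len(ids):
            raise StructureError("frame_ids are not unique")
        ref = self.conformations[0].topology_signature()
        for conf in self.conformations[1:]:
            if conf.topology_signature() != ref:
                raise StructureError(
                    f"topology mismatch in frame {conf.frame_id}: ensembles must "
                    "share residue count, names and atom ordering"
                )

    def __len__(self) -> int:
        return len(self.conformations)

    def __iter__(self):
        return iter(self.conformations)

    def frame(self, frame_id: int) -> ProteinConformation:
        for conf in self.conformations:
            if conf.frame_id == frame_id:
                return conf
        raise KeyError(f"no frame with id {frame_id}")

    def subset(self, frame_ids: Sequence[int], source_tag: Optional[str] = None) -> "ConformationEnsemble":
        wanted = set(frame_ids)
        confs = [c for c in self.conformations if c.frame_id in wanted]
        return ConformationEnsemble(confs, source_tag or self.source_tag)


@dataclass
class LigandModel:
    """A small molecule: atoms, bonds, rings, H-bond donors/acceptors.

    ``donors`` pairs the heavy donor atom (N/O/S) with its hydrogen;
    ``acceptors`` lists heavy N/O/S atoms; ``aromatic_rings`` are sets of
    atom positions forming one ring each.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    aromatic_rings: list[frozenset[int]] = field(default_factory=list)
    donors: list[tuple[int, int]] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)
    rotatable_bonds: int = 0
    name: str = "LIG"

    def __post_init__(self) -> None:
        for ring in self.aromatic_rings:
            if len(ring) < 5:
                raise StructureError("aromatic ring with fewer than 5 atoms")
            if any(not self.atoms[i].is_heavy for i in ring):
                raise StructureError("aromatic ring contains hydrogen atoms")
        bonded = {frozenset((i, j)) for i, j, _ in self.bonds}
        for heavy, h in self.donors:
            if self.atoms[heavy].element.upper() not in ("N", "O", "S"):
                raise StructureError("donor heavy atom must be N, O or S")
            if self.atoms[h].element.upper() != "H":
                raise StructureError("donor hydrogen position is not a hydrogen")
            if bonded and frozenset((heavy, h)) not in bonded:
                raise StructureError("donor hydrogen not bonded to its heavy atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def net_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.is_heavy], dtype=int)


@dataclass
class Pose:
    """One placed ligand copy: coordinates (ligand atom order), score, origin."""

    ligand_coords: np.ndarray
    raw_score: float
    frame_id: int
    origin_residue: Optional[int] = None

    def __post_init__(self) -> None:
        self.ligand_coords = np.asarray(self.ligand_coords, dtype=float)
        if self.ligand_coords.ndim != 2 or self.ligand_coords.shape[1] != 3:
            raise StructureError("pose coordinates must be (n_atoms, 3)")


@dataclass
class DockedEnsemble:
    """One selected pose per frame plus all per-residue candidates."""

    selected: list[Pose]
    candidates: dict[int, list[Pose]]
    backend_tag: str
    polarity: str  # lower_is_better | higher_is_better
    ensemble: Optional[ConformationEnsemble] = None
    ligand: Optional[LigandModel] = None
    failed_frames: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.polarity not in ("lower_is_better", "higher_is_better"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        seen = set()
        for pose in self.selected:
            if pose.frame_id in seen:
                raise StructureError(f"two selected poses for frame {pose.frame_id}")
            seen.add(pose.frame_id)

    def scores(self) -> np.ndarray:
        return np.array([p.raw_score for p in self.selected])

    def pose_for(self, frame_id: int) -> Pose:
        for p in self.selected:
            if p.frame_id == frame_id:
                return p
        raise KeyError(f"no selected pose for frame {frame_id}")


@dataclass
class BoundEnsemble:
    """A ligand-bound (holo-style) ensemble: protein frames + one ligand pose each."""

    protein: ConformationEnsemble
    ligand: LigandModel
    ligand_coords: list[np.ndarray]  # one (n_atoms, 3) array per frame, frame order

    def __post_init__(self) -> None:
        if len(self.ligand_coords) != len(self.protein):
            raise StructureError("one ligand pose per protein frame required")
        self.ligand_coords = [np.asarray(c, dtype=float) for c in self.ligand_coords]
        for c in self.ligand_coords:
            if c.shape != (self.ligand.n_atoms, 3):
                raise StructureError("ligand pose shape does not match ligand atoms")

    def __len__(self) -> int:
        return len(self.protein)


# ---------------------------------------------------------------------------
# PDB I/O (multi-model ensembles)
# ---------------------------------------------------------------------------


def _element_from_pdb_atom(bio_atom) -> str:
    elem = (bio_atom.element or "").strip()
    if elem:
        return elem.capitalize() if len(elem) > 1 else elem.upper()
    name = bio_atom.get_name().strip()
    return name[0].upper()


def read_ensemble(path: str | Path, source_tag: str = "apo") -> ConformationEnsemble:
    """Read a multi-model PDB into a :class:`ConformationEnsemble`.

    One conformation per MODEL block; ``frame_id`` is the model serial.
    Alternate location A is kept (others dropped with a warning); insertion
    codes are rejected.  All models must share residue count, names and atom
    ordering; a mismatch raises :class:`StructureError` naming the model.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ens", str(path))
    models = list(structure)
    if not models:
        raise StructureError(f"{path}: no MODEL blocks / atoms found")

    conformations = []
    dropped_altloc = False
    for model in models:
        residues: list[Residue] = []
        idx = 0
        for chain in model:
            for res in chain:
                het, seq, icode = res.get_id()
                if het.strip():
                    continue  # skip waters/heteroatoms in protein ensembles
                if icode.strip():
                    raise StructureError(
                        f"{path}: insertion code {icode!r} at residue {seq} not supported"
                    )
                idx += 1
                atoms = []
                for a in res.get_unpacked_list():
                    alt = a.get_altloc()
                    if alt not in (" ", "", "A"):
                        dropped_altloc = True
                        continue
                    elem = _element_from_pdb_atom(a)
                    atoms.append(Atom(a.get_name(), elem, np.array(a.get_coord(), dtype=float)))
                residues.append(Residue(idx, seq, res.get_resname(), atoms))
        if not residues:
            raise StructureError(f"{path}: model {model.id + 1} has no protein residues")
        conformations.append(ProteinConformation(residues, frame_id=model.serial_num))
    if dropped_altloc:
        warnings.warn("alternate locations other than A were dropped")

    ref = conformations[0].topology_signature()
    for conf in conformations[1:]:
        if conf.topology_signature() != ref:
            raise StructureError(
                f"{path}: model {conf.frame_id} does not share the topology of model "
                f"{conformations[0].frame_id}"
            )
    return ConformationEnsemble(conformations, source_tag)


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str, resnum: int,
                   xyz: np.ndarray, element: str) -> str:
    name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"ATOM  {serial:>5d} {name_f:<4s} {resname:<3s} {chain}{resnum:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element.upper():>2s}"
    )


def write_ensemble(ensemble: ConformationEnsemble, path: str | Path,
                   ligand: Optional[LigandModel] = None,
                   ligand_coords: Optional[Sequence[np.ndarray]] = None) -> None:
    """Write a multi-model PDB; optionally append a ligand (HETATM-free, resname
    from the ligand model) after the protein in every MODEL block."""
    path = Path(path)
    lines: list[str] = []
    for fi, conf in enumerate(ensemble):
        lines.append(f"MODEL     {conf.frame_id:>4d}")
        serial = 0
        for res in conf.residues:
            for a in res.atoms:
                serial += 1
                lines.append(_pdb_atom_line(serial, a.name, res.name, "A",
                                            res.pdb_number, a.coords, a.element))
        lines.append("TER")
        if ligand is not None and ligand_coords is not None:
            coords = ligand_coords[fi]
            for ai, a in enumerate(ligand.atoms):
                serial += 1
                lines.append(_pdb_atom_line(serial, a.name, ligand.name[:3], "B",
                                            1, coords[ai], a.element))
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_bound_ensemble(path: str | Path, ligand: LigandModel,
                        source_tag: str = "holo") -> BoundEnsemble:
    """Read a multi-model PDB written with a ligand on chain B back into a
    :class:`BoundEnsemble`.  The ligand atom count must match ``ligand``."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("holo", str(path))
    conformations = []
    lig_coords = []
    for model in structure:
        residues = []
        lig_xyz = []
        idx = 0
        for chain in model:
            for res in chain:
                atoms_xyz = [np.array(a.get_coord(), dtype=float) for a in res]
                if chain.id == "B" or res.get_resname() == ligand.name[:3]:
                    lig_xyz.extend(atoms_xyz)
                    continue
                idx += 1
                atoms = [Atom(a.get_name(), _element_from_pdb_atom(a),
                              np.array(a.get_coord(), dtype=float)) for a in res]
                residues.append(Residue(idx, res.get_id()[1], res.get_resname(), atoms))
        conformations.append(ProteinConformation(residues, frame_id=model.serial_num))
        arr = np.array(lig_xyz)
        if arr.shape != (ligand.n_atoms, 3):
            raise StructureError(
                f"{path}: model {model.serial_num} ligand has {arr.shape[0]} atoms, "
                f"expected {ligand.n_atoms}"
            )
        lig_coords.append(arr)
    return BoundEnsemble(ConformationEnsemble(conformations, source_tag), ligand, lig_coords)


# ---------------------------------------------------------------------------
# Ligand I/O (RDKit-backed)
# ---------------------------------------------------------------------------


def _ligand_from_rdkit(mol, name: str = "LIG") -> LigandModel:
    from rdkit import Chem

    if mol is None:
        raise StructureError("RDKit could not parse the ligand file")
    conf = mol.GetConformer()
    atoms = []
    for a in mol.GetAtoms():
        pos = conf.GetAtomPosition(a.GetIdx())
        atoms.append(Atom(
            name=a.GetSymbol() + str(a.GetIdx() + 1),
            element=a.GetSymbol(),
            coords=np.array([pos.x, pos.y, pos.z]),
            formal_charge=a.GetFormalCharge(),
            mass=a.GetMass(),
        ))
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
             for b in mol.GetBonds()]
    rings = []
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring) and len(ring) >= 5:
            rings.append(frozenset(ring))
    donors = []
    for a in mol.GetAtoms():
        if a.GetSymbol() in ("N", "O", "S"):
            for nb in a.GetNeighbors():
                if nb.GetSymbol() == "H":
                    donors.append((a.GetIdx(), nb.GetIdx()))
    acceptors = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O", "S")]
    if not any(a.GetSymbol() == "H" for a in mol.GetAtoms()):
        warnings.warn("ligand has no explicit hydrogens; hydrogen-bond donors empty")
    from rdkit.Chem import rdMolDescriptors

    rot = rdMolDescriptors.CalcNumRotatableBonds(mol)
    return LigandModel(atoms, bonds, rings, donors, acceptors, rot, name=name)


def read_ligand(path: str | Path, name: str = "LIG") -> LigandModel:
    """Read an SDF (preferred), MOL2 or PDB ligand file into a LigandModel.

    Hydrogens are kept; aromaticity comes from the input flags / RDKit ring
    perception; formal charges from the connection table annotations.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        mol = next(iter(supplier), None)
    elif suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False)
    elif suffix == ".pdb":
        mol = Chem.MolFromPDBFile(str(path), removeHs=False)
    else:
        raise StructureError(f"unsupported ligand format {suffix!r}")
    return _ligand_from_rdkit(mol, name=name)


def write_ligand_sdf(ligand: LigandModel, path: str | Path) -> None:
    """Write a LigandModel as a V2000 SDF block (coordinates, bonds, charges)."""
    path = Path(path)
    n_atoms, n_bonds = ligand.n_atoms, len(ligand.bonds)
    lines = [ligand.name, "  idpdock", "", f"{n_atoms:>3d}{n_bonds:>3d}  0  0  0  0  0  0  0  0999 V2000"]
    for a in ligand.atoms:
        x, y, z = a.coords
        lines.append(f"{x:>10.4f}{y:>10.4f}{z:>10.4f} {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    order_code = {1.0: 1, 2.0: 2, 3.0: 3, 1.5: 4}
    for i, j, order in ligand.bonds:
        lines.append(f"{i + 1:>3d}{j + 1:>3d}{order_code.get(order, 1):>3d}  0  0  0  0")
    charged = [(i, a.formal_charge) for i, a in enumerate(ligand.atoms) if a.formal_charge]
    for k in range(0, len(charged), 8):
        chunk = charged[k:k + 8]
        line = f"M  CHG{len(chunk):>3d}"
        for i, q in chunk:
            line += f"{i + 1:>4d}{q:>4d}"
        lines.append(line)
    lines += ["M  END", "$$$$"]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Docked-ensemble persistence
# ---------------------------------------------------------------------------


def write_docked_ensemble(de: DockedEnsemble, path_prefix: str | Path) -> tuple[Path, Path]:
    """Persist a docked ensemble: ``<prefix>.pdb`` (protein + selected ligand
    pose per MODEL) and ``<prefix>_scores.tsv`` (frame_id, origin_residue,
    raw_score).  Returns the two paths."""
    if not de.selected:
        raise StructureError("docked ensemble has no selected poses")
    if de.ensemble is None or de.ligand is None:
        raise StructureError("docked ensemble lacks its protein ensemble or ligand")
    prefix = Path(path_prefix)
    pdb_path = prefix.with_suffix(".pdb")
    tsv_path = prefix.parent / (prefix.name + "_scores.tsv")

    selected_ids = [p.frame_id for p in de.selected]
    sub = de.ensemble.subset(selected_ids)
    coords = [de.pose_for(c.frame_id).ligand_coords for c in sub]
    write_ensemble(sub, pdb_path, ligand=de.ligand, ligand_coords=coords)

    rows = ["frame_id\torigin_residue\traw_score"]
    for p in de.selected:
        origin = "" if p.origin_residue is None else str(p.origin_residue)
        rows.append(f"{p.frame_id}\t{origin}\t{p.raw_score:.6f}")
    tsv_path.write_text("\n".join(rows) + "\n")
    return pdb_path, tsv_path


def read_score_table(path: str | Path):
    """Read a `<prefix>_scores.tsv` file into a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path, sep="\t")
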