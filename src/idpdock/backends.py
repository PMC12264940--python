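"""Docking backend contract, the built-in mock grid backend, and a thin
adapter for external grid engines.

Every backend exposes ``spec`` (a :class:`BackendSpec` declaring its score
polarity and search mode) and ``dock(request) -> [(Pose, score), ...]``.
The mock backend is fully deterministic and oracle-checkable: it translates
the rigid ligand conformer over a regular grid filling the search box and
scores each placement with a short-range pair potential.  It exists so the
ensemble protocol and all downstream statistics can be exercised and
verified without an external docking binary; it does not sample ligand
torsions or rotations.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .boxes import SearchBox, radius_of_gyration
from .core import LigandModel, Pose, ProteinConformation

__all__ = [
    "BackendSpec",
    "DockRequest",
    "BackendError",
    "BackendUnavailableError",
    "MockGridBackend",
    "mock_grid_dock",
    "GridEngineAdapter",
    "whole_conformation_box",
]

# Mock pair potential: hard clash below 2 Å, Gaussian attraction centred at
# 3.5 Å, zero beyond the 8 Å interaction cutoff.
CLASH_DISTANCE = 2.0
CLASH_PENALTY = 1000.0
WELL_DISTANCE = 3.5
PAIR_CUTOFF = 8.0


class BackendError(RuntimeError):
    """A docking call failed (bad box, engine crash, unparsable output)."""


class BackendUnavailableError(BackendError):
    """The external engine binary/runtime is not present."""


@dataclass
class BackendSpec:
    name: str
    polarity: str  # lower_is_better | higher_is_better
    mode: str  # boxed | whole_conformation
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.polarity not in ("lower_is_better", "higher_is_better"):
            raise ValueError(f"polarity must be declared, got {self.polarity!r}")
        if self.mode not in ("boxed", "whole_conformation"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class DockRequest:
    conformation: ProteinConformation
    ligand: LigandModel
    box: Optional[SearchBox] = None
    n_poses: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_poses < 1:
            raise ValueError("n_poses must be >= 1")


def whole_conformation_box(conf: ProteinConformation, ligand: LigandModel) -> SearchBox:
    """Cubic box covering the whole protein plus a 2·Rg ligand margin."""
    coords = conf.coords()
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    margin = 2.0 * max(radius_of_gyration(ligand), 1.0)
    edge = float((hi - lo).max() + 2.0 * margin)
    return SearchBox(center=(lo + hi) / 2.0, edge=edge)


def pair_score_terms(distances: np.ndarray) -> np.ndarray:
    """Score contribution of ligand-heavy/protein-heavy pairs at given distances."""
    terms = np.where(
        distances < CLASH_DISTANCE,
        CLASH_PENALTY,
        -np.exp(-((distances - WELL_DISTANCE) ** 2) / 2.0),
    )
    return np.where(distances <= PAIR_CUTOFF, terms, 0.0)


def _grid_offsets(edge: float, spacing: float) -> np.ndarray:
    """1-D grid coordinates (relative to the box centre) of spacing ``spacing``
    filling an edge of length ``edge``, symmetric about zero."""
    n = int(np.floor(edge / spacing))
    if n < 1:
        raise BackendError(f"empty grid: edge {edge:.3f} Å < spacing {spacing:.3f} Å")
    return (np.arange(n) - (n - 1) / 2.0) * spacing


def mock_grid_dock(req: DockRequest, spacing: float = 1.0,
                   frame_id: Optional[int] = None) -> list[tuple[Pose, float]]:
    """Deterministic rigid-body grid docking.

    The ligand conformer is translated (no rotation) so its geometric
    centroid visits every node of a regular grid of the given spacing that
    fills the box.  Each placement is scored by summing the pair potential
    over all ligand-heavy/protein-heavy atom pairs within 8 Å.  Placements
    are returned sorted by ascending score (lower is better); ties break by
    lexicographic grid order (x, then y, then z).
    """
    if req.box is None:
        raise BackendError("mock grid docking requires a search box")
    if spacing <= 0:
        raise BackendError("grid spacing must be positive")
    box = req.box
    offs = _grid_offsets(box.edge, spacing)
    # grid points in lexicographic (x, y, z) order
    gx, gy, gz = np.meshgrid(offs, offs, offs, indexing="ij")
    points = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1) + box.center

    lig_coords = req.ligand.coords()
    centroid = lig_coords.mean(axis=0)
    rel = lig_coords - centroid
    heavy = req.ligand.heavy_indices()
    rel_heavy = rel[heavy]

    prot = req.conformation.heavy_coords()
    # prefilter protein atoms that can interact with any grid placement
    reach = box.edge * np.sqrt(3.0) / 2.0 + np.linalg.norm(rel_heavy, axis=1).max(initial=0.0) + PAIR_CUTOFF
    near = prot[np.linalg.norm(prot - box.center, axis=1) <= reach]

    n_points = points.shape[0]
    scores = np.zeros(n_points)
    if near.shape[0] and rel_heavy.shape[0]:
        chunk = max(1, int(2e6 // max(1, rel_heavy.shape[0] * near.shape[0])))
        for start in range(0, n_points, chunk):
            pts = points[start:start + chunk]
            # (chunk, n_heavy, 3) ligand atom positions
            lig = pts[:, None, :] + rel_heavy[None, :, :]
            d = np.linalg.norm(lig[:, :, None, :] - near[None, None, :, :], axis=-1)
            scores[start:start + chunk] = pair_score_terms(d).sum(axis=(1, 2))

    order = np.lexsort((np.arange(n_points), scores))  # score, then grid order
    fid = frame_id if frame_id is not None else -1
    results = []
    for idx in order[: req.n_poses]:
        pose = Pose(ligand_coords=rel + points[idx], raw_score=float(scores[idx]), frame_id=fid)
        results.append((pose, float(scores[idx])))
    return results


class MockGridBackend:
    """Built-in deterministic backend (lower score is better).

    ``mode='boxed'`` requires a box per request; ``mode='whole_conformation'``
    builds a box covering the protein plus a 2·Rg margin.
    """

    def __init__(self, spacing: float = 1.0, mode: str = "boxed"):
        self.spacing = spacing
        self.spec = BackendSpec(
            name="mock-grid", polarity="lower_is_better", mode=mode,
            parameters={"spacing": spacing},
        )

    def dock(self, req: DockRequest, frame_id: Optional[int] = None) -> list[tuple[Pose, float]]:
        if self.spec.mode == "whole_conformation" and req.box is None:
            req = DockRequest(req.conformation, req.ligand,
                              box=whole_conformation_box(req.conformation, req.ligand),
                              n_poses=req.n_poses, seed=req.seed)
        return mock_grid_dock(req, spacing=self.spacing, frame_id=frame_id)


# ---------------------------------------------------------------------------
# External grid-engine adapter (Vina-style command line)
# ---------------------------------------------------------------------------

_PDBQT_TYPES = {"C": "C", "N": "N", "O": "OA", "S": "SA", "H": "HD", "P": "P",
                "F": "F", "CL": "Cl", "BR": "Br", "I": "I"}


def emit_receptor_pdbqt(conf: ProteinConformation, path: str | Path) -> None:
    """Write a rigid-receptor PDBQT (zero partial charges, element-derived types)."""
    lines = []
    serial = 0
    for res in conf.residues:
        for a in res.atoms:
            serial += 1
            t = _PDBQT_TYPES.get(a.element.upper(), a.element.upper())
            x, y, z = a.coords
            lines.append(
                f"ATOM  {serial:>5d}  {a.name:<3s} {res.name:<3s} A{res.pdb_number:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}    {0.0:6.3f} {t:<2s}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def emit_ligand_pdbqt(ligand: LigandModel, path: str | Path) -> None:
    """Write the ligand as a rigid PDBQT (single ROOT block, no torsion tree).

    Torsional flexibility is left to engine-side preparation tools; this
    writer exists so the adapter can hand the engine valid input when no
    preparation tool is configured.
    """
    lines = ["ROOT"]
    for i, a in enumerate(ligand.atoms, start=1):
        t = _PDBQT_TYPES.get(a.element.upper(), a.element.upper())
        x, y, z = a.coords
        lines.append(
            f"ATOM  {i:>5d}  {a.name:<3s} LIG B   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}    {0.0:6.3f} {t:<2s}"
        )
    lines += ["ENDROOT", "TORSDOF 0"]
    Path(path).write_text("\n".join(lines) + "\n")


def parse_vina_scores(text: str) -> list[float]:
    """Extract pose scores from engine output (``REMARK VINA RESULT`` lines)."""
    scores = []
    for line in text.splitlines():
        if line.startswith("REMARK VINA RESULT:"):
            parts = line.split()
            try:
                scores.append(float(parts[3]))
            except (IndexError, ValueError) as exc:
                raise BackendError(f"unparsable engine output line: {line!r}") from exc
    if not scores:
        raise BackendError("no scores found in engine output")
    return scores


def parse_vina_poses(pdbqt_text: str, ligand: LigandModel,
                     frame_id: int = -1) -> list[tuple[Pose, float]]:
    """Parse a multi-MODEL output PDBQT into scored poses (ligand atom order)."""
    poses: list[tuple[Pose, float]] = []
    coords: list[list[float]] = []
    score: Optional[float] = None
    for line in pdbqt_text.splitlines() + ["ENDMDL"]:
        if line.startswith("REMARK VINA RESULT:"):
            score = float(line.split()[3])
        elif line.startswith(("ATOM", "HETATM")):
            coords.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
        elif line.startswith("ENDMDL") and coords:
            if score is None:
                raise BackendError("pose block without a VINA RESULT score")
            arr = np.array(coords)
            if arr.shape[0] != ligand.n_atoms:
                raise BackendError(
                    f"pose has {arr.shape[0]} atoms, ligand has {ligand.n_atoms}"
                )
            poses.append((Pose(arr, score, frame_id), score))
            coords, score = [], None
    if not poses:
        raise BackendError("no poses found in engine output")
    return poses


class GridEngineAdapter:
    """Thin subprocess adapter for Vina-style boxed grid engines.

    Confidence-reporting engines (DiffDock-style) plug in through the same
    contract with ``polarity='higher_is_better'`` and ``mode=
    'whole_conformation'``; their adapter normalizes reported uncertainty to
    a higher-is-better confidence at this boundary.
    """

    def __init__(self, spec: BackendSpec):
        self.spec = spec

    def build_command(self, receptor: str, ligand: str, out: str,
                      box: SearchBox, n_poses: int, seed: int) -> list[str]:
        binary = self.spec.parameters.get("binary", self.spec.name)
        cfg = box.to_engine_config()
        cmd = [binary, "--receptor", receptor, "--ligand", ligand, "--out", out]
        for key in ("center_x", "center_y", "center_z", "size_x", "size_y", "size_z"):
            cmd += [f"--{key}", f"{cfg[key]:.3f}"]
        cmd += ["--num_modes", str(n_poses), "--seed", str(seed)]
        for key, value in self.spec.parameters.items():
            if key not in ("binary",):
                cmd += [f"--{key}", str(value)]
        return cmd

    def dock(self, req: DockRequest, workdir: str | Path = ".",
             frame_id: Optional[int] = None) -> list[tuple[Pose, float]]:
        binary = self.spec.parameters.get("binary", self.spec.name)
        if shutil.which(binary) is None:
            raise BackendUnavailableError(f"engine binary {binary!r} not found on PATH")
        if self.spec.mode == "boxed" and req.box is None:
            raise BackendError("boxed engine requires a search box")
        workdir = Path(workdir)
        rec, lig, out = workdir / "receptor.pdbqt", workdir / "ligand.pdbqt", workdir / "out.pdbqt"
        emit_receptor_pdbqt(req.conformation, rec)
        emit_ligand_pdbqt(req.ligand, lig)
        cmd = self.build_command(str(rec), str(lig), str(out), req.box, req.n_poses, req.seed)
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise BackendError(f"engine failed ({proc.returncode}): {proc.stderr[-2000:]}")
        fid = frame_id if frame_id is not None else -1
        return parse_vina_poses(out.read_text(), req.ligand, frame_id=fid)
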