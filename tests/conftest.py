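import numpy as np
import pytest

import idpdock as d
from idpdock.core import Atom, ProteinConformation, Residue


@pytest.fixture(scope="session")
def peptide_ensemble():
    """Small mixed-composition disordered peptide ensemble."""
    classes = ["charged-", "hydrophobic", "aromatic", "polar", "charged+",
               "hydrophobic", "polar", "aromatic", "charged-", "hydrophobic"]
    spec = d.FixtureSpec(n_res=10, residue_classes=classes, n_frames=6, seed=42)
    return d.generate_peptide_ensemble(spec)


@pytest.fixture(scope="session")
def ring_ligand():
    return d.generate_ligand(ring=True, amine=True, hbond_donor=True, n_heavy=9)


@pytest.fixture(scope="session")
def probe_ligand():
    return d.generate_ligand(n_heavy=2)


def make_conformation(ca_positions, frame_id=1, resname="LEU"):
    """Cα-only conformation from a list of coordinates."""
    residues = [
        Residue(i + 1, i + 1, resname, [Atom("CA", "C", np.asarray(p, dtype=float))])
        for i, p in enumerate(ca_positions)
    ]
    return ProteinConformation(residues, frame_id=frame_id)
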