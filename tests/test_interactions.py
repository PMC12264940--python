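"""Geometric interaction classifiers: constructed boundary cases, neighbor
search vs all-pairs oracle, aggregation and comparison statistics."""

import numpy as np
import pytest

import idpdock as d
from idpdock.core import Atom, LigandModel, ProteinConformation, Residue
from idpdock.interactions import FrameFingerprint, pairs_within, ring_geometry


def _residue(atoms, name="GLY", index=1):
    return Residue(index, index, name, atoms)


def _conf(residues):
    return ProteinConformation(residues, frame_id=1)


def _probe_ligand(atoms, **kw):
    return LigandModel(atoms, **kw)


def _hexagon(center, u, v, radius=1.39):
    pts = []
    for k in range(6):
        ang = 2 * np.pi * k / 6
        pts.append(np.asarray(center) + radius * (np.cos(ang) * np.asarray(u)
                                                  + np.sin(ang) * np.asarray(v)))
    return pts


# --- charge contacts --------------------------------------------------------


@pytest.mark.parametrize("dist,expected", [(4.9, True), (5.1, False)])
def test_charge_contact_boundary(dist, expected):
    res = _residue([Atom("CA", "C", (0, 0, 0)), Atom("OD1", "O", (1, 0, 0), formal_charge=-1)],
                   name="ASP")
    lig = _probe_ligand([Atom("N1", "N", (1 + dist, 0, 0), formal_charge=1)])
    fp = d.fingerprint_frame(_conf([res]), lig, lig.coords())
    assert bool(fp.charge[0]) is expected


def test_like_charges_do_not_count():
    res = _residue([Atom("NZ", "N", (0, 0, 0), formal_charge=1)], name="LYS")
    lig = _probe_ligand([Atom("N1", "N", (3.0, 0, 0), formal_charge=1)])
    fp = d.fingerprint_frame(_conf([res]), lig, lig.coords())
    assert not fp.charge[0]


def test_template_charges_apply_by_residue_name():
    """Asp carboxylate oxygens are charged by template even when the input
    file carries no explicit formal charge."""
    res = _residue([Atom("OD1", "O", (0, 0, 0))], name="ASP")
    lig = _probe_ligand([Atom("N1", "N", (4.0, 0, 0), formal_charge=1)])
    fp = d.fingerprint_frame(_conf([res]), lig, lig.coords())
    assert fp.charge[0]


# --- hydrogen bonds ---------------------------------------------------------


def _hbond_fixture(angle_deg, ha_dist=3.4):
    """Ligand N–H donor; protein O acceptor at the given D–H–A angle."""
    donor_heavy = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    ang = np.radians(180.0 - angle_deg)
    acceptor = h + ha_dist * np.array([np.cos(ang), np.sin(ang), 0.0])
    lig = _probe_ligand(
        [Atom("N1", "N", donor_heavy), Atom("H1", "H", h)],
        bonds=[(0, 1, 1.0)], donors=[(0, 1)], acceptors=[0],
    )
    res = _residue([Atom("O", "O", acceptor)], name="SER")
    return _conf([res]), lig


@pytest.mark.parametrize("angle,expected", [(170.0, True), (140.0, False)])
def test_hbond_angle_boundary(angle, expected):
    conf, lig = _hbond_fixture(angle)
    fp = d.fingerprint_frame(conf, lig, lig.coords())
    assert bool(fp.hbond[0]) is expected


def test_hbond_distance_boundary():
    conf, lig = _hbond_fixture(170.0, ha_dist=3.6)
    fp = d.fingerprint_frame(conf, lig, lig.coords())
    assert not fp.hbond[0]


def test_protein_side_donor_detected():
    """A protein hydroxyl hydrogen can donate to a ligand acceptor."""
    res = _residue([Atom("OG", "O", (0, 0, 0)), Atom("HG", "H", (0.96, 0, 0))],
                   name="SER")
    lig = _probe_ligand([Atom("O1", "O", (3.96, 0, 0))], acceptors=[0])
    fp = d.fingerprint_frame(_conf([res]), lig, lig.coords())
    assert fp.hbond[0]  # H–A 3.0 Å, angle 180°


# --- aromatic stacking ------------------------------------------------------


def _phe_residue(center, u, v):
    names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    pts = _hexagon(center, u, v)
    return _residue([Atom("CA", "C", np.asarray(center) + [0, 0, -5.0])]
                    + [Atom(n, "C", p) for n, p in zip(names, pts)], name="PHE")


def _ring_ligand(center, u, v):
    pts = _hexagon(center, u, v)
    atoms = [Atom(f"C{i+1}", "C", p) for i, p in enumerate(pts)]
    return _probe_ligand(atoms, aromatic_rings=[frozenset(range(6))])


def test_face_to_face_stack_detected():
    prot = _phe_residue((0, 0, 0), (1, 0, 0), (0, 1, 0))
    lig = _ring_ligand((0, 0, 3.5), (1, 0, 0), (0, 1, 0))
    fp = d.fingerprint_frame(_conf([prot]), lig, lig.coords())
    assert fp.aromatic_stack[0]


def test_offset_sixty_degrees_not_stacked():
    prot = _phe_residue((0, 0, 0), (1, 0, 0), (0, 1, 0))
    offset = 3.5 * np.array([np.sin(np.radians(60)), 0.0, np.cos(np.radians(60))])
    lig = _ring_ligand(offset, (1, 0, 0), (0, 1, 0))
    fp = d.fingerprint_frame(_conf([prot]), lig, lig.coords())
    assert not fp.aromatic_stack[0]


def test_stack_angle_folding_handles_normal_sign():
    """Flipping the ligand ring's atom order (reversing its normal) must not
    change the classification."""
    prot = _phe_residue((0, 0, 0), (1, 0, 0), (0, 1, 0))
    lig = _ring_ligand((0, 0, 3.5), (0, 1, 0), (1, 0, 0))  # swapped basis
    fp = d.fingerprint_frame(_conf([prot]), lig, lig.coords())
    assert fp.aromatic_stack[0]


def test_ring_geometry_normal_is_unit_and_perpendicular():
    pts = np.array(_hexagon((1, 2, 3), (1, 0, 0), (0, 0.6, 0.8)))
    geo = ring_geometry(pts)
    np.testing.assert_allclose(np.linalg.norm(geo.normal), 1.0)
    for p in pts:
        assert abs(np.dot(p - geo.centroid, geo.normal)) < 1e-9


# --- hydrophobic contacts ---------------------------------------------------


def test_hydrophobic_excludes_calpha():
    res_ca_only = _residue([Atom("CA", "C", (0, 0, 0))], name="GLY")
    lig = _probe_ligand([Atom("C1", "C", (3.0, 0, 0))])
    fp = d.fingerprint_frame(_conf([res_ca_only]), lig, lig.coords())
    assert not fp.hydrophobic[0]
    res_with_cb = _residue([Atom("CA", "C", (0, 0, 0)), Atom("CB", "C", (1.5, 0, 0))],
                           name="ALA")
    fp2 = d.fingerprint_frame(_conf([res_with_cb]), lig, lig.coords())
    assert fp2.hydrophobic[0]


def test_contact_flag_is_independent_of_specific_classes():
    """A residue within 6 Å registers a contact even with no specific class."""
    res = _residue([Atom("CA", "C", (0, 0, 0))], name="GLY")
    lig = _probe_ligand([Atom("C1", "C", (5.9, 0, 0))])
    fp = d.fingerprint_frame(_conf([res]), lig, lig.coords())
    assert fp.contact[0] and not fp.hydrophobic[0]
    assert fp.contacted_residues == frozenset({1})


def test_rigid_motion_invariance_of_all_classes(peptide_ensemble, ring_ligand):
    from scipy.spatial.transform import Rotation

    conf = peptide_ensemble.conformations[0]
    bound = d.plant_bound_poses(peptide_ensemble.subset([conf.frame_id]), ring_ligand,
                                np.eye(conf.n_residues)[2], seed=5)
    pose = bound.ligand_coords[0]
    fp1 = d.fingerprint_frame(conf, ring_ligand, pose)
    rot = Rotation.random(random_state=3).as_matrix()
    shift = np.array([7.0, -2.0, 4.0])
    moved_residues = []
    for r in conf.residues:
        atoms = [Atom(a.name, a.element, rot @ a.coords + shift, a.formal_charge)
                 for a in r.atoms]
        moved_residues.append(Residue(r.index, r.pdb_number, r.name, atoms))
    moved_conf = ProteinConformation(moved_residues, frame_id=1)
    fp2 = d.fingerprint_frame(moved_conf, ring_ligand, pose @ rot.T + shift)
    for cls in ("contact", "hydrophobic", "aromatic_stack", "charge", "hbond"):
        np.testing.assert_array_equal(fp1.flags(cls), fp2.flags(cls))


def test_enlarging_cutoffs_never_decreases_populations(peptide_ensemble, ring_ligand):
    probs = np.full(10, 0.08)
    bound = d.plant_bound_poses(peptide_ensemble, ring_ligand, probs, seed=8)
    tight = d.InteractionCriteria()
    loose = d.InteractionCriteria(contact_cutoff=8.0, hydrophobic_cutoff=7.0,
                                  charge_cutoff=7.0, hbond_ha_cutoff=4.5,
                                  stack_centroid_cutoff=7.0)
    p_tight = d.aggregate_profiles(d.fingerprint_bound_ensemble(bound, tight))
    p_loose = d.aggregate_profiles(d.fingerprint_bound_ensemble(bound, loose))
    for cls in ("contact", "hydrophobic", "charge", "hbond", "aromatic_stack"):
        assert np.all(p_loose.populations[cls] >= p_tight.populations[cls])


# --- neighbor search oracle -------------------------------------------------


def test_pairs_within_equals_all_pairs_double_loop():
    rng = np.random.default_rng(19)
    for _ in range(120):
        a = rng.uniform(-5, 5, size=(rng.integers(0, 12), 3))
        b = rng.uniform(-5, 5, size=(rng.integers(0, 12), 3))
        cutoff = float(rng.uniform(1.0, 6.0))
        got = {tuple(p) for p in pairs_within(a, b, cutoff)}
        expected = {
            (i, j)
            for i in range(a.shape[0])
            for j in range(b.shape[0])
            if np.linalg.norm(a[i] - b[j]) <= cutoff
        }
        assert got == expected


# --- aggregation ------------------------------------------------------------


def _fp(contacts, n_res=5, frame_id=1, hbond=None):
    z = np.zeros(n_res, dtype=bool)
    c = z.copy()
    c[list(contacts)] = True
    h = z.copy()
    if hbond:
        h[list(hbond)] = True
    return FrameFingerprint(contact=c, hydrophobic=z.copy(), aromatic_stack=z.copy(),
                            charge=z.copy(), hbond=h, frame_id=frame_id)


def test_aggregate_population_fraction():
    fps = [_fp([0], hbond=[2]), _fp([0, 1])]
    prof = d.aggregate_profiles(fps)
    assert prof.populations["hbond"][2] == pytest.approx(0.5)
    assert prof.populations["contact"][0] == pytest.approx(1.0)
    assert prof.populations["contact"][1] == pytest.approx(0.5)


def test_all_false_fingerprints_zero_profile():
    prof = d.aggregate_profiles([_fp([]), _fp([])])
    for cls, pops in prof.populations.items():
        assert np.all(pops == 0)


def test_single_frame_dual_contact_matrix():
    dm = d.dual_contact_matrix([_fp([2, 4], n_res=6)])
    m = dm.matrix
    for i, j in [(2, 2), (4, 4), (2, 4), (4, 2)]:
        assert m[i, j] == 1.0
    assert m.sum() == 4.0


def test_dual_contact_matrix_invariants_on_random_fingerprints():
    rng = np.random.default_rng(2)
    fps = [FrameFingerprint(contact=rng.random(8) < 0.4,
                            hydrophobic=np.zeros(8, bool),
                            aromatic_stack=np.zeros(8, bool),
                            charge=np.zeros(8, bool), hbond=np.zeros(8, bool))
           for _ in range(300)]
    dm = d.dual_contact_matrix(fps)
    m = dm.matrix
    np.testing.assert_allclose(m, m.T)
    counts = np.array([fp.contact for fp in fps], dtype=float)
    np.testing.assert_allclose(np.diag(m), counts.mean(axis=0))
    for i in range(8):
        for j in range(8):
            assert m[i, j] <= min(m[i, i], m[j, j]) + 1e-12


def test_independent_contacts_product_law():
    """Residues contacted independently with p=0.5 give off-diagonal ≈ 0.25."""
    rng = np.random.default_rng(4)
    n = 4000
    fps = [FrameFingerprint(contact=rng.random(4) < 0.5,
                            hydrophobic=np.zeros(4, bool),
                            aromatic_stack=np.zeros(4, bool),
                            charge=np.zeros(4, bool), hbond=np.zeros(4, bool))
           for _ in range(n)]
    m = d.dual_contact_matrix(fps).matrix
    se = 3 * np.sqrt(0.25 * 0.75 / n)
    off = m[~np.eye(4, dtype=bool)]
    assert np.all(np.abs(off - 0.25) < se + 0.01)


# --- profile comparison -----------------------------------------------------


def test_compare_identical_profiles():
    a = np.array([0.1, 0.5, 0.9])
    stats = d.compare_profiles(a, a.copy())
    assert stats.pearson_r == pytest.approx(1.0)
    assert stats.rmse == 0.0


def test_compare_affine_reversal():
    a = np.array([0.1, 0.5, 0.9])
    stats = d.compare_profiles(a, 1.0 - a)
    assert stats.pearson_r == pytest.approx(-1.0)


def test_compare_matches_direct_formulas():
    a = np.array([1.0, 2.0, 4.0, 3.0])
    b = np.array([0.5, 2.5, 3.5, 2.0])
    stats = d.compare_profiles(a, b)
    am, bm = a.mean(), b.mean()
    r = np.sum((a - am) * (b - bm)) / np.sqrt(np.sum((a - am) ** 2) * np.sum((b - bm) ** 2))
    assert stats.pearson_r == pytest.approx(r, abs=1e-12)
    assert stats.rmse == pytest.approx(np.sqrt(np.mean((a - b) ** 2)), abs=1e-12)


def test_compare_matrices_upper_triangle_and_diagonal():
    m1 = np.array([[1.0, 0.5], [0.5, 0.8]])
    m2 = np.array([[0.9, 0.4], [0.4, 0.7]])
    stats = d.compare_profiles(m1, m2)
    vals1, vals2 = np.array([1.0, 0.5, 0.8]), np.array([0.9, 0.4, 0.7])
    assert stats.rmse == pytest.approx(np.sqrt(np.mean((vals1 - vals2) ** 2)))


def test_zero_variance_reports_missing_r():
    with pytest.warns(UserWarning):
        stats = d.compare_profiles(np.ones(4), np.array([1.0, 2.0, 3.0, 4.0]))
    assert stats.pearson_r is None
    assert stats.rmse > 0
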