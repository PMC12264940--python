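"""Mock grid backend vs an independent brute-force oracle; engine adapter."""

import math

import numpy as np
import pytest

import idpdock as d
from idpdock.backends import (
    BackendError,
    BackendUnavailableError,
    GridEngineAdapter,
    parse_vina_poses,
    parse_vina_scores,
)
from idpdock.core import Atom, LigandModel, ProteinConformation, Residue

from conftest import make_conformation


def brute_force_grid_dock(protein_heavy, ligand_coords, ligand_heavy_mask, box, spacing):
    """Plain-Python enumeration of every grid placement and its pair score."""
    n = math.floor(box.edge / spacing)
    assert n >= 1
    offs = [(i - (n - 1) / 2.0) * spacing for i in range(n)]
    centroid = np.mean(ligand_coords, axis=0)
    rel = ligand_coords - centroid
    results = []
    flat = 0
    for ox in offs:
        for oy in offs:
            for oz in offs:
                point = box.center + np.array([ox, oy, oz])
                score = 0.0
                for rl, heavy in zip(rel, ligand_heavy_mask):
                    if not heavy:
                        continue
                    for p in protein_heavy:
                        dd = float(np.linalg.norm(point + rl - p))
                        if dd > 8.0:
                            continue
                        score += 1000.0 if dd < 2.0 else -math.exp(-((dd - 3.5) ** 2) / 2.0)
                results.append((flat, score, point))
                flat += 1
    results.sort(key=lambda t: (t[1], t[0]))
    return results


def _random_request(rng):
    n_prot = rng.integers(1, 4)
    prot = rng.uniform(-4, 4, size=(n_prot, 3))
    conf = make_conformation(prot, frame_id=1)
    n_lig = rng.integers(1, 3)
    lig = LigandModel([Atom(f"C{i}", "C", c)
                       for i, c in enumerate(rng.uniform(-1, 1, size=(n_lig, 3)))])
    box = d.SearchBox(center=rng.uniform(-2, 2, size=3), edge=float(rng.uniform(2.0, 4.0)))
    spacing = float(rng.uniform(0.8, 1.5))
    return conf, lig, box, spacing


def test_mock_grid_equals_brute_force_enumeration():
    """Backend output must exactly equal independent enumeration of every
    grid point, including score ordering and tie-breaking."""
    rng = np.random.default_rng(17)
    for _ in range(120):
        conf, lig, box, spacing = _random_request(rng)
        n = math.floor(box.edge / spacing)
        req = d.DockRequest(conf, lig, box=box, n_poses=n ** 3)
        got = d.mock_grid_dock(req, spacing=spacing)
        expected = brute_force_grid_dock(conf.heavy_coords(), lig.coords(),
                                         [a.is_heavy for a in lig.atoms], box, spacing)
        assert len(got) == len(expected)
        centroid = lig.coords().mean(axis=0)
        for (pose, score), (_, exp_score, exp_point) in zip(got, expected):
            assert score == pytest.approx(exp_score, abs=1e-9)
            np.testing.assert_allclose(pose.ligand_coords.mean(axis=0), exp_point, atol=1e-9)


def test_empty_protein_returns_first_grid_point_all_zero():
    conf = make_conformation([(100.0, 100.0, 100.0)])  # far outside 8 Å of the box
    lig = LigandModel([Atom("C1", "C", (0, 0, 0))])
    box = d.SearchBox(center=np.zeros(3), edge=3.0)
    req = d.DockRequest(conf, lig, box=box, n_poses=27)
    results = d.mock_grid_dock(req, spacing=1.0)
    assert all(s == 0.0 for _, s in results)
    np.testing.assert_allclose(results[0][0].ligand_coords[0], [-1.0, -1.0, -1.0])


def test_single_atom_optimum_near_well_distance():
    """With one protein atom and a one-atom ligand, the selected grid point is
    the feasible point whose distance to the atom is closest to 3.5 Å."""
    conf = make_conformation([(0.0, 0.0, 0.0)])
    lig = LigandModel([Atom("C1", "C", (0, 0, 0))])
    box = d.SearchBox(center=np.array([2.0, 0.0, 0.0]), edge=5.0)
    req = d.DockRequest(conf, lig, box=box, n_poses=1)
    spacing = 0.5
    (pose, score), = d.mock_grid_dock(req, spacing=spacing)
    expected = brute_force_grid_dock(conf.heavy_coords(), lig.coords(), [True], box, spacing)
    best = min((e for e in expected if e[1] < 1000), key=lambda t: (t[1], t[0]))
    np.testing.assert_allclose(pose.ligand_coords[0], best[2], atol=1e-9)
    dist = np.linalg.norm(pose.ligand_coords[0])
    feasible = [np.linalg.norm(p) for _, s, p in expected if s < 1000]
    assert abs(dist - 3.5) == pytest.approx(min(abs(f - 3.5) for f in feasible), abs=1e-9)


def test_translation_equivariance():
    rng = np.random.default_rng(23)
    conf, lig, box, spacing = _random_request(rng)
    shift = np.array([5.0, -3.0, 2.0])
    moved_conf = make_conformation(conf.coords() + shift, frame_id=1)
    moved_box = d.SearchBox(center=box.center + shift, edge=box.edge)
    a = d.mock_grid_dock(d.DockRequest(conf, lig, box=box, n_poses=5), spacing=spacing)
    b = d.mock_grid_dock(d.DockRequest(moved_conf, lig, box=moved_box, n_poses=5),
                         spacing=spacing)
    for (pa, sa), (pb, sb) in zip(a, b):
        assert sa == pytest.approx(sb, abs=1e-9)
        np.testing.assert_allclose(pb.ligand_coords, pa.ligand_coords + shift, atol=1e-9)


def test_never_selects_clash_when_alternative_exists():
    rng = np.random.default_rng(31)
    for _ in range(50):
        conf, lig, box, spacing = _random_request(rng)
        req = d.DockRequest(conf, lig, box=box, n_poses=1)
        (pose, score), = d.mock_grid_dock(req, spacing=spacing)
        if score < 900.0:  # below any possible clash penalty
            prot = conf.heavy_coords()
            heavy = pose.ligand_coords[lig.heavy_indices()]
            dmin = np.linalg.norm(heavy[:, None] - prot[None], axis=-1).min()
            assert dmin >= 2.0


def test_empty_grid_errors():
    conf = make_conformation([(0, 0, 0)])
    lig = LigandModel([Atom("C1", "C", (0, 0, 0))])
    box = d.SearchBox(center=np.zeros(3), edge=0.5)
    with pytest.raises(BackendError):
        d.mock_grid_dock(d.DockRequest(conf, lig, box=box), spacing=1.0)


def test_determinism_same_request_same_output():
    rng = np.random.default_rng(5)
    conf, lig, box, spacing = _random_request(rng)
    req = d.DockRequest(conf, lig, box=box, n_poses=3, seed=9)
    a = d.mock_grid_dock(req, spacing=spacing)
    b = d.mock_grid_dock(req, spacing=spacing)
    for (pa, sa), (pb, sb) in zip(a, b):
        assert sa == sb
        np.testing.assert_array_equal(pa.ligand_coords, pb.ligand_coords)


# --- external adapter -------------------------------------------------------


def test_command_construction_golden_line():
    spec = d.BackendSpec(name="vina", polarity="lower_is_better", mode="boxed",
                         parameters={"binary": "vina", "exhaustiveness": 8})
    adapter = GridEngineAdapter(spec)
    box = d.SearchBox(center=np.array([1.0, 2.0, 3.0]), edge=10.0)
    cmd = adapter.build_command("rec.pdbqt", "lig.pdbqt", "out.pdbqt", box,
                                n_poses=9, seed=42)
    assert cmd == [
        "vina", "--receptor", "rec.pdbqt", "--ligand", "lig.pdbqt", "--out",
        "out.pdbqt", "--center_x", "1.000", "--center_y", "2.000", "--center_z",
        "3.000", "--size_x", "10.000", "--size_y", "10.000", "--size_z", "10.000",
        "--num_modes", "9", "--seed", "42", "--exhaustiveness", "8",
    ]


VINA_OUT = """REMARK VINA RESULT:    -7.2      0.000      0.000
ATOM      1  C1  LIG B   1       1.000   2.000   3.000  1.00  0.00     0.000 C
ENDMDL
REMARK VINA RESULT:    -6.1      1.200      2.100
ATOM      1  C1  LIG B   1       2.000   3.000   4.000  1.00  0.00     0.000 C
ENDMDL
"""


def test_parse_engine_output_fixture():
    lig = LigandModel([Atom("C1", "C", (0, 0, 0))])
    poses = parse_vina_poses(VINA_OUT, lig)
    assert [s for _, s in poses] == [-7.2, -6.1]
    assert sorted(s for _, s in poses) == [s for _, s in poses]  # monotone
    np.testing.assert_allclose(poses[0][0].ligand_coords, [[1.0, 2.0, 3.0]])
    assert parse_vina_scores(VINA_OUT) == [-7.2, -6.1]


def test_missing_binary_is_structured_error(tmp_path, probe_ligand):
    spec = d.BackendSpec(name="definitely-not-a-dock-engine",
                         polarity="lower_is_better", mode="boxed")
    adapter = GridEngineAdapter(spec)
    conf = make_conformation([(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)])
    box = d.SearchBox(center=np.zeros(3), edge=5.0)
    with pytest.raises(BackendUnavailableError):
        adapter.dock(d.DockRequest(conf, probe_ligand, box=box), workdir=tmp_path)
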