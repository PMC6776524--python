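"""Topology/trajectory I/O, re-imaging, superposition and RMSD."""

import numpy as np
import pytest

import piezomd as pm
from piezomd.core import TrajectoryError, kabsch_rotation
from piezomd.pdbio import PDBParseError

TOY_PDB = """\
CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.000   2.000   3.000  1.00  0.00           C
ATOM      3  C   ALA A   1       3.000   2.000   3.000  1.00  0.00           C
ATOM      4  CA  GLY A   2       4.000   2.000   3.000  1.00  0.00           C
TER       5      GLY A   2
ATOM      6  CA  SER B   3       8.000   2.000   3.000  1.00  0.00           C
END
"""


@pytest.fixture
def toy_top(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return pm.load_topology(str(p))


def _random_traj(seed=0, n_atoms=12, n_frames=4, box=50.0):
    rng = np.random.default_rng(seed)
    rows = [("CA", "C", i + 1, "ALA", "A", i) for i in range(n_atoms)]
    names, elements, resids, resnames, chains, mols = zip(*rows)
    top = pm.Topology(np.array(names, dtype=object), np.array(elements, dtype=object),
                      np.array(resids), np.array(resnames, dtype=object),
                      np.array(chains, dtype=object), np.array(mols))
    coords = rng.uniform(5, box - 5, (n_frames, n_atoms, 3))
    return pm.Trajectory(top, coords, np.full((n_frames, 3), box),
                         np.arange(n_frames) * 1.2)


class TestLoadTopology:
    def test_two_chains_two_molecules(self, toy_top):
        assert toy_top.n_atoms == 5
        assert len(toy_top.molecules()) == 2

    def test_duplicate_serials_reindexed_with_warning(self, tmp_path):
        text = TOY_PDB.replace("ATOM      2", "ATOM      1")
        p = tmp_path / "dup.pdb"
        p.write_text(text)
        with pytest.warns(UserWarning, match="duplicate"):
            top = pm.load_topology(str(p))
        assert top.n_atoms == 5

    def test_malformed_record_names_line(self, tmp_path):
        bad = TOY_PDB.replace("   2.000   2.000   3.000", "   x.yyy   2.000   3.000")
        p = tmp_path / "bad.pdb"
        p.write_text(bad)
        with pytest.raises(PDBParseError, match="line 3"):
            pm.load_topology(str(p))

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(ValueError):
            pm.load_topology(str(p))


class TestSelections:
    def test_resid_range_matches_brute_force(self):
        resids = np.arange(1950, 2101)
        n = len(resids)
        top = pm.Topology(np.array(["CA"] * n, dtype=object),
                          np.array(["C"] * n, dtype=object), resids,
                          np.array(["ALA"] * n, dtype=object),
                          np.array(["A"] * n, dtype=object), np.arange(n))
        got = top.select("resid 1961-2063")
        expected = [i for i in range(n) if 1961 <= resids[i] <= 2063]
        assert got.tolist() == expected

    def test_boolean_combinations(self, toy_top):
        assert toy_top.select("name CA and chain A").tolist() == [1, 3]
        assert toy_top.select("backbone").tolist() == [0, 1, 2, 3, 4]
        assert toy_top.select("not element N").tolist() == [1, 2, 3, 4]
        assert toy_top.select("(resid 1 or resid 3) and name CA").tolist() == [1, 4]


class TestLoadTrajectory:
    def test_multi_model_pdb_frame_count(self, tmp_path):
        traj = _random_traj(n_frames=5)
        path = tmp_path / "t.pdb"
        pm.write_trajectory(traj, str(path))
        top = pm.load_topology(str(path))
        loaded = pm.load_trajectory(str(path), top)
        assert loaded.n_frames == 5

    def test_pdb_roundtrip_coordinates(self, tmp_path):
        traj = _random_traj()
        path = tmp_path / "rt.pdb"
        pm.write_trajectory(traj, str(path))
        loaded = pm.load_trajectory(str(path), traj.topology)
        np.testing.assert_allclose(loaded.coords, traj.coords, atol=1.1e-3)
        np.testing.assert_allclose(loaded.box, traj.box)

    def test_dcd_xtc_cross_format_agreement(self, tmp_path):
        traj = _random_traj(seed=3)
        dcd, xtc = tmp_path / "t.dcd", tmp_path / "t.xtc"
        pm.write_trajectory(traj, str(dcd))
        pm.write_trajectory(traj, str(xtc))
        a = pm.load_trajectory(str(dcd), traj.topology)
        b = pm.load_trajectory(str(xtc), traj.topology)
        assert np.max(np.abs(a.coords - b.coords)) < 1e-2
        np.testing.assert_allclose(a.coords, traj.coords, atol=1e-2)

    def test_atom_count_mismatch_reports_both_counts(self, tmp_path):
        traj = _random_traj(n_atoms=12)
        path = tmp_path / "t.pdb"
        pm.write_trajectory(traj, str(path))
        small = _random_traj(n_atoms=7).topology
        with pytest.raises(TrajectoryError, match="12.*7|7.*12"):
            pm.load_trajectory(str(path), small)

    def test_default_times_follow_output_interval(self, tmp_path):
        traj = _random_traj(n_frames=3)
        path = tmp_path / "t.pdb"
        pm.write_trajectory(traj, str(path))
        loaded = pm.load_trajectory(str(path), traj.topology)
        np.testing.assert_allclose(loaded.times, [0.0, 1.2, 2.4])


class TestReimage:
    def test_displaced_molecule_translated_back(self):
        traj = _random_traj(seed=1)
        traj.coords = 20.0 + 10.0 * (traj.coords - 5.0) / 40.0  # keep compact
        shifted = traj.copy()
        mol = traj.topology.molecules()[3]
        shifted.coords[:, mol, 0] += traj.box[0, 0]
        out = pm.reimage_to_anchor(shifted, np.array([0]))
        np.testing.assert_allclose(out.coords, traj.coords, atol=1e-9)

    def test_contiguous_system_unchanged(self):
        traj = _random_traj(seed=2, box=200.0)
        traj.coords = 75.0 + (traj.coords - 5.0) / 190.0 * 50.0  # all within 50 Å
        out = pm.reimage_to_anchor(traj, np.array([0]))
        np.testing.assert_allclose(out.coords, traj.coords)

    def test_scatter_within_half_box_vs_brute_force(self):
        rng = np.random.default_rng(7)
        traj = _random_traj(seed=4, n_atoms=10, n_frames=1, box=30.0)
        traj.coords[0] += rng.integers(-3, 4, (10, 3)) * 30.0
        out = pm.reimage_to_anchor(traj, np.array([0]))
        L = traj.box[0]
        anchor = out.coords[0, 0]
        # brute force: the chosen image must be the best of all 27 neighbors
        for i in range(10):
            assert np.all(np.abs(out.coords[0, i] - anchor) <= L / 2 + 1e-9)
            best = min(np.max(np.abs(out.coords[0, i] + np.array([ix, iy, iz]) * L - anchor))
                       for ix in (-1, 0, 1) for iy in (-1, 0, 1) for iz in (-1, 0, 1))
            assert np.max(np.abs(out.coords[0, i] - anchor)) <= best + 1e-9

    def test_intramolecular_distances_preserved(self):
        traj = _random_traj(seed=5)
        top = traj.topology
        top.molecule_ids[:] = np.repeat(np.arange(4), 3)  # 4 triatomic molecules
        shifted = traj.copy()
        shifted.coords[:, :3, 1] += traj.box[0, 1] * 2
        out = pm.reimage_to_anchor(shifted, np.array([11]))
        for mol in top.molecules():
            d0 = np.linalg.norm(traj.coords[0, mol[0]] - traj.coords[0, mol[1]])
            d1 = np.linalg.norm(out.coords[0, mol[0]] - out.coords[0, mol[1]])
            assert d0 == pytest.approx(d1, abs=1e-12)

    def test_empty_anchor_errors(self):
        with pytest.raises(TrajectoryError, match="anchor"):
            pm.reimage_to_anchor(_random_traj(), np.array([], dtype=int))


class TestSuperpose:
    def test_pure_translation_removed(self):
        traj = _random_traj(seed=6, n_frames=2)
        traj.coords[1] = traj.coords[0] + np.array([5.0, 5.0, 5.0])
        out = pm.superpose_frames(traj, 0, "all")
        np.testing.assert_allclose(out.coords[1], out.coords[0], atol=1e-9)

    def test_pure_rotation_removed(self):
        traj = _random_traj(seed=7, n_frames=2)
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        traj.coords[1] = traj.coords[0] @ Rz.T
        out = pm.superpose_frames(traj, 0, "all")
        np.testing.assert_allclose(out.coords[1], out.coords[0], atol=1e-8)

    def test_collinear_selection_errors(self):
        traj = _random_traj(seed=8)
        traj.coords[:, :4] = np.arange(4)[None, :, None] * np.array([1.0, 0, 0])
        with pytest.raises(TrajectoryError, match="collinear"):
            pm.superpose_frames(traj, 0, np.arange(4))

    def test_never_increases_selection_rmsd(self):
        traj = _random_traj(seed=9, n_frames=6)
        sel = np.arange(12)
        out = pm.superpose_frames(traj, 0, sel)
        for f in range(6):
            before = np.sqrt(np.mean(np.sum((traj.coords[f] - traj.coords[0]) ** 2, 1)))
            after = np.sqrt(np.mean(np.sum((out.coords[f] - out.coords[0]) ** 2, 1)))
            assert after <= before + 1e-9

    def test_no_reflection(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=(10, 3))
        mirrored = a * np.array([1.0, 1.0, -1.0])
        R, _ = kabsch_rotation(mirrored, a)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


class TestRmsdSeries:
    def test_reference_frame_is_zero(self):
        series = pm.rmsd_series(_random_traj(seed=11), 0, "all")
        assert series.rmsd_A[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(series.rmsd_A >= 0)

    def test_two_atom_closed_form(self):
        """Two collinear segments of lengths L and L+2 superpose with each
        atom off by half the length difference → RMSD exactly 1 Å."""
        rows = [("CA", "C", 1, "ALA", "A", 0), ("CA", "C", 2, "ALA", "A", 1)]
        names, elements, resids, resnames, chains, mols = zip(*rows)
        top = pm.Topology(np.array(names, dtype=object), np.array(elements, dtype=object),
                          np.array(resids), np.array(resnames, dtype=object),
                          np.array(chains, dtype=object), np.array(mols))
        coords = np.array([[[0.0, 0, 0], [4.0, 0, 0]],
                           [[0.0, 0, 0], [6.0, 0, 0]]])
        traj = pm.Trajectory(top, coords, np.full((2, 3), 50.0), np.array([0.0, 1.2]))
        series = pm.rmsd_series(traj, 0, "all")
        assert series.rmsd_A[1] == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_global_rigid_motion(self):
        traj = _random_traj(seed=12, n_frames=5)
        base = pm.rmsd_series(traj, 0, "all").rmsd_A
        Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = traj.copy()
        moved.coords = traj.coords @ Rz.T + np.array([3.0, -2.0, 7.0])
        np.testing.assert_allclose(pm.rmsd_series(moved, 0, "all").rmsd_A, base,
                                   atol=1e-9)

    def test_growing_tilt_has_growing_rmsd(self):
        traj, _ = pm.make_arm_tilt_trajectory(pm.ArmSpec(seed=0, n_frames=40))
        series = pm.rmsd_series(traj, 0, "name CA")
        # monotone envelope: every later quarter exceeds the previous one
        q = np.array_split(series.rmsd_A, 4)
        means = [x.mean() for x in q]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_csv_output_columns(self, tmp_path):
        series = pm.rmsd_series(_random_traj(seed=13), 0, "all")
        path = tmp_path / "rmsd.csv"
        series.to_csv(str(path))
        header = path.read_text().splitlines()[0]
        assert header == "time_ns,rmsd_A,selection,reference_frame"


def test_trajectory_invariant_validation():
    traj = _random_traj()
    with pytest.raises(TrajectoryError, match="increasing"):
        pm.Trajectory(traj.topology, traj.coords, traj.box,
                      np.zeros(traj.n_frames))
    with pytest.raises(TrajectoryError, match="positive"):
        pm.Trajectory(traj.topology, traj.coords, -traj.box, traj.times)
    with pytest.raises(TrajectoryError, match="atom count"):
        pm.Trajectory(traj.topology, traj.coords[:, :5], traj.box, traj.times)
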