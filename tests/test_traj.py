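"""Conformation metrics: closed-form cases, invariances, oracle equivalence."""

import numpy as np
import pytest

from aptaselex.traj import (
    Trajectory,
    radius_of_gyration,
    rg_series,
    rmsd,
    rmsd_series,
    rmsf,
    read_trajectory,
)

TOL = 1e-9


def _rotation_z(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _toy_trajectory(rng, n_frames=6, n_atoms=5):
    frames = np.cumsum(rng.normal(size=(n_frames, n_atoms, 3)), axis=0)
    masses = rng.uniform(1.0, 16.0, n_atoms)
    return Trajectory(
        frames=frames,
        masses=masses,
        atom_labels=tuple(f"X{i}" for i in range(n_atoms)),
        residue_index=np.array([0, 0, 1, 1, 1][:n_atoms]),
    )


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert radius_of_gyration([[3.0, -2.0, 7.0]], [12.0]) == pytest.approx(0.0)

    def test_two_unit_masses_at_plus_minus_one(self):
        frame = [[1.0, 0, 0], [-1.0, 0, 0]]
        assert radius_of_gyration(frame, [1.0, 1.0]) == pytest.approx(1.0, abs=TOL)

    def test_four_corner_atoms(self):
        frame = [[0.5, 0.5, 0], [0.5, -0.5, 0], [-0.5, 0.5, 0], [-0.5, -0.5, 0]]
        assert radius_of_gyration(frame, np.ones(4)) == pytest.approx(
            np.sqrt(0.5), abs=TOL
        )

    def test_zero_atoms_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            radius_of_gyration(np.empty((0, 3)), np.empty(0))

    def test_rigid_invariance_and_linear_scaling(self, rng):
        frame = rng.normal(size=(8, 3))
        masses = rng.uniform(1, 20, 8)
        base = radius_of_gyration(frame, masses)
        moved = frame @ _rotation_z(0.7).T + np.array([5.0, -3.0, 2.0])
        assert radius_of_gyration(moved, masses) == pytest.approx(base, abs=TOL)
        assert radius_of_gyration(3.5 * frame, masses) == pytest.approx(
            3.5 * base, abs=TOL
        )


class TestRmsd:
    def test_identical_frames_zero(self, rng):
        frame = rng.normal(size=(6, 3))
        assert rmsd(frame, frame, superpose=False) == pytest.approx(0.0, abs=TOL)
        assert rmsd(frame, frame, superpose=True) == pytest.approx(0.0, abs=TOL)

    def test_uniform_translation(self, rng):
        frame = rng.normal(size=(6, 3))
        shifted = frame + 1.0
        assert rmsd(frame, shifted, superpose=False) == pytest.approx(
            np.sqrt(3.0), abs=TOL
        )
        assert rmsd(frame, shifted, superpose=True) == pytest.approx(0.0, abs=1e-7)

    def test_rigid_rotation_removed_by_superposition(self, rng):
        frame = rng.normal(size=(7, 3))
        rotated = frame @ _rotation_z(np.pi / 2).T
        assert rmsd(frame, rotated, superpose=True) == pytest.approx(0.0, abs=1e-7)
        assert rmsd(frame, rotated, superpose=False) > 0.1

    def test_superposition_never_increases_rmsd_and_is_symmetric(self, rng):
        for _ in range(5):
            a = rng.normal(size=(9, 3))
            b = rng.normal(size=(9, 3))
            m = rng.uniform(1, 10, 9)
            fitted = rmsd(a, b, superpose=True, masses=m)
            raw = rmsd(a, b, superpose=False, masses=m)
            assert fitted <= raw + TOL
            assert fitted == pytest.approx(
                rmsd(b, a, superpose=True, masses=m), abs=1e-7
            )

    def test_matches_independent_mdanalysis_result(self, rng):
        from MDAnalysis.analysis import rms

        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        ours = rmsd(a, b, superpose=True)
        theirs = rms.rmsd(a, b, center=True, superposition=True)
        assert ours == pytest.approx(theirs, abs=1e-8)

    def test_atom_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            rmsd(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestRmsf:
    def test_static_trajectory_all_zero(self, rng):
        frame = rng.normal(size=(5, 3))
        traj = Trajectory(
            frames=np.repeat(frame[None], 4, axis=0),
            masses=np.ones(5),
            atom_labels=tuple("ABCDE"),
            residue_index=np.zeros(5, dtype=int),
        )
        np.testing.assert_allclose(rmsf(traj), np.zeros(5), atol=TOL)

    def test_single_oscillating_atom_without_superposition(self):
        a = 0.75
        base = np.array(
            [[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]], dtype=float
        )
        frames = []
        for sign in (1, -1, 1, -1):
            f = base.copy()
            f[0, 0] += sign * a
            frames.append(f)
        traj = Trajectory(
            frames=np.array(frames),
            masses=np.ones(4),
            atom_labels=("a", "b", "c", "d"),
            residue_index=np.arange(4),
        )
        vals = rmsf(traj, superpose=False)
        assert vals[0] == pytest.approx(a, abs=TOL)
        np.testing.assert_allclose(vals[1:], 0.0, atol=TOL)

    def test_matches_brute_force_definition(self, rng):
        traj = _toy_trajectory(rng)
        vals = rmsf(traj, superpose=False)
        # literal evaluation of the definition, frame by frame
        mean = traj.frames.mean(axis=0)
        expected = []
        for i in range(traj.n_atoms):
            acc = 0.0
            for t in range(traj.n_frames):
                acc += np.sum((traj.frames[t, i] - mean[i]) ** 2)
            expected.append(np.sqrt(acc / traj.n_frames))
        np.testing.assert_allclose(vals, expected, atol=TOL)

    def test_bounded_by_max_pairwise_displacement(self, rng):
        traj = _toy_trajectory(rng, n_frames=8)
        vals = rmsf(traj, superpose=False)
        for i in range(traj.n_atoms):
            coords = traj.frames[:, i, :]
            diffs = coords[:, None, :] - coords[None, :, :]
            max_disp = np.sqrt((diffs**2).sum(axis=2)).max()
            assert vals[i] <= max_disp + TOL

    def test_superposed_rigid_motion_gives_zero(self, rng):
        base = rng.normal(size=(6, 3))
        frames = [base]
        for theta in (0.3, 1.1, 2.0):
            frames.append(base @ _rotation_z(theta).T + theta)
        traj = Trajectory(
            frames=np.array(frames),
            masses=rng.uniform(1, 10, 6),
            atom_labels=tuple("abcdef"),
            residue_index=np.zeros(6, dtype=int),
        )
        np.testing.assert_allclose(rmsf(traj, superpose=True), 0.0, atol=1e-7)

    def test_residue_grouping_is_mass_weighted_mean(self, rng):
        traj = _toy_trajectory(rng)
        per_atom = rmsf(traj, superpose=False)
        grouped = rmsf(traj, group_by_residue=True, superpose=False)
        w = traj.masses
        expected0 = np.average(per_atom[:2], weights=w[:2])
        expected1 = np.average(per_atom[2:], weights=w[2:])
        np.testing.assert_allclose(grouped, [expected0, expected1], atol=TOL)

    def test_single_frame_rejected(self, rng):
        traj = Trajectory(
            frames=rng.normal(size=(1, 3, 3)),
            masses=np.ones(3),
            atom_labels=("a", "b", "c"),
            residue_index=np.zeros(3, dtype=int),
        )
        with pytest.raises(ValueError, match="two frames"):
            rmsf(traj)


def _pdb_atom(serial, name, resname, resseq, xyz, element):
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d} {name:<4s} {resname:<3s} A{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


class TestReaders:
    def test_multi_model_pdb(self, tmp_path, rng):
        coords = rng.normal(size=(3, 4, 3)).round(3)
        lines = []
        for m, frame in enumerate(coords, start=1):
            lines.append(f"MODEL     {m}")
            for i, xyz in enumerate(frame):
                element = ["C", "N", "O", "P"][i]
                lines.append(
                    _pdb_atom(i + 1, f"{element}{i+1}", "G", 1, xyz, element)
                )
            lines.append("ENDMDL")
        lines.append("END")
        path = tmp_path / "traj.pdb"
        path.write_text("\n".join(lines) + "\n")
        traj = read_trajectory(path)
        assert traj.n_frames == 3 and traj.n_atoms == 4
        np.testing.assert_allclose(traj.frames, coords, atol=1e-3)
        assert (traj.masses > 0).all()
        assert len(rg_series(traj)) == 3
        assert rmsd_series(traj)[0] == pytest.approx(0.0, abs=1e-7)

    def test_xyz_with_mass_override(self, tmp_path):
        text = (
            "2\nframe 0\nC 0.0 0.0 0.0\nO 1.0 0.0 0.0\n"
            "2\nframe 1\nC 0.0 0.0 0.0\nO 2.0 0.0 0.0\n"
        )
        path = tmp_path / "toy.xyz"
        path.write_text(text)
        traj = read_trajectory(path, mass_overrides={"O": 18.0})
        assert traj.n_frames == 2 and traj.n_atoms == 2
        assert traj.masses[1] == pytest.approx(18.0)
        assert traj.frames[1, 1, 0] == pytest.approx(2.0)
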