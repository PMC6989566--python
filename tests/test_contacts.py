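"""Minimum contact distances across trajectory frames."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from chirospec import (AtomSelection, FormatError, Trajectory, ValidationError,
                       conformer_split, min_distance_series, read_trajectory,
                       write_trajectory)


def make_traj(coords, elements=None, names=None):
    coords = np.asarray(coords, float)
    n = coords.shape[1]
    elements = elements or ("C",) * n
    names = names or tuple(f"C{i}" for i in range(n))
    times = np.arange(coords.shape[0], dtype=float)
    return Trajectory(coords, names, elements, times)


class TestMinDistanceSeries:
    def test_fixed_pair_constant_series(self):
        frame = [[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]]
        traj = make_traj([frame] * 4)
        s = min_distance_series(traj, AtomSelection("a", [0]),
                                AtomSelection("b", [1]))
        np.testing.assert_array_equal(s.min_distances, [5.0] * 4)
        assert s.mean == 5.0 and s.sd == 0.0
        assert all(p == (0, 1) for p in s.pair_ids)

    def test_minimum_dominates_duplicated_selection(self):
        frame = [[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [8.0, 0.0, 0.0]]
        traj = make_traj([frame] * 3)
        s = min_distance_series(traj, AtomSelection("a", [0]),
                                AtomSelection("b", [1, 2]))
        assert np.all(s.min_distances == 3.0)

    def test_matches_brute_force_all_pairs(self, rng):
        coords = rng.uniform(0.0, 30.0, (5, 40, 3))
        traj = make_traj(coords)
        a = AtomSelection("a", list(range(20)))
        b = AtomSelection("b", list(range(20, 40)))
        s = min_distance_series(traj, a, b)
        for k in range(5):
            brute = min(np.linalg.norm(coords[k, i] - coords[k, j])
                        for i in range(20) for j in range(20, 40))
            assert s.min_distances[k] == pytest.approx(brute, abs=0.0)

    def test_symmetric_under_selection_swap(self, rng):
        coords = rng.uniform(0.0, 20.0, (3, 10, 3))
        traj = make_traj(coords)
        a = AtomSelection("a", [0, 1, 2])
        b = AtomSelection("b", [5, 6, 7, 8])
        np.testing.assert_array_equal(
            min_distance_series(traj, a, b).min_distances,
            min_distance_series(traj, b, a).min_distances)

    def test_adding_atoms_never_increases_minimum(self, rng):
        coords = rng.uniform(0.0, 20.0, (4, 12, 3))
        traj = make_traj(coords)
        b = AtomSelection("b", [8, 9, 10, 11])
        small = min_distance_series(traj, AtomSelection("a", [0, 1]), b)
        big = min_distance_series(traj, AtomSelection("a", [0, 1, 2, 3]), b)
        assert np.all(big.min_distances <= small.min_distances)

    def test_invariant_under_rigid_motion(self, rng):
        coords = rng.uniform(0.0, 20.0, (6, 16, 3))
        traj = make_traj(coords)
        a = AtomSelection("a", list(range(8)))
        b = AtomSelection("b", list(range(8, 16)))
        base = min_distance_series(traj, a, b)
        rots = Rotation.random(6, rng=rng)
        shifts = rng.uniform(-50.0, 50.0, (6, 3))
        moved = np.stack([rots[k].apply(coords[k]) + shifts[k] for k in range(6)])
        out = min_distance_series(make_traj(moved), a, b)
        np.testing.assert_allclose(out.min_distances, base.min_distances,
                                   atol=1e-9)

    def test_overlapping_selections_rejected(self):
        traj = make_traj(np.zeros((1, 4, 3)) + np.arange(4)[None, :, None])
        with pytest.raises(ValidationError):
            min_distance_series(traj, AtomSelection("a", [0, 1]),
                                AtomSelection("b", [1, 2]))

    def test_hydrogens_excluded_by_default(self):
        # hydrogen of set b sits closer than any heavy atom
        frame = [[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [6.0, 0.0, 0.0]]
        traj = make_traj([frame], elements=("C", "H", "C"),
                         names=("C1", "HB2", "C3"))
        s = min_distance_series(traj, AtomSelection("a", [0]),
                                AtomSelection("b", [1, 2]))
        assert s.min_distances[0] == 6.0
        explicit = min_distance_series(
            traj, AtomSelection("a", [0]),
            AtomSelection("b", [1, 2], element_filter={"H"}))
        assert explicit.min_distances[0] == 2.0

    def test_unresolvable_atom_id_rejected(self):
        traj = make_traj(np.zeros((1, 3, 3)) + np.arange(3)[None, :, None])
        with pytest.raises(ValidationError):
            min_distance_series(traj, AtomSelection("a", [0]),
                                AtomSelection("b", [99]))

    def test_skip_frames_discards_equilibration(self):
        coords = np.zeros((4, 2, 3))
        coords[:, 1, 0] = [50.0, 5.0, 5.0, 5.0]     # first frame unequilibrated
        traj = make_traj(coords)
        s = min_distance_series(traj, AtomSelection("a", [0]),
                                AtomSelection("b", [1]), skip_frames=1)
        assert len(s) == 3 and s.mean == 5.0


class TestTrajectoryIO:
    @pytest.mark.parametrize("suffix,precision", [(".pdb", 1.5e-3), (".xyz", 1e-5)])
    def test_round_trip_preserves_coordinates(self, tmp_path, rng, suffix, precision):
        coords = rng.uniform(0.0, 50.0, (10, 7, 3))
        traj = make_traj(coords)
        path = tmp_path / f"traj{suffix}"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        assert back.n_frames == 10 and back.n_atoms == 7
        assert np.abs(back.coords - traj.coords).max() < precision
        assert back.elements == traj.elements

    def test_single_frame_pdb(self, tmp_path, rng):
        traj = make_traj(rng.uniform(0, 10, (1, 5, 3)))
        path = tmp_path / "one.pdb"
        write_trajectory(traj, path)
        assert read_trajectory(path).n_frames == 1

    def test_identical_xyz_frames(self, tmp_path, rng):
        frame = rng.uniform(0, 10, (1, 4, 3))
        traj = make_traj(np.repeat(frame, 3, axis=0))
        path = tmp_path / "same.xyz"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        assert back.n_frames == 3
        assert np.abs(back.coords[0] - back.coords[2]).max() == 0.0

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FormatError):
            read_trajectory(tmp_path / "nope.pdb")

    def test_zero_frames_rejected(self):
        with pytest.raises(ValidationError):
            Trajectory(np.empty((0, 3, 3)), ("C",) * 3, ("C",) * 3, np.empty(0))


class TestConformerSplit:
    def test_bimodal_partition(self):
        d = np.array([4.0, 4.1, 9.0, 9.2, 3.9, 8.8])
        traj = make_traj(np.stack([[[0, 0, 0], [x, 0, 0]] for x in d]))
        s = min_distance_series(traj, AtomSelection("a", [0]),
                                AtomSelection("b", [1]))
        split = conformer_split(s, 6.5)
        assert split.proximal.n_frames == 3 and split.distal.n_frames == 3
        assert split.proximal.occupancy == pytest.approx(0.5)
        assert split.proximal.mean == pytest.approx(4.0)
        assert not split.empty_subset

    def test_threshold_above_range_flags_empty_subset(self):
        traj = make_traj([[[0, 0, 0], [5.0, 0, 0]]] * 4)
        s = min_distance_series(traj, AtomSelection("a", [0]),
                                AtomSelection("b", [1]))
        split = conformer_split(s, 100.0)
        assert split.proximal.occupancy == 1.0
        assert split.distal.n_frames == 0 and split.distal.mean is None
        assert split.empty_subset

    def test_midpoint_threshold_splits_two_value_series(self):
        traj = make_traj([[[0, 0, 0], [3.0, 0, 0]], [[0, 0, 0], [9.0, 0, 0]]])
        s = min_distance_series(traj, AtomSelection("a", [0]),
                                AtomSelection("b", [1]))
        split = conformer_split(s, 6.0)
        assert split.proximal.n_frames == 1 and split.distal.n_frames == 1
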