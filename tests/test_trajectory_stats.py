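import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import _atom

from aptamd.fixtures import make_paired_helix, make_rigid_trajectory, random_rigid_transforms
from aptamd.interactions import InteractionConfig
from aptamd.model_io import Frame, Trajectory
from aptamd.trajectory_stats import (
    intramolecular_hbond_series,
    kabsch_superpose,
    radius_of_gyration,
    rg_series,
    rmsd_series,
    rmsf_profile,
)


def _plain_frame(xyz, index=0, resids=None):
    xyz = np.asarray(xyz, float)
    atoms = [
        _atom(i + 1, f"C{i+1}", "C", "RES", 1 if resids is None else resids[i], "A", p)
        for i, p in enumerate(xyz)
    ]
    return Frame(index, atoms, {
        "receptor": frozenset(range(len(atoms))), "ligand": frozenset(),
        "water": frozenset(), "ion": frozenset(),
    })


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert radius_of_gyration(_plain_frame([[1, 2, 3]])) == pytest.approx(0.0, abs=1e-12)

    def test_two_unit_masses_two_angstrom_apart(self):
        fr = _plain_frame([[0, 0, 0], [2, 0, 0]])
        assert radius_of_gyration(fr, mass_weighted=False) == pytest.approx(1.0)

    def test_unit_cube_corner_rg_is_sqrt3(self):
        corners = [[x, y, z] for x in (0, 2) for y in (0, 2) for z in (0, 2)]
        fr = _plain_frame(corners)
        assert radius_of_gyration(fr, mass_weighted=False) == pytest.approx(math.sqrt(3))

    def test_rigid_motion_invariance_and_linear_scaling(self):
        rng = np.random.default_rng(0)
        xyz = rng.normal(size=(12, 3))
        fr = _plain_frame(xyz)
        rot = Rotation.random(random_state=rng).as_matrix()
        moved = _plain_frame(xyz @ rot.T + [5, -3, 2])
        scaled = _plain_frame(3.0 * xyz)
        rg = radius_of_gyration(fr, mass_weighted=False)
        assert radius_of_gyration(moved, mass_weighted=False) == pytest.approx(rg, abs=1e-10)
        assert radius_of_gyration(scaled, mass_weighted=False) == pytest.approx(3 * rg, abs=1e-10)

    def test_mass_weighting_shifts_rg_toward_heavy_atoms(self):
        atoms = [
            _atom(1, "O1", "O", "RES", 1, "A", np.array([0.0, 0, 0])),
            _atom(2, "H1", "H", "RES", 1, "A", np.array([2.0, 0, 0])),
        ]
        fr = Frame(0, atoms, {"receptor": frozenset({0, 1}), "ligand": frozenset(),
                              "water": frozenset(), "ion": frozenset()})
        assert radius_of_gyration(fr, mass_weighted=True) < radius_of_gyration(fr, mass_weighted=False)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(_plain_frame([[0, 0, 0]]), selection=[])


class TestKabsch:
    def test_identical_sets_give_zero_and_identity(self):
        rng = np.random.default_rng(1)
        xyz = rng.normal(size=(6, 3))
        rot, trans, rmsd = kabsch_superpose(xyz, xyz)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)

    def test_translation_removed(self):
        rng = np.random.default_rng(2)
        xyz = rng.normal(size=(6, 3))
        _, _, rmsd = kabsch_superpose(xyz, xyz + [5.0, 0, 0])
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_matches_scipy_align_vectors_on_random_clouds(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(6, 3))
            _, _, rmsd = kabsch_superpose(a, b)
            # independent oracle: scipy quaternion-based optimal alignment
            ac = a - a.mean(axis=0)
            bc = b - b.mean(axis=0)
            rot, _ = Rotation.align_vectors(bc, ac)
            oracle = np.sqrt(((rot.apply(ac) - bc) ** 2).sum() / len(a))
            assert rmsd == pytest.approx(oracle, abs=1e-6)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        assert kabsch_superpose(a, b)[2] == pytest.approx(kabsch_superpose(b, a)[2], abs=1e-10)

    def test_degenerate_and_mismatched_inputs_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line + [0, 1.0, 0])
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRmsdSeries:
    def _random_base(self, n=10, seed=5):
        rng = np.random.default_rng(seed)
        return _plain_frame(rng.normal(scale=3.0, size=(n, 3))), rng

    def test_rigid_motion_copies_have_zero_rmsd(self):
        base, rng = self._random_base()
        traj = make_rigid_trajectory(base, random_rigid_transforms(5, rng))
        series = rmsd_series(traj, 0)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)

    def test_paired_mode_against_itself_is_zero(self):
        base, rng = self._random_base()
        traj = make_rigid_trajectory(base, random_rigid_transforms(4, rng))
        series = rmsd_series(traj, paired=traj)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-12)

    def test_single_displaced_atom_matches_hand_formula(self):
        base, _ = self._random_base(n=8)
        frames = []
        for i in range(3):
            xyz = base.coords.copy()
            if i == 2:
                xyz[0] += [1.7, 0, 0]
            frames.append(_plain_frame(xyz, index=i))
        traj = Trajectory(frames)
        series = rmsd_series(traj, 0, superpose=False)
        assert series.values[0] == pytest.approx(0.0)
        assert series.values[2] == pytest.approx(math.sqrt(1.7**2 / 8))

    def test_summary_statistics_consistent_with_values(self):
        base, rng = self._random_base()
        traj = make_rigid_trajectory(base, random_rigid_transforms(6, rng), noise_sigma=0.3, seed=1)
        s = rmsd_series(traj, 0)
        v = np.array(s.values)
        assert s.mean == pytest.approx(v.mean())
        assert s.min == pytest.approx(v.min())
        assert s.max == pytest.approx(v.max())
        assert s.sd == pytest.approx(v.std(ddof=1))


class TestRmsf:
    def test_static_trajectory_all_zero(self):
        base = _plain_frame(np.random.default_rng(6).normal(size=(6, 3)))
        traj = make_rigid_trajectory(base, [(np.eye(3), np.zeros(3))] * 4)
        prof = rmsf_profile(traj, superpose=False)
        assert all(v == pytest.approx(0.0) for _, v in prof.per_atom)

    def test_two_frame_unit_oscillation_gives_unit_rmsf(self):
        a = np.array([[0.0, 0, 0], [5, 0, 0], [0, 5, 0], [0, 0, 5], [-1.0, 3, 2]])
        b = a.copy()
        a[4, 0] = -1.0 + 1.0
        b[4, 0] = -1.0 - 1.0
        traj = Trajectory([_plain_frame(a, 0), _plain_frame(b, 1)])
        prof = rmsf_profile(traj, superpose=False)
        assert prof.per_atom[4][1] == pytest.approx(1.0)

    def test_matches_direct_formula_on_random_trajectory(self):
        rng = np.random.default_rng(7)
        frames = [_plain_frame(rng.normal(scale=2.0, size=(7, 3)), i) for i in range(10)]
        # make topologies identical
        traj = Trajectory(frames)
        prof = rmsf_profile(traj, superpose=False)
        arr = np.array([f.coords for f in frames])
        mean = arr.mean(axis=0)
        oracle = np.sqrt(((arr - mean) ** 2).sum(axis=2).mean(axis=0))
        np.testing.assert_allclose([v for _, v in prof.per_atom], oracle, atol=1e-10)

    def test_frame_order_independence(self):
        rng = np.random.default_rng(8)
        frames = [_plain_frame(rng.normal(size=(6, 3)), i) for i in range(6)]
        traj = Trajectory(frames)
        shuffled = Trajectory([_plain_frame(frames[k].coords, i)
                               for i, k in enumerate([3, 0, 5, 1, 4, 2])])
        a = [v for _, v in rmsf_profile(traj, superpose=False).per_atom]
        b = [v for _, v in rmsf_profile(shuffled, superpose=False).per_atom]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_region_means_recombine_to_per_atom_sum(self):
        rng = np.random.default_rng(9)
        resids = [1, 1, 2, 2, 3, 3]
        frames = [_plain_frame(rng.normal(size=(6, 3)), i, resids) for i in range(5)]
        traj = Trajectory(frames)
        regions = [("r1", [1]), ("r23", [2, 3])]
        prof = rmsf_profile(traj, superpose=False, regions=regions)
        total_from_regions = sum(
            mean * len([r for r in resids if r in rid_set])
            for (label, _, mean), rid_set in zip(prof.per_region, ([1], [2, 3]))
        )
        assert total_from_regions == pytest.approx(sum(v for _, v in prof.per_atom))

    def test_empty_region_rejected(self):
        rng = np.random.default_rng(10)
        frames = [_plain_frame(rng.normal(size=(4, 3)), i) for i in range(3)]
        with pytest.raises(ValueError):
            rmsf_profile(Trajectory(frames), superpose=False, regions=[("ghost", [99])])


class TestIntramolecularHbonds:
    def test_planted_watson_crick_pairs_counted(self):
        traj = make_paired_helix(6, n_frames=2)
        series = intramolecular_hbond_series(traj)
        assert series.values == [12.0, 12.0]

    def test_separated_strands_count_zero(self):
        traj = make_paired_helix(6, separation=20.0)
        assert intramolecular_hbond_series(traj).values == [0.0]

    def test_same_residue_pairs_excluded(self):
        # a lone hydroxyl next to its own carbonyl oxygen: no intra-residue bond
        atoms = [
            _atom(1, "O1", "O", "RES", 1, "A", np.zeros(3)),
            _atom(2, "H1", "H", "RES", 1, "A", np.array([0.97, 0, 0])),
            _atom(3, "O2", "O", "RES", 1, "A", np.array([2.9, 0, 0])),
        ]
        fr = Frame(0, atoms, {"receptor": frozenset(range(3)), "ligand": frozenset(),
                              "water": frozenset(), "ion": frozenset()})
        traj = Trajectory([fr])
        assert intramolecular_hbond_series(traj).values == [0.0]


def test_rg_series_constant_under_identity_transforms():
    base = _plain_frame(np.random.default_rng(11).normal(size=(9, 3)))
    traj = make_rigid_trajectory(base, [(np.eye(3), np.zeros(3))] * 4)
    s = rg_series(traj)
    assert s.sd == pytest.approx(0.0, abs=1e-12)
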