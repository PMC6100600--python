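import math

import numpy as np
import pytest

from conftest import (
    _atom,
    brute_hbonds,
    brute_hydrophobic,
    brute_water_bridges,
    plane_normal_eig,
    random_polar_frame,
)

from aptamd.interactions import (
    InteractionConfig,
    detect_hbonds,
    detect_hydrophobic,
    detect_pistacking,
    detect_water_bridges,
    fit_ring_plane,
    profile_frame,
    profile_trajectory,
    read_records_tsv,
    write_records_tsv,
)
from aptamd.fixtures import (
    FixtureSpec,
    PlantedInteraction,
    default_fixture_config,
    make_complex,
)
from aptamd.model_io import Frame, Ring, assign_roles_trajectory


def _frame(atoms, lig, rec, wat=()):
    return Frame(0, atoms, {
        "ligand": frozenset(lig), "receptor": frozenset(rec),
        "water": frozenset(wat), "ion": frozenset(),
    })


def _donor_acceptor_frame(da_dist, angle_deg=180.0):
    """Ligand hydroxyl donor at the origin, receptor O acceptor placed at the
    requested D-A distance with the requested D-H...A angle."""
    d = np.zeros(3)
    h = np.array([0.97, 0.0, 0.0])
    th = math.radians(180.0 - angle_deg)
    acc = h + (da_dist - 0.97) * np.array([math.cos(th), math.sin(th), 0.0])
    atoms = [
        _atom(1, "O1", "O", "LIG", 1, "B", d, {"donor-heavy", "acceptor"}),
        _atom(2, "HO1", "H", "LIG", 1, "B", h, {"hydrogen"}),
        _atom(3, "O2", "O", "RES", 2, "A", acc, {"acceptor"}),
    ]
    return _frame(atoms, {0, 1}, {2})


class TestHbonds:
    def test_ideal_geometry_detected_with_chem_type(self, config):
        fr = _donor_acceptor_frame(2.9, 180.0)
        recs = detect_hbonds(fr, config)
        assert len(recs) == 1
        assert recs[0].chem_type == "O–H⋯O"
        assert recs[0].donor_side == "ligand"
        assert recs[0].distances["D-A"] == pytest.approx(2.9, abs=1e-9)

    def test_beyond_distance_or_angle_rejected(self, config):
        assert detect_hbonds(_donor_acceptor_frame(6.0, 180.0), config) == []
        assert detect_hbonds(_donor_acceptor_frame(2.9, 90.0), config) == []

    def test_empty_partition_raises(self, config):
        fr = _donor_acceptor_frame(2.9)
        bad = Frame(0, fr.atoms, {"ligand": frozenset({0, 1, 2}), "receptor": frozenset(),
                                  "water": frozenset(), "ion": frozenset()})
        with pytest.raises(ValueError):
            detect_hbonds(bad, config)

    def test_each_donor_hydrogen_keeps_only_nearest_acceptor(self, config):
        fr = _donor_acceptor_frame(2.9, 180.0)
        far = _atom(4, "O3", "O", "RES", 3, "A", np.array([3.4, 0.1, 0.0]), {"acceptor"})
        fr = _frame(fr.atoms + [far], {0, 1}, {2, 3})
        recs = detect_hbonds(fr, config)
        assert len(recs) == 1
        assert recs[0].receptor_atom == "O2"

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_enumeration(self, seed, config):
        rng = np.random.default_rng(seed)
        fr = random_polar_frame(rng, n_lig=5, n_rec=12, n_wat=0)
        recs = detect_hbonds(fr, config)
        got = set()
        for r in recs:
            d_name, a_name = (r.ligand_atom, r.receptor_atom) if r.donor_side == "ligand" else (r.receptor_atom, r.ligand_atom)
            donor = next(a for a in fr.atoms if a.name == d_name)
            acc = next(a for a in fr.atoms if a.name == a_name)
            h = next(a for a in fr.atoms if a.name == r.hydrogen_atom)
            got.add((donor.serial, h.serial, acc.serial))
        assert got == brute_hbonds(fr, config)

    def test_monotone_in_distance_threshold(self):
        rng = np.random.default_rng(42)
        fr = random_polar_frame(rng, n_lig=6, n_rec=12, n_wat=0)
        def keyset(cfg):
            return {(r.ligand_atom, r.receptor_atom, r.donor_side)
                    for r in detect_hbonds(fr, cfg)}
        loose = keyset(InteractionConfig(hbond_da_max=4.5, hbond_angle_min=90.0))
        mid = keyset(InteractionConfig(hbond_da_max=4.1, hbond_angle_min=90.0))
        tight = keyset(InteractionConfig(hbond_da_max=3.0, hbond_angle_min=90.0))
        assert tight <= mid <= loose


class TestWaterBridges:
    def _bridge_frame(self, with_water=True, donor_element="O"):
        d = np.zeros(3)
        h = np.array([0.97, 0.0, 0.0])
        w = np.array([2.8, 0.0, 0.0])
        om = math.radians(115.0)
        acc = w + 2.8 * np.array([math.cos(math.radians(180 - 115)), math.sin(om), 0.0]) * 0
        # acceptor at 115 deg from the water->H direction
        acc_dir = np.array([-math.cos(om), math.sin(om), 0.0])
        acc = w + 2.8 * acc_dir
        atoms = [
            _atom(1, f"{donor_element}1", donor_element, "LIG", 1, "B", d,
                  {"donor-heavy", "acceptor"}),
            _atom(2, "H1", "H", "LIG", 1, "B", h, {"hydrogen"}),
            _atom(3, "O4", "O", "RES", 2, "A", acc, {"acceptor"}),
        ]
        wat = []
        if with_water:
            atoms.append(_atom(4, "OW", "O", "HOH", 3, "W", w,
                               {"water-oxygen", "acceptor", "donor-heavy"}))
            wat = [3]
        return _frame(atoms, {0, 1}, {2}, wat)

    def test_planted_bridge_detected_and_typed(self, config):
        recs = detect_water_bridges(self._bridge_frame(), config)
        assert len(recs) == 1
        assert recs[0].chem_type == "O–H⋯O–H⋯O"
        assert recs[0].water_id == 3
        assert recs[0].angles["omega"] == pytest.approx(115.0, abs=1e-6)

    def test_no_water_no_bridge(self, config):
        assert detect_water_bridges(self._bridge_frame(with_water=False), config) == []

    def test_amine_donor_gives_nitrogen_chem_type(self, config):
        # receptor-side N-H donating through the water to a ligand acceptor
        fr = self._bridge_frame(donor_element="N")
        recs = detect_water_bridges(fr, config)
        assert recs[0].chem_type == "N–H⋯O–H⋯O"

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_triples(self, seed, config):
        rng = np.random.default_rng(100 + seed)
        fr = random_polar_frame(rng, n_lig=4, n_rec=8, n_wat=10)
        recs = detect_water_bridges(fr, config)
        got = set()
        for r in recs:
            d_name, a_name = (r.ligand_atom, r.receptor_atom) if r.donor_side == "ligand" else (r.receptor_atom, r.ligand_atom)
            donor = next(a for a in fr.atoms if a.name == d_name)
            acc = next(a for a in fr.atoms if a.name == a_name)
            water = next(a for a in fr.atoms if a.residue_id == r.water_id and a.name == "OW")
            got.add((donor.serial, water.serial, acc.serial))
        assert got == brute_water_bridges(fr, config)

    def test_both_legs_must_sit_inside_the_distance_window(self, config):
        fr = self._bridge_frame()
        fr.atoms[2].coords = fr.atoms[3].coords + np.array([0.0, 5.0, 0.0])
        assert detect_water_bridges(fr, config) == []


class TestRingPlane:
    @staticmethod
    def _hexagon(center=(0, 0, 0), normal_axis=2, radius=1.39):
        pts = []
        for k in range(6):
            th = math.pi / 3 * k
            p = [radius * math.cos(th), radius * math.sin(th), 0.0]
            if normal_axis == 0:
                p = [p[2], p[0], p[1]]
            pts.append(np.array(p) + np.asarray(center, float))
        return np.array(pts)

    def test_flat_hexagon_centroid_and_normal(self):
        c, n = fit_ring_plane(self._hexagon())
        np.testing.assert_allclose(c, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(n, [0, 0, 1], atol=1e-12)

    def test_translation_equivariance(self):
        c, n = fit_ring_plane(self._hexagon(center=(1, 2, 3)))
        np.testing.assert_allclose(c, [1, 2, 3], atol=1e-12)
        np.testing.assert_allclose(n, [0, 0, 1], atol=1e-12)

    def test_puckered_ring_matches_eigen_oracle(self):
        rng = np.random.default_rng(5)
        pts = self._hexagon()
        pts[:, 2] += rng.uniform(-0.1, 0.1, 6)
        c, n = fit_ring_plane(pts)
        oracle = plane_normal_eig(pts)
        if oracle[2] < 0:
            oracle = -oracle
        np.testing.assert_allclose(np.abs(np.dot(n, oracle)), 1.0, atol=1e-9)
        assert math.degrees(math.acos(abs(n[2]))) < 5.0

    def test_collinear_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError):
            fit_ring_plane(line)


class TestPiStacking:
    def _ring_frame(self, offset=(0.0, 0.0, 3.5), rotate_deg=0.0):
        lig_pts = TestRingPlane._hexagon()
        th = math.radians(rotate_deg)
        rot = np.array([[1, 0, 0], [0, math.cos(th), -math.sin(th)],
                        [0, math.sin(th), math.cos(th)]])
        rec_pts = TestRingPlane._hexagon() @ rot.T + np.asarray(offset, float)
        atoms = []
        for i, p in enumerate(lig_pts):
            atoms.append(_atom(i + 1, f"C{i+1}", "C", "LIG", 1, "B", p, {"aromatic-member"}))
        for i, p in enumerate(rec_pts):
            atoms.append(_atom(7 + i, f"CR{i+1}", "C", "RES", 2, "A", p, {"aromatic-member"}))
        fr = _frame(atoms, set(range(6)), set(range(6, 12)))
        fr.rings = [
            Ring(("B", 1, "LIG"), "ringL", tuple(range(6))),
            Ring(("A", 2, "RES"), "ringR", tuple(range(6, 12))),
        ]
        return fr

    def test_parallel_stack_detected(self, config):
        recs = detect_pistacking(self._ring_frame(), config)
        assert len(recs) == 1
        assert recs[0].chem_type == "parallel"
        assert recs[0].distances["centroid"] == pytest.approx(3.5)

    def test_coplanar_lateral_offset_rejected(self, config):
        recs = detect_pistacking(self._ring_frame(offset=(4.0, 0.0, 0.0)), config)
        assert recs == []

    def test_perpendicular_rings_are_t_shaped(self, config):
        recs = detect_pistacking(self._ring_frame(offset=(0.0, 0.0, 4.8), rotate_deg=90.0), config)
        assert len(recs) == 1
        assert recs[0].chem_type == "T-shaped"
        assert recs[0].angles["planes"] == pytest.approx(90.0, abs=1e-6)

    def test_intermediate_tilt_rejected(self, config):
        assert detect_pistacking(self._ring_frame(offset=(0.0, 0.0, 4.0), rotate_deg=45.0), config) == []


class TestHydrophobic:
    def test_within_cutoff_detected_and_beyond_rejected(self, config):
        def fr(d):
            atoms = [
                _atom(1, "C1", "C", "LIG", 1, "B", np.zeros(3), {"hydrophobic-carbon"}),
                _atom(2, "C7", "C", "RES", 2, "A", np.array([d, 0, 0]), {"hydrophobic-carbon"}),
            ]
            return _frame(atoms, {0}, {1})
        assert len(detect_hydrophobic(fr(3.8), config)) == 1
        assert detect_hydrophobic(fr(4.5), config) == []

    def test_reduced_to_minimum_distance_per_residue_and_ligand_atom(self, config):
        atoms = [_atom(1, "C1", "C", "LIG", 1, "B", np.zeros(3), {"hydrophobic-carbon"})]
        for i, d in enumerate((3.9, 3.2, 3.7)):
            atoms.append(_atom(2 + i, f"C{5+i}", "C", "RES", 2, "A",
                               np.array([d, 0, 0]), {"hydrophobic-carbon"}))
        fr = _frame(atoms, {0}, {1, 2, 3})
        recs = detect_hydrophobic(fr, config)
        assert len(recs) == 1
        assert recs[0].receptor_atom == "C6"
        assert recs[0].distances["C-C"] == pytest.approx(3.2)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_group_by_min_oracle(self, seed, config):
        rng = np.random.default_rng(200 + seed)
        fr = random_polar_frame(rng, n_lig=0, n_rec=0, n_wat=0, with_hydrophobic=True)
        recs = detect_hydrophobic(fr, config)
        got = {(r.receptor_residue, r.ligand_atom): round(r.distances["C-C"], 9)
               for r in recs}
        want = {k: round(v[0], 9) for k, v in brute_hydrophobic(fr, config).items()}
        assert got == want


class TestRigidMotionInvariance:
    def test_all_detector_geometry_invariant_under_rigid_motion(self, config):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(9)
        fr = random_polar_frame(rng, n_lig=5, n_rec=10, n_wat=8, with_hydrophobic=True)
        rot = Rotation.random(random_state=rng).as_matrix()
        trans = rng.uniform(-20, 20, 3)
        moved_atoms = [
            _atom(a.serial, a.name, a.element, a.residue_name, a.residue_id, a.chain,
                  rot @ a.coords + trans, a.role_flags)
            for a in fr.atoms
        ]
        moved = Frame(0, moved_atoms, fr.partition)

        def geo(frame):
            out = []
            for r in (detect_hbonds(frame, config)
                      + detect_water_bridges(frame, config)
                      + detect_hydrophobic(frame, config)):
                out.append((r.iclass, r.ligand_atom, r.receptor_atom,
                            tuple(sorted(r.distances.items())),
                            tuple(sorted(r.angles.items()))))
            return sorted(out)

        for (c1, l1, r1, d1, a1), (c2, l2, r2, d2, a2) in zip(geo(fr), geo(moved)):
            assert (c1, l1, r1) == (c2, l2, r2)
            for (k1, v1), (k2, v2) in zip(d1, d2):
                assert k1 == k2 and v1 == pytest.approx(v2, abs=1e-6)
            for (k1, v1), (k2, v2) in zip(a1, a2):
                assert k1 == k2 and v1 == pytest.approx(v2, abs=1e-6)


class TestProfileTrajectory:
    def test_planted_hbond_appears_only_in_planted_frames(self):
        spec = FixtureSpec(seed=11, n_frames=5,
                           planted=[PlantedInteraction("hbond", (0, 1, 2, 3))])
        traj = make_complex(spec)
        recs = profile_trajectory(traj, default_fixture_config())
        assert [r.iclass for r in recs] == ["hbond"] * 4
        assert {r.frame_index for r in recs} == {0, 1, 2, 3}

    def test_profile_equals_union_of_per_frame_calls(self):
        spec = FixtureSpec(seed=12, n_frames=4,
                           planted=[PlantedInteraction("hbond", (0, 2)),
                                    PlantedInteraction("hydrophobic", (1, 2, 3)),
                                    PlantedInteraction("water_bridge", (0, 3))],
                           n_decoy_waters=4)
        traj = make_complex(spec)
        cfg = default_fixture_config()
        full = profile_trajectory(traj, cfg)
        manual = []
        assign_roles_trajectory(traj, cfg)
        for fr in traj.frames:
            manual += profile_frame(fr, cfg)
        key = lambda r: (r.frame_index, r.iclass, r.receptor_residue, r.ligand_atom,
                         r.receptor_atom, r.water_id)
        assert sorted(map(key, full)) == sorted(map(key, manual))

    def test_records_tsv_round_trip(self, tmp_path):
        spec = FixtureSpec(seed=13, n_frames=3,
                           planted=[PlantedInteraction("hbond", (0, 1)),
                                    PlantedInteraction("pistack", (2,)),
                                    PlantedInteraction("water_bridge", (1,))])
        traj = make_complex(spec)
        recs = profile_trajectory(traj, default_fixture_config())
        path = write_records_tsv(recs, tmp_path / "records.tsv")
        back = read_records_tsv(path)
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert (a.frame_index, a.iclass, a.receptor_residue, a.ligand_atom,
                    a.receptor_atom, a.water_id, a.chem_type, a.donor_side) == (
                b.frame_index, b.iclass, b.receptor_residue, b.ligand_atom,
                b.receptor_atom, b.water_id, b.chem_type, b.donor_side)
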