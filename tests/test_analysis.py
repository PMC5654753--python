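"""Superposition, RMSD, ET-distance screening, contacts, H-bonds, rod shape."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from iscarod.analysis import (
    MarcusModel,
    contact_map,
    edge_to_edge_distance,
    hydrogen_bonds,
    kabsch_align,
    marcus_coupling,
    nearest_cluster_series,
    rmsd_series,
    rod_shape_profile,
)
from iscarod.errors import GeometryError, InputError, SelectionError, WindowError
from iscarod.structure import AtomRecord, Structure, Trajectory

from oracles import (
    contact_pairs_oracle,
    grid_search_rmsd,
    hydrogen_bond_oracle,
    min_distance_oracle,
)


def _atoms(positions, element="C", chain="A", res_start=1, names=None,
           res_ids=None, res_name="ALA"):
    out = []
    for i, pos in enumerate(positions):
        out.append(
            AtomRecord(
                serial=i + 1,
                name=names[i] if names else f"C{i}",
                element=element if isinstance(element, str) else element[i],
                res_name=res_name,
                res_id=res_ids[i] if res_ids else res_start + i,
                chain_id=chain,
                position=np.asarray(pos, float),
            )
        )
    return out


class TestKabschAlign:
    def test_identity_for_equal_sets(self, rng):
        pts = rng.normal(size=(10, 3)) * 5
        rotation, translation, aligned = kabsch_align(pts, pts)
        np.testing.assert_allclose(rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(translation, 0.0, atol=1e-10)
        np.testing.assert_allclose(aligned, pts, atol=1e-10)

    def test_exact_recovery_of_arbitrary_rotation(self, rng):
        pts = rng.normal(size=(12, 3)) * 5
        R = Rotation.from_rotvec(0.6458 * np.array([0.2, -0.5, 0.8])).as_matrix()
        moved = pts @ R.T + np.array([3.0, -1.0, 7.0])
        _, _, aligned = kabsch_align(moved, pts)
        assert np.sqrt(np.mean(np.sum((aligned - pts) ** 2, axis=1))) < 1e-10

    def test_rotation_is_proper(self, rng):
        mobile = rng.normal(size=(8, 3))
        reference = rng.normal(size=(8, 3))
        rotation, _, _ = kabsch_align(mobile, reference)
        assert np.linalg.det(rotation) == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(rotation @ rotation.T, np.eye(3), atol=1e-10)

    def test_noisy_fit_beats_5_degree_grid(self, rng):
        """Least-squares optimum is never worse than exhaustive grid search."""
        pts = rng.normal(size=(8, 3)) * 4
        R = Rotation.from_rotvec([0.9, 0.2, -0.4]).as_matrix()
        noisy = pts @ R.T + rng.normal(0, 0.4, pts.shape)
        _, _, aligned = kabsch_align(noisy, pts)
        kabsch_rmsd = np.sqrt(np.mean(np.sum((aligned - pts) ** 2, axis=1)))
        assert kabsch_rmsd <= grid_search_rmsd(noisy, pts) + 1e-9

    def test_degenerate_subset_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(GeometryError):
            kabsch_align(line, line)


class TestRmsdSeries:
    def _traj(self, frames):
        topo = Structure(_atoms(frames[0]))
        return Trajectory(topo, np.asarray(frames, float))

    def test_constant_trajectory_is_zero(self, rng):
        base = rng.normal(size=(6, 3)) * 4
        traj = self._traj([base, base, base])
        np.testing.assert_allclose(rmsd_series(traj), 0.0, atol=1e-12)

    def test_pure_translation_without_fit(self, rng):
        base = rng.normal(size=(6, 3)) * 4
        traj = self._traj([base, base + np.array([0.0, 4.0, 0.0])])
        series = rmsd_series(traj, superpose=False)
        assert series[1] == pytest.approx(4.0)
        # With superposition the translation is removed entirely.
        assert rmsd_series(traj)[1] == pytest.approx(0.0, abs=1e-10)

    def test_matches_per_frame_formula_oracle(self, rng):
        base = rng.normal(size=(7, 3)) * 4
        frames = [base + rng.normal(0, 0.5, base.shape) for _ in range(5)]
        frames[0] = base
        traj = self._traj(frames)
        series = rmsd_series(traj)
        for m in range(5):
            rotation, translation, aligned = kabsch_align(traj.frames[m], base)
            expected = np.sqrt(np.mean(np.sum((aligned - base) ** 2, axis=1)))
            assert series[m] == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_mdanalysis(self, rng):
        """Independent library oracle for superposed RMSD."""
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        base = rng.normal(size=(9, 3)) * 5
        frame = base + rng.normal(0, 0.8, base.shape)
        traj = self._traj([base, frame])
        ours = rmsd_series(traj)[1]
        theirs = mda_rmsd(frame, base, superposition=True)
        assert ours == pytest.approx(theirs, abs=1e-6)


class TestEdgeToEdge:
    def test_two_single_atoms(self):
        s = Structure(_atoms([(0, 0, 0), (30.0, 0, 0)]))
        assert edge_to_edge_distance(s, [0], [1]) == pytest.approx(30.0)
        assert edge_to_edge_distance(s, [1], [0]) == pytest.approx(30.0)

    def test_shared_atom_excluded_from_pairing(self):
        s = Structure(_atoms([(0, 0, 0), (1.0, 0, 0), (5.0, 0, 0)]))
        # Sets overlap in atom 1; its zero self-distance must not count.
        assert edge_to_edge_distance(s, [0, 1], [1, 2]) == pytest.approx(1.0)

    def test_hydrogens_excluded_by_default(self):
        s = Structure(
            _atoms([(0, 0, 0), (10.0, 0, 0), (1.0, 0, 0)], element=["C", "C", "H"])
        )
        assert edge_to_edge_distance(s, [0], [1, 2]) == pytest.approx(10.0)
        assert edge_to_edge_distance(s, [0], [1, 2], heavy_only=False) == pytest.approx(1.0)

    def test_matches_all_pairs_oracle(self, rng):
        pts = rng.uniform(-20, 20, size=(60, 3))
        s = Structure(_atoms(pts))
        a, b = np.arange(30), np.arange(30, 60)
        expected = min_distance_oracle(pts[a], pts[b])
        assert edge_to_edge_distance(s, a, b) == pytest.approx(expected, abs=1e-12)

    def test_empty_set_rejected(self):
        s = Structure(_atoms([(0, 0, 0)]))
        with pytest.raises(SelectionError):
            edge_to_edge_distance(s, [], [0])


class TestNearestClusterSeries:
    def _static_traj(self, positions, n_frames=3):
        topo = Structure(_atoms(positions))
        frames = np.repeat(topo.coords[None], n_frames, axis=0)
        return Trajectory(topo, frames)

    def test_single_cluster_constant_distance(self):
        traj = self._static_traj([(0, 0, 0), (35.0, 0, 0)])
        (series,) = nearest_cluster_series(
            traj, {"Cry0": {"d_FAD": [0]}}, [np.array([1])]
        )
        np.testing.assert_allclose(series.per_frame, 35.0)
        assert series.kind == "d_FAD" and series.std == 0.0

    def test_nearest_of_two_clusters_wins(self):
        traj = self._static_traj([(0, 0, 0), (40.0, 0, 0), (0, 33.0, 0)])
        (series,) = nearest_cluster_series(
            traj, {"Cry0": {"d_FAD": [0]}}, [np.array([1]), np.array([2])]
        )
        np.testing.assert_allclose(series.per_frame, 33.0)

    def test_min_property_against_single_cluster_calls(self, docked_fixture, default_spec):
        from iscarod.synthetic import make_complex_trajectory

        traj = make_complex_trajectory(docked_fixture.structure, n_frames=3,
                                       seed=default_spec.seed)
        clusters = docked_fixture.cluster_sets()
        series = nearest_cluster_series(
            traj, {"Cry0": docked_fixture.cofactor_sets()["Cry0"]}, clusters
        )
        for s in series:
            for cluster in clusters[:5]:
                cofactor = docked_fixture.cofactor_sets()["Cry0"][s.kind]
                single = edge_to_edge_distance(
                    traj.topology, cofactor, cluster, frame=traj.frames[0]
                )
                assert s.per_frame[0] <= single + 1e-9

    def test_planted_distances_stay_inside_band(self, docked_fixture, default_spec):
        """Fixture distances remain in the planted 30-50 A interval."""
        from iscarod.synthetic import make_complex_trajectory

        traj = make_complex_trajectory(docked_fixture.structure, n_frames=5,
                                       seed=default_spec.seed)
        series = nearest_cluster_series(
            traj, docked_fixture.cofactor_sets(), docked_fixture.cluster_sets()
        )
        assert len(series) == 20
        for s in series:
            assert np.all(s.per_frame >= 30.0) and np.all(s.per_frame <= 50.0)
            planted = docked_fixture.planted[s.partner_id][s.kind]
            np.testing.assert_allclose(s.per_frame, planted, atol=1e-6)

    def test_no_clusters_rejected(self):
        traj = self._static_traj([(0, 0, 0)])
        with pytest.raises(InputError):
            nearest_cluster_series(traj, {"Cry0": {"d_FAD": [0]}}, [])


class TestMarcusCoupling:
    def test_zero_distance_gives_v0_squared(self):
        assert marcus_coupling(MarcusModel(v0=3.0, beta=1.4, r=0.0)) == pytest.approx(9.0)

    def test_one_angstrom_ratio(self):
        a = marcus_coupling(MarcusModel(beta=1.4, r=11.0))
        b = marcus_coupling(MarcusModel(beta=1.4, r=10.0))
        assert a / b == pytest.approx(np.exp(-1.4), rel=1e-12)
        assert a / b == pytest.approx(0.2466, abs=1e-4)

    def test_log_linear_slope_recovers_beta(self):
        """Regression oracle: ln-coupling vs distance has slope -beta."""
        beta = 1.4
        distances = np.linspace(5.0, 32.0, 10)
        logs = [np.log(marcus_coupling(MarcusModel(beta=beta, r=r))) for r in distances]
        slope = np.polyfit(distances, logs, 1)[0]
        assert slope == pytest.approx(-beta, abs=1e-9)

    def test_doubling_beta_squares_relative_coupling(self):
        r = 7.3
        single = marcus_coupling(MarcusModel(beta=1.1, r=r))
        double = marcus_coupling(MarcusModel(beta=2.2, r=r))
        assert double == pytest.approx(single**2, rel=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(InputError):
            MarcusModel(beta=1.4, r=-1.0)


class TestContactMap:
    def _pair_traj(self, separation, n_frames=4):
        positions = [(0, 0, 0), (separation, 0, 0)]
        topo = Structure(
            _atoms(positions, chain="A", res_ids=[1, 50], names=["CA", "CB"])
        )
        frames = np.repeat(topo.coords[None], n_frames, axis=0)
        return Trajectory(topo, frames)

    def test_persistent_contact_fully_occupied(self):
        traj = self._pair_traj(2.9)
        cmap = contact_map(traj, [0], [1], cutoff=3.0)
        assert cmap.occupancy == {(1, 50): 1.0}

    def test_pair_just_outside_cutoff_absent(self):
        traj = self._pair_traj(3.1)
        assert contact_map(traj, [0], [1], cutoff=3.0).occupancy == {}

    def test_matches_exhaustive_residue_scan(self, rng):
        positions = rng.uniform(0, 15, size=(30, 3))
        topo = Structure(
            _atoms(positions, res_ids=list(range(1, 31)))
        )
        frames = positions[None] + rng.normal(0, 0.3, size=(3, 30, 3))
        traj = Trajectory(topo, frames)
        a, b = np.arange(15), np.arange(15, 30)
        cmap = contact_map(traj, a, b, cutoff=3.0)
        expected = set()
        for m in range(3):
            expected |= contact_pairs_oracle(topo, traj.frames[m], a, b, 3.0)
        assert cmap.cells() == expected

    def test_monotone_in_cutoff(self, rng):
        positions = rng.uniform(0, 12, size=(20, 3))
        topo = Structure(_atoms(positions, res_ids=list(range(1, 21))))
        traj = Trajectory(topo, positions[None])
        tight = contact_map(traj, np.arange(10), np.arange(10, 20), cutoff=3.0)
        loose = contact_map(traj, np.arange(10), np.arange(10, 20), cutoff=4.0)
        assert tight.cells() <= loose.cells()

    def test_empty_window_rejected(self):
        traj = self._pair_traj(2.9)
        with pytest.raises(WindowError):
            contact_map(traj, [0], [1], window=(99.0, 100.0))


class TestHydrogenBonds:
    def _hbond_system(self, n_o_distance=2.9, angle=180.0):
        # Donor N with H along +x; acceptor O placed at the given N-O
        # distance such that the N-H...O angle equals ``angle``.
        n_pos = np.array([0.0, 0.0, 0.0])
        h_pos = np.array([1.0, 0.0, 0.0])
        theta = np.radians(180.0 - angle)
        o_pos = h_pos + (n_o_distance - 1.0) * np.array(
            [np.cos(theta), np.sin(theta), 0.0]
        )
        atoms = _atoms([n_pos, h_pos], element=["N", "H"], chain="A",
                       res_ids=[10, 10], names=["N", "H"])
        atoms += _atoms([o_pos], element="O", chain="B", res_ids=[20], names=["O"])
        topo = Structure(atoms)
        frames = np.repeat(topo.coords[None], 2, axis=0)
        return Trajectory(topo, frames)

    def test_ideal_bond_detected_with_full_occupancy(self):
        traj = self._hbond_system()
        (record,) = hydrogen_bonds(traj, donors=[0], acceptors=[2])
        assert record.occupancy == 1.0
        assert record.label == "A10(A)-A20(B)"

    def test_group_labels_format(self):
        traj = self._hbond_system()
        (record,) = hydrogen_bonds(
            traj, donors=[0], acceptors=[2],
            group_labels={"A": "ISCA1", "B": "Cry"},
        )
        assert record.label == "A10(ISCA1)-A20(Cry)"

    def test_long_distance_not_detected(self):
        traj = self._hbond_system(n_o_distance=4.0)
        assert hydrogen_bonds(traj, donors=[0], acceptors=[2]) == []

    def test_bent_geometry_not_detected(self):
        traj = self._hbond_system(angle=120.0)
        assert hydrogen_bonds(traj, donors=[0], acceptors=[2]) == []

    def test_matches_exhaustive_triple_loop(self, rng):
        """Five planted bonds among decoys, against the brute-force scan."""
        donor_atoms, acceptor_atoms = [], []
        donors = []
        for k in range(5):
            base = np.array([k * 10.0, 0.0, 0.0])
            donor_atoms += _atoms([base, base + [1.0, 0, 0]], element=["N", "H"],
                                  chain="A", res_ids=[k + 1, k + 1],
                                  names=["N", "H"])
            acceptor_atoms += _atoms([base + [2.9, 0, 0]], element="O", chain="B",
                                     res_ids=[k + 1], names=["O"])
            donors.append(2 * k)
        # Decoy acceptors scattered far away.
        for d, pos in enumerate(rng.uniform(100, 200, size=(4, 3))):
            acceptor_atoms += _atoms([pos], element="O", chain="B",
                                     res_ids=[50 + d], names=["O"])
        acceptors = list(range(len(donor_atoms), len(donor_atoms) + len(acceptor_atoms)))
        topo = Structure(donor_atoms + acceptor_atoms)
        traj = Trajectory(topo, topo.coords[None])
        records = hydrogen_bonds(traj, donors=donors, acceptors=acceptors)
        got = {(r.donor, r.acceptor) for r in records}
        donors_h = [(d, [d + 1]) for d in donors]
        expected = hydrogen_bond_oracle(topo.coords, donors_h, acceptors, 3.5, 150.0)
        assert got == expected and len(got) == 5

    def test_donor_without_hydrogen_rejected(self):
        atoms = _atoms([(0, 0, 0), (3.0, 0, 0)], element=["N", "O"],
                       res_ids=[1, 2], names=["N", "O"])
        topo = Structure(atoms)
        traj = Trajectory(topo, topo.coords[None])
        with pytest.raises(Exception, match="no bonded hydrogen"):
            hydrogen_bonds(traj, donors=[0], acceptors=[1])


class TestRodShapeProfile:
    def _traj_from_centroids(self, centroid_sets):
        n = len(centroid_sets[0])
        topo = Structure(_atoms(centroid_sets[0], res_ids=list(range(1, n + 1))))
        frames = np.asarray(centroid_sets, float)
        return Trajectory(topo, frames), [np.array([i]) for i in range(n)]

    def test_straight_rod(self):
        pts = [(float(i), 0.0, 0.0) for i in range(10)]
        traj, partition = self._traj_from_centroids([pts])
        (shape,) = rod_shape_profile(traj, partition)
        assert shape.ratio == pytest.approx(1.0)
        assert shape.sign_changes == 0

    def test_single_arc_has_no_sign_change(self):
        angles = np.linspace(0, np.pi / 2, 10)
        pts = np.column_stack([np.cos(angles), np.sin(angles), np.zeros(10)]) * 20
        traj, partition = self._traj_from_centroids([pts])
        (shape,) = rod_shape_profile(traj, partition)
        assert shape.sign_changes == 0
        assert shape.ratio < 1.0

    def test_planted_s_mode_has_one_sign_change(self):
        s = np.linspace(0.0, 1.0, 12)
        pts = np.column_stack([100 * s, 8.0 * np.sin(2 * np.pi * s), np.zeros(12)])
        traj, partition = self._traj_from_centroids([pts])
        (shape,) = rod_shape_profile(traj, partition)
        assert shape.sign_changes == 1
        assert shape.ratio < 1.0

    def test_rigid_motion_invariance(self, rng):
        s = np.linspace(0.0, 1.0, 12)
        pts = np.column_stack([100 * s, 8.0 * np.sin(2 * np.pi * s), np.zeros(12)])
        R = Rotation.from_rotvec([0.4, 0.8, -0.3]).as_matrix()
        moved = pts @ R.T + rng.normal(0, 10, 3)
        traj, partition = self._traj_from_centroids([pts, moved])
        shapes = rod_shape_profile(traj, partition)
        assert shapes[0].ratio == pytest.approx(shapes[1].ratio, abs=1e-9)
        assert shapes[0].sign_changes == shapes[1].sign_changes

    def test_too_few_monomers_rejected(self):
        pts = [(0.0, 0, 0), (1.0, 0, 0), (2.0, 0, 0)]
        traj, partition = self._traj_from_centroids([pts])
        with pytest.raises(GeometryError):
            rod_shape_profile(traj, partition)
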