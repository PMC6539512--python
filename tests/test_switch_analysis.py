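"""Micro-switch trajectory metrics against generator ground truth."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tmhkit import switch_analysis as sa
from tmhkit import synthetic_trajectory as st
from tmhkit.helix_geometry import wrap_angle
from tmhkit.structure_io import AtomRecord, StructureModel, Trajectory

from conftest import random_rotation


def two_atom_trajectory(distances, times=None):
    """Trajectory with R3.50-like and S6.33-like marker atoms at prescribed
    separations (minimal topology for pair metrics)."""
    topo = [
        AtomRecord("A", 119, "ARG", "NE", "N", np.zeros(3)),
        AtomRecord("A", 119, "ARG", "NH1", "N", np.array([-1.0, 0.5, 0.0])),
        AtomRecord("A", 230, "SER", "OG", "O", np.array([2.9, 0.0, 0.0])),
    ]
    coords = np.zeros((len(distances), 3, 3))
    coords[:, 1] = [-1.0, 0.5, 0.0]
    coords[:, 2, 0] = distances
    return Trajectory(topology=topo, coords=coords, frame_times=times)


class TestPairDistance:
    def test_constant_bonded_geometry(self, scenario_labels):
        traj = two_atom_trajectory(np.full(5, 2.9), times=np.arange(5.0))
        ts = sa.pair_distance_series(traj, scenario_labels,
                                     sa.PairSpec("3.50", ("NE", "NH1"), "6.33", ("OG",)))
        np.testing.assert_allclose(ts.values, 2.9, atol=1e-12)

    def test_single_frame(self, scenario_labels):
        traj = two_atom_trajectory(np.array([3.4]), times=np.array([0.0]))
        ts = sa.pair_distance_series(traj, scenario_labels,
                                     sa.PairSpec("3.50", ("NE",), "6.33", ("OG",)))
        assert ts.values.shape == (1,)

    def test_minimum_over_cross_product(self, scenario_labels):
        traj = two_atom_trajectory(np.array([5.0]), times=np.array([0.0]))
        ts = sa.pair_distance_series(traj, scenario_labels,
                                     sa.PairSpec("3.50", ("NE", "NH1"), "6.33", ("OG",)))
        d_nh1 = np.linalg.norm(np.array([5.0, 0, 0]) - np.array([-1.0, 0.5, 0.0]))
        assert ts.values[0] == pytest.approx(min(5.0, d_nh1))

    def test_unresolvable_atom_reported(self, scenario_labels):
        traj = two_atom_trajectory(np.array([3.0]), times=np.array([0.0]))
        with pytest.raises(Exception, match="OD1"):
            sa.pair_distance_series(traj, scenario_labels,
                                    sa.PairSpec("3.50", ("OD1",), "6.33", ("OG",)))

    def test_generator_truth_recovered(self, wt_run, scenario_labels):
        _, traj, truth = wt_run
        ts = sa.pair_distance_series(
            traj, scenario_labels,
            sa.PairSpec("6.43", ("NE2", "OE1"), "7.49", ("OD1", "OD2")))
        assert np.max(np.abs(ts.values - truth["qd_hbond"])) < 1e-3


class TestIonicLock:
    def test_constant_29_occupancy_one(self, scenario_labels):
        n = 40
        traj = two_atom_trajectory(np.full(n, 2.9), times=np.arange(n) * 10.0)
        ts = sa.ionic_lock_series(traj, scenario_labels,
                                  sa.SwitchThresholds(equilibration_cut=100.0))
        assert ts.occupancy == pytest.approx(1.0)

    def test_constant_33_occupancy_zero(self, scenario_labels):
        n = 40
        traj = two_atom_trajectory(np.full(n, 3.3), times=np.arange(n) * 10.0)
        ts = sa.ionic_lock_series(traj, scenario_labels)
        assert ts.occupancy == pytest.approx(0.0)

    def test_occupancy_matches_generator(self, mutant_run, scenario_labels):
        _, traj, truth = mutant_run
        ts = sa.ionic_lock_series(traj, scenario_labels)
        truth_occ = float((truth["ionic_lock"][ts.post_cut] <= 3.2).mean())
        assert ts.occupancy == pytest.approx(truth_occ, abs=1e-12)


class TestArginineCage:
    def test_threshold_classification(self, scenario_labels):
        for d, bonded in ((3.5, True), (4.5, False)):
            traj = two_atom_trajectory(np.full(3, d), times=np.arange(3.0))
            # reuse pair machinery against D3.49-style carboxylate proxy
            ts = sa.pair_distance_series(traj, scenario_labels,
                                         sa.PairSpec("3.50", ("NE",), "6.33", ("OG",)),
                                         threshold=4.0)
            assert bool(ts.bound_flags[0]) is bonded

    def test_flag_flips_at_switch_frame(self, scenario_labels):
        d = np.full(30, 3.5)
        d[17:] = 6.5
        traj = two_atom_trajectory(d, times=np.arange(30.0))
        ts = sa.pair_distance_series(traj, scenario_labels,
                                     sa.PairSpec("3.50", ("NE",), "6.33", ("OG",)),
                                     threshold=4.0)
        assert ts.bound_flags[16] and not ts.bound_flags[17]

    def test_generator_truth(self, wt_run, scenario_labels):
        _, traj, truth = wt_run
        ts = sa.arginine_cage_series(traj, scenario_labels)
        assert np.max(np.abs(ts.values - truth["arginine_cage"])) < 1e-3


class TestIcEndSeparation:
    def test_generator_truth(self, mutant_run, scenario_labels):
        _, traj, truth = mutant_run
        ts = sa.ic_end_separation(traj, scenario_labels)
        assert np.max(np.abs(ts.values - truth["ic_end_separation"])) < 1e-3

    def test_rigid_rotation_invariance(self, wt_run, scenario_labels, rng):
        _, traj, _ = wt_run
        R = random_rotation(rng)
        rotated = Trajectory(topology=traj.topology,
                             coords=traj.coords[:200] @ R.T + 5.0,
                             frame_times=traj.frame_times[:200])
        a = sa.ic_end_separation(traj, scenario_labels).values[:200]
        b = sa.ic_end_separation(rotated, scenario_labels).values
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_wrong_set_size_rejected(self, wt_run, scenario_labels):
        _, traj, _ = wt_run
        with pytest.raises(ValueError):
            sa.ic_end_separation(traj, scenario_labels, tmh3_residues=[120, 121])


class TestSodiumPocket:
    def test_generator_truth(self, mutant_run, scenario_labels):
        _, traj, truth = mutant_run
        na = sa.sodium_pocket_distances(traj, scenario_labels)
        assert np.max(np.abs(na[0].values - truth["na_ca_3.39"])) < 1e-3
        assert np.max(np.abs(na[1].values - truth["na_ca_1.50"])) < 1e-3

    def test_displacement_shift(self, wt_run, mutant_run, scenario_labels):
        """Mutant-like sodium sits ≈3 Å further from Cα(1.50) than WT-like."""
        _, wt_traj, _ = wt_run
        _, mut_traj, _ = mutant_run
        wt = sa.sodium_pocket_distances(wt_traj, scenario_labels)[1].values.mean()
        mut = sa.sodium_pocket_distances(mut_traj, scenario_labels)[1].values.mean()
        assert mut - wt == pytest.approx(3.0, abs=0.1)

    def test_multiple_ions_rejected(self, wt_run, scenario_labels):
        _, traj, _ = wt_run
        topo = list(traj.topology) + [AtomRecord("A", 501, "NA", "NA", "NA",
                                                 np.zeros(3), hetatm=True)]
        coords = np.concatenate([traj.coords[:3],
                                 np.zeros((3, 1, 3))], axis=1)
        bad = Trajectory(topology=topo, coords=coords, frame_times=traj.frame_times[:3])
        with pytest.raises(ValueError, match="exactly one"):
            sa.sodium_pocket_distances(bad, scenario_labels)


class TestChi1Series:
    def test_generator_truth_within_half_degree(self, wt_run, scenario_labels):
        _, traj, truth = wt_run
        ts = sa.chi1_series(traj, scenario_labels, "7.49")
        err = np.max(np.abs(wrap_angle(ts.values - truth["chi1_7.49"])))
        assert err < 0.5

    def test_dominant_states_follow_scenario(self, wt_run, mutant_run, scenario_labels):
        _, wt_traj, _ = wt_run
        _, mut_traj, _ = mutant_run
        wt_ts = sa.chi1_series(wt_traj, scenario_labels, "7.49")
        mut_ts = sa.chi1_series(mut_traj, scenario_labels, "7.49")
        assert wt_ts.extra["dominant_state"] == "g_minus"   # +55° well
        assert mut_ts.extra["dominant_state"] == "g_plus"   # −55° well

    def test_von_mises_circular_mean(self, scenario_labels):
        """Trans well at 170°: circular mean of a κ=20 von Mises sample must
        be ≈170° (arithmetic mean would be wrecked by the ±180° wrap)."""
        spec = st.RotamerHopSpec(well_means=(170.0,), kappas=(20.0,),
                                 transition_matrix=np.array([[1.0]]),
                                 n_frames=4000, seed=3)
        _, chi = st.sample_rotamer_path(spec)
        a = np.radians(chi)
        mean = np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a))))
        assert wrap_angle(mean - 170.0) == pytest.approx(0.0, abs=2.0)

    def test_no_chi1_residue_rejected(self, wt_run, scenario_labels):
        _, traj, _ = wt_run
        with pytest.raises(ValueError):
            sa.chi1_series(traj, scenario_labels, "108")  # alanine


class TestRmsdSeries:
    @staticmethod
    def cube_trajectory():
        corners = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                            for sz in (-1, 1)], dtype=float) * 3.0
        topo = [AtomRecord("A", i + 1, "ALA", "CA", "C", corners[i])
                for i in range(8)]
        return topo, corners

    def test_reference_vs_itself_zero(self):
        topo, corners = self.cube_trajectory()
        traj = Trajectory(topology=topo, coords=corners[None], frame_times=[0.0])
        ts = sa.rmsd_series(traj, traj.frame(0))
        assert ts.values[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_removed(self, rng):
        topo, corners = self.cube_trajectory()
        frames = np.stack([
            corners @ random_rotation(rng).T + rng.standard_normal(3) * 8
            for _ in range(5)])
        traj = Trajectory(topology=topo, coords=frames, frame_times=np.arange(5.0))
        ref = StructureModel([AtomRecord("A", i + 1, "ALA", "CA", "C", corners[i])
                              for i in range(8)])
        np.testing.assert_allclose(sa.rmsd_series(traj, ref).values, 0.0, atol=1e-6)

    def test_analytic_half_displacement(self):
        topo, corners = self.cube_trajectory()
        moved = corners.copy()
        moved[moved[:, 0] > 0, 0] += 1.0
        traj = Trajectory(topology=topo, coords=moved[None], frame_times=[0.0])
        ref = StructureModel([AtomRecord("A", i + 1, "ALA", "CA", "C", corners[i])
                              for i in range(8)])
        assert sa.rmsd_series(traj, ref).values[0] == pytest.approx(0.5, abs=1e-9)


class TestOccupancySummary:
    @staticmethod
    def series(flags, dt=1.0, cut=0.0):
        n = len(flags)
        return sa.SwitchTimeSeries("m", np.arange(n) * dt,
                                   np.where(flags, 2.9, 6.0),
                                   bound_flags=np.asarray(flags, bool),
                                   threshold=3.2, equilibration_cut=cut)

    def test_all_true_single_interval(self):
        s = sa.occupancy_summary(self.series([True] * 10))
        assert s.occupancy == 1.0
        assert len(s.intervals) == 1
        assert s.n_formations == 0 and s.n_breakages == 0

    def test_alternating_event_count(self):
        flags = [True, False] * 10
        s = sa.occupancy_summary(self.series(flags))
        assert s.n_formations + s.n_breakages == len(flags) - 1

    def test_mean_dwell_matches_markov_rate(self):
        """Bonded dwell time of the two-state generator ≈ 1/k_off."""
        spec = st.TwoStateSpec(k_on=0.8, k_off=0.5, n_frames=20_000, dt=0.1, seed=5)
        states, dist = st.sample_two_state(spec)
        s = sa.occupancy_summary(self.series(states.astype(bool), dt=0.1))
        durations = np.array([d for (_, _, d) in s.intervals])
        # discrete geometric dwell: mean (1/p_off) frames → dt/p_off ns
        expected = spec.dt / (spec.k_off * spec.dt)
        se = durations.std(ddof=1) / np.sqrt(len(durations))
        assert durations.mean() == pytest.approx(expected, abs=3 * se + 0.05)

    def test_short_series_warns_empty(self):
        s = sa.occupancy_summary(self.series([True, False], cut=100.0))
        assert s.occupancy is None
        assert s.warning is not None


class TestStateReport:
    def test_wt_like_is_lock_broken(self, wt_run, scenario_labels):
        _, traj, _ = wt_run
        rep = sa.state_report(traj, scenario_labels)
        assert rep.classification == "lock-broken"

    def test_mutant_like_is_lock_intermittent(self, mutant_run, scenario_labels):
        _, traj, _ = mutant_run
        rep = sa.state_report(traj, scenario_labels)
        assert rep.classification == "lock-intermittent"

    def test_constant_bonded_is_lock_stable(self, scenario_labels):
        n = 60
        traj = two_atom_trajectory(np.full(n, 2.9), times=np.arange(n) * 5.0)
        ts = sa.ionic_lock_series(traj, scenario_labels)
        assert ts.occupancy == 1.0  # would classify lock-stable

    def test_report_dict_serializable(self, wt_run, scenario_labels):
        import json

        _, traj, _ = wt_run
        rep = sa.state_report(traj, scenario_labels)
        text = json.dumps(rep.to_dict(), default=float)
        assert "lock-broken" in text


class TestRigidMotionInvariance:
    def test_all_distance_metrics_invariant_per_frame(self, wt_run, scenario_labels, rng):
        """Random per-frame rotations+translations leave every distance
        series unchanged."""
        _, traj, truth = wt_run
        n = 150
        coords = traj.coords[:n].copy()
        for f in range(n):
            R = random_rotation(rng)
            coords[f] = coords[f] @ R.T + rng.standard_normal(3) * 20
        moved = Trajectory(topology=traj.topology, coords=coords,
                           frame_times=traj.frame_times[:n])
        assert np.max(np.abs(sa.ionic_lock_series(moved, scenario_labels).values
                             - truth["ionic_lock"][:n])) < 1e-6
        assert np.max(np.abs(sa.ic_end_separation(moved, scenario_labels).values
                             - truth["ic_end_separation"][:n])) < 1e-6
        na = sa.sodium_pocket_distances(moved, scenario_labels)
        assert np.max(np.abs(na[1].values - truth["na_ca_1.50"][:n])) < 1e-6
        chi = sa.chi1_series(moved, scenario_labels, "7.49")
        assert np.max(np.abs(wrap_angle(chi.values - truth["chi1_7.49"][:n]))) < 1e-6
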