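import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from fragsite.synthetic_data import (CovarianceSpec, make_receptor_fixture,
                                     make_trajectory)
from fragsite.trajectory_metrics import (ActivationTrace, AnalysisConfig,
                                         LMIMatrix, Trajectory,
                                         TrajectoryError, activation_trace,
                                         com_distance_series, contact_fraction,
                                         high_correlation_regions,
                                         kabsch_superpose, lmi_matrix,
                                         moving_average, rmsd_series, rmsf,
                                         rmsf_distribution)


def _table(n, resid=None, element="C", heavy=True, mass=12.011):
    return pd.DataFrame({
        "resid": resid if resid is not None else np.arange(1, n + 1),
        "resname": "ALA", "atom_name": "CA",
        "element": element, "heavy": heavy, "mass": mass,
    })


def _static_traj(coords, n_frames=3, dt=1.0, table=None):
    coords = np.asarray(coords, dtype=float)
    return Trajectory(coordinates=np.repeat(coords[None], n_frames, axis=0),
                      atom_table=table if table is not None else _table(len(coords)),
                      time_per_frame=dt)


class TestTrajectoryContainer:
    def test_shape_validation(self):
        with pytest.raises(TrajectoryError):
            Trajectory(coordinates=np.zeros((3, 4)), atom_table=_table(4))

    def test_table_length_validation(self):
        with pytest.raises(TrajectoryError):
            Trajectory(coordinates=np.zeros((2, 4, 3)), atom_table=_table(5))

    def test_missing_column(self):
        t = _table(4).drop(columns=["mass"])
        with pytest.raises(TrajectoryError, match="mass"):
            Trajectory(coordinates=np.zeros((2, 4, 3)), atom_table=t)

    def test_select(self):
        traj = _static_traj(np.zeros((4, 3)))
        assert traj.select(resids=[2, 3]).tolist() == [1, 2]


class TestKabsch:
    def test_identical_gives_zero(self, rng):
        x = rng.normal(size=(10, 3))
        _, _, r = kabsch_superpose(x, x)
        assert r <= 1e-12

    def test_rigid_copy_gives_zero(self, rng):
        x = rng.normal(size=(12, 3))
        R = Rotation.random(rng=rng).as_matrix()
        moved = x @ R.T + np.array([3.0, -1.0, 7.0])
        Rh, th, r = kabsch_superpose(moved, x)
        assert r <= 1e-8
        assert np.linalg.det(Rh) == pytest.approx(1.0, abs=1e-10)

    def test_grid_search_oracle(self):
        # 4-point crafted case: brute-force over a dense rotation grid
        ref = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 2.0, 0], [0, 0, 1.0]])
        mob = ref + np.array([[0.05, -0.02, 0.01], [-0.03, 0.04, 0.0],
                              [0.02, 0.01, -0.05], [0.0, -0.03, 0.04]])
        _, _, r = kabsch_superpose(mob, ref)
        best = np.inf
        cm, cr = mob.mean(0), ref.mean(0)
        for a in np.linspace(-0.2, 0.2, 21):
            for b in np.linspace(-0.2, 0.2, 21):
                for c in np.linspace(-0.2, 0.2, 21):
                    R = Rotation.from_euler("xyz", [a, b, c]).as_matrix()
                    moved = (mob - cm) @ R.T + cr
                    best = min(best, np.sqrt(np.mean(
                        np.sum((moved - ref) ** 2, axis=1))))
        assert r <= best + 1e-3

    def test_too_few_or_collinear_rejected(self):
        with pytest.raises(TrajectoryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(TrajectoryError, match="collinear"):
            kabsch_superpose(line, line)


class TestRMSD:
    def test_static_trajectory_zero(self, rng):
        x = rng.normal(size=(8, 3))
        traj = _static_traj(x, n_frames=4)
        s = rmsd_series(traj, x, np.arange(8))
        assert np.all(s <= 1e-12)

    def test_rigidly_moved_frames_zero(self, rng):
        x = rng.normal(size=(8, 3))
        frames = [x]
        for _ in range(3):
            R = Rotation.random(rng=rng).as_matrix()
            frames.append(x @ R.T + rng.normal(size=3))
        traj = Trajectory(coordinates=np.stack(frames), atom_table=_table(8))
        assert np.all(rmsd_series(traj, x, np.arange(8)) <= 1e-8)

    def test_hand_computed_case(self):
        # 2 frames, 3 atoms; frame 1 shifts one atom by 0.3 Å after perfect fit
        ref = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 2.0, 0], [0, 0, 2.0]])
        frame2 = ref.copy()
        # pure per-atom displacement pattern that is not a rigid motion
        frame2[0, 0] += 0.3
        frame2[1, 0] -= 0.3
        traj = Trajectory(coordinates=np.stack([ref, frame2]),
                          atom_table=_table(4))
        s = rmsd_series(traj, ref, np.arange(4))
        assert s[0] == pytest.approx(0.0, abs=1e-12)
        assert 0.0 < s[1] <= np.sqrt((2 * 0.3 ** 2) / 4) + 1e-12


class TestRMSF:
    def test_static_zero(self, rng):
        traj = _static_traj(rng.normal(size=(6, 3)), n_frames=5)
        assert np.all(rmsf(traj).to_numpy() <= 1e-12)

    def test_gaussian_truth(self):
        spec = CovarianceSpec(n_residues=5, sigma=0.5)
        traj, truth = make_trajectory(spec, n_frames=4000, seed=0)
        vals = rmsf(traj, fit=False)
        assert np.allclose(vals.to_numpy(), truth["rmsf"].to_numpy(), rtol=0.05)

    def test_rigid_body_motion_removed_by_fit(self, rng):
        x = rng.normal(size=(6, 3)) * 3.0
        frames = []
        for _ in range(10):
            R = Rotation.random(rng=rng).as_matrix()
            frames.append(x @ R.T + rng.normal(size=3))
        traj = Trajectory(coordinates=np.stack(frames), atom_table=_table(6))
        assert np.all(rmsf(traj, fit=True).to_numpy() <= 1e-6)

    def test_residue_aggregation(self):
        # two atoms in one residue: per-residue value is the mean of per-atom
        table = _table(2, resid=[1, 1])
        coords = np.zeros((4, 2, 3))
        coords[:, 0, 0] = [0.0, 1.0, 0.0, 1.0]   # atom 0 fluctuates
        traj = Trajectory(coordinates=coords, atom_table=table)
        v = rmsf(traj, fit=False)
        assert list(v.index) == [1]
        assert v.iloc[0] == pytest.approx(0.25)  # (0.5 + 0) / 2

    def test_distribution_summary(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0],
                      index=pd.Index([1, 2, 3, 4], name="resid"))
        d = rmsf_distribution(s, [1, 2, 3, 4])
        assert d["mean"] == pytest.approx(2.5)
        assert d["median"] == pytest.approx(2.5)
        assert d["n"] == 4
        with pytest.raises(TrajectoryError):
            rmsf_distribution(s, [99])


class TestDistancesContacts:
    def test_com_distance_two_atoms(self):
        coords = np.array([[[0.0, 0, 0], [5.0, 0, 0]]])
        traj = Trajectory(coordinates=coords, atom_table=_table(2))
        d = com_distance_series(traj, np.array([0]), np.array([1]))
        assert d[0] == pytest.approx(5.0)

    def test_com_distance_mass_weighted(self):
        table = _table(2, resid=[1, 2])
        table.loc[1, "mass"] = 36.033  # 3x the other mass
        coords = np.array([[[0.0, 0, 0], [4.0, 0, 0]]])
        traj = Trajectory(coordinates=coords, atom_table=table)
        d = com_distance_series(traj, np.array([0]), np.array([0, 1]))
        assert d[0] == pytest.approx(3.0)

    def test_contact_fraction_exact_60_of_100(self):
        # residue 1 = ligand; residue 2 = receptor residue
        table = _table(2, resid=[1, 2])
        coords = np.zeros((100, 2, 3))
        coords[:, 1, 0] = 10.0
        coords[:60, 1, 0] = 2.0  # within 3 Å in exactly 60 frames
        traj = Trajectory(coordinates=coords, atom_table=table)
        pct = contact_fraction(traj, traj.select(resids=[1]), [2], cutoff=3.0)
        assert pct[2] == 60.0

    def test_boundary_counts_as_contact(self):
        table = _table(2, resid=[1, 2])
        coords = np.zeros((1, 2, 3))
        coords[0, 1, 0] = 3.0  # exactly the cutoff
        traj = Trajectory(coordinates=coords, atom_table=table)
        assert contact_fraction(traj, np.array([0]), [2], cutoff=3.0)[2] == 100.0

    def test_hydrogens_ignored(self):
        table = _table(3, resid=[1, 1, 2])
        table.loc[1, "heavy"] = False
        table.loc[1, "element"] = "H"
        coords = np.zeros((1, 3, 3))
        coords[0, 1, 0] = 2.9   # hydrogen close — must not count
        coords[0, 2, 0] = 10.0  # heavy receptor atom far
        traj = Trajectory(coordinates=coords, atom_table=table)
        # ligand heavy atom at origin, receptor at 10 → no contact
        assert contact_fraction(traj, np.array([0, 1]), [2])[2] == 0.0

    def test_unknown_residue_named_in_error(self):
        traj = _static_traj(np.zeros((2, 3)), table=_table(2, resid=[1, 2]))
        with pytest.raises(TrajectoryError, match="77"):
            contact_fraction(traj, np.array([0]), [77])

    def test_monotone_in_cutoff(self, rng):
        table = _table(2, resid=[1, 2])
        coords = rng.uniform(-4, 4, size=(50, 2, 3))
        traj = Trajectory(coordinates=coords, atom_table=table)
        sel = np.array([0])
        prev = -1.0
        for cutoff in (1.0, 2.0, 4.0, 8.0):
            v = contact_fraction(traj, sel, [2], cutoff=cutoff)[2]
            assert v >= prev
            prev = v


class TestActivation:
    def test_inactive_reference_trajectory(self):
        fix = make_receptor_fixture()
        ref = fix.coordinates
        traj = fix.as_trajectory(np.repeat(ref[None], 4, axis=0))
        tr = activation_trace(traj, fix.select("ionic_lock_arg"),
                              fix.select("ionic_lock_glu"),
                              fix.select("npxxy"), inactive_ref=ref)
        assert np.all(tr.npxxy_rmsd <= 1e-8)
        assert np.allclose(tr.lock_distance, tr.inactive_marker[0])
        assert tr.inactive_marker[1] == 0.0

    def test_active_marker_reported(self):
        fix = make_receptor_fixture()
        inact = fix.coordinates
        act = inact.copy()
        npxxy = fix.select("npxxy")
        act[npxxy] += np.array([1.0, 0.3, -0.4])  # distort the motif
        traj = fix.as_trajectory(np.repeat(act[None], 3, axis=0))
        tr = activation_trace(traj, fix.select("ionic_lock_arg"),
                              fix.select("ionic_lock_glu"), npxxy,
                              inactive_ref=inact, active_ref=act)
        assert np.allclose(tr.npxxy_rmsd, tr.active_marker[1], atol=1e-8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(TrajectoryError):
            ActivationTrace(lock_distance=np.zeros(3), npxxy_rmsd=np.zeros(4))


class TestMovingAverage:
    def test_constant_series(self):
        out = moving_average(np.full(10, 2.5), window=3.0, time_per_frame=1.0)
        assert np.allclose(out, 2.5)

    def test_one_frame_window_identity(self):
        s = np.arange(7.0)
        assert np.array_equal(moving_average(s, 1.0, 1.0), s)

    def test_ramp_blocks(self):
        s = np.arange(1.0, 11.0)
        out = moving_average(s, window=5.0, time_per_frame=1.0)
        assert np.allclose(out, [3.0, 8.0])

    def test_partial_trailing_block(self):
        s = np.arange(1.0, 8.0)  # 7 frames, blocks of 5 -> [1..5], [6,7]
        out = moving_average(s, 5.0, 1.0)
        assert np.allclose(out, [3.0, 6.5])

    def test_mean_preserved_for_exact_division(self, rng):
        s = rng.normal(size=20)
        out = moving_average(s, 4.0, 1.0)
        assert out.mean() == pytest.approx(s.mean())

    def test_window_shorter_than_frame_rejected(self):
        with pytest.raises(TrajectoryError):
            moving_average(np.zeros(5), 0.5, 1.0)


class TestLMI:
    def test_planted_correlation_recovered(self):
        spec = CovarianceSpec(
            n_residues=8, sigma=0.5,
            domains={"A": [0, 1, 2], "B": [4, 5, 6]},
            block_pairs=[("A", "B", 0.8)])
        traj, truth = make_trajectory(spec, n_frames=6000, seed=3)
        m = lmi_matrix(traj)
        for i, j in zip([0, 1, 2], [4, 5, 6]):
            assert m.values[i, j] == pytest.approx(0.8, abs=0.03)

    def test_null_off_diagonal_small(self):
        spec = CovarianceSpec(n_residues=6, sigma=0.5)
        traj, _ = make_trajectory(spec, n_frames=6000, seed=4)
        m = lmi_matrix(traj)
        off = m.values[~np.eye(6, dtype=bool)]
        assert off.max() <= 0.1

    def test_diagonal_one_symmetric_bounded(self):
        spec = CovarianceSpec(n_residues=5, sigma=0.3)
        traj, _ = make_trajectory(spec, n_frames=500, seed=5)
        m = lmi_matrix(traj)
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.allclose(m.values, m.values.T)
        assert m.values.min() >= 0.0 and m.values.max() <= 1.0

    def test_rigid_motion_invariance_with_fit(self, rng):
        spec = CovarianceSpec(n_residues=5, sigma=0.4)
        traj, _ = make_trajectory(spec, n_frames=400, seed=6)
        m0 = lmi_matrix(traj, fit=True)
        moved = np.empty_like(traj.coordinates)
        for f in range(traj.n_frames):
            R = Rotation.random(rng=rng).as_matrix()
            moved[f] = traj.coordinates[f] @ R.T + rng.normal(size=3) * 5
        traj2 = Trajectory(coordinates=moved, atom_table=traj.atom_table)
        m1 = lmi_matrix(traj2, fit=True)
        assert np.allclose(m0.values, m1.values, atol=0.08)

    def test_too_few_frames_rejected(self):
        spec = CovarianceSpec(n_residues=3, sigma=0.5)
        traj, _ = make_trajectory(spec, n_frames=5, seed=0)
        with pytest.raises(TrajectoryError, match="frames"):
            lmi_matrix(traj)

    def test_singular_covariance_rejected(self):
        coords = np.zeros((20, 3, 3))
        coords[:, 0, 0] = np.random.default_rng(0).normal(size=20)
        traj = Trajectory(coordinates=coords, atom_table=_table(3))
        with pytest.raises(TrajectoryError, match="singular|more frames"):
            lmi_matrix(traj)

    def test_matrix_validation(self):
        with pytest.raises(TrajectoryError):
            LMIMatrix(values=np.array([[1.0, 0.5], [0.4, 1.0]]), resids=[1, 2])
        with pytest.raises(TrajectoryError):
            LMIMatrix(values=np.array([[1.0, 1.5], [1.5, 1.0]]), resids=[1, 2])


class TestRegions:
    def _matrix(self):
        vals = np.eye(4)
        vals[0, 2] = vals[2, 0] = 0.9
        vals[1, 3] = vals[3, 1] = 0.7
        vals[0, 1] = vals[1, 0] = 0.95  # same-domain, must be ignored
        return LMIMatrix(values=vals, resids=[10, 11, 20, 21])

    def test_planted_block_detected_exactly(self):
        m = self._matrix()
        dmap = {10: "A", 11: "A", 20: "B", 21: "B"}
        regions = high_correlation_regions(m, 0.625, dmap)
        assert len(regions) == 1
        reg = regions[0]
        assert (reg.domain_a, reg.domain_b) == ("A", "B")
        assert reg.pairs == frozenset({(10, 20), (11, 21)})
        assert reg.runs_a == ((10, 11),)
        assert reg.runs_b == ((20, 21),)
        assert reg.max_lmi == pytest.approx(0.9)

    def test_threshold_above_max_gives_empty(self):
        m = self._matrix()
        dmap = {10: "A", 11: "A", 20: "B", 21: "B"}
        assert high_correlation_regions(m, 0.99, dmap) == []

    def test_threshold_zero_reports_all_interdomain(self):
        m = self._matrix()
        dmap = {10: "A", 11: "A", 20: "B", 21: "B"}
        regions = high_correlation_regions(m, 0.0, dmap)
        pairs = {p for r in regions for p in r.pairs}
        assert pairs == {(10, 20), (11, 21)}  # all inter-domain pairs with LMI > 0

    def test_unmapped_residue_goes_to_other(self):
        m = self._matrix()
        regions = high_correlation_regions(m, 0.625, {10: "A", 11: "A"})
        assert {(r.domain_a, r.domain_b) for r in regions} == {("A", "other")}
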