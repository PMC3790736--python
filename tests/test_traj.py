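"""Superposition, rmsd/rmsf closed forms, cross-correlation matrices."""

import numpy as np
import pytest

from zdsum.traj import (
    Trajectory,
    cross_correlation,
    method_agreement,
    rmsd_trace,
    rmsf,
    superpose,
)


def rotation_z(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


REF4 = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], float)


class TestSuperpose:
    def test_identity(self):
        moved, rmsd = superpose(REF4, REF4, range(4))
        np.testing.assert_allclose(moved, REF4, atol=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self):
        frame = REF4 @ rotation_z(0.7).T + np.array([5.0, -2.0, 1.0])
        _, rmsd = superpose(frame, REF4, range(4))
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_known_displacement_matches_independent_fit(self):
        """One point moved 1 Å; compare with biotite's least-squares fit."""
        import biotite.structure as struc

        frame = REF4.copy()
        frame[3, 2] += 1.0
        _, rmsd = superpose(frame, REF4, range(4))
        fitted, _ = struc.superimpose(REF4, frame)
        expected = float(struc.rmsd(REF4, fitted))
        assert rmsd == pytest.approx(expected, rel=1e-6)

    def test_collinear_set_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(ValueError, match="degenerate"):
            superpose(line, line, range(4))

    def test_no_reflection(self):
        mirrored = REF4 * np.array([-1.0, 1.0, 1.0])
        _, rmsd = superpose(mirrored, REF4, range(4))
        assert rmsd > 0.5  # a reflection could fake a perfect fit


class TestRmsdTrace:
    def test_static_trajectory_is_zero(self):
        traj = Trajectory(frames=np.repeat(REF4[None], 5, axis=0), times_ps=np.arange(5.0))
        trace = rmsd_trace(traj, REF4, range(4))
        np.testing.assert_allclose(trace, 0.0, atol=1e-12)
        assert trace.shape == (5,)

    def test_single_frame_consistent_with_superpose(self):
        frame = REF4.copy()
        frame[0] += [0.5, 0.5, 0]
        traj = Trajectory(frames=frame[None], times_ps=[0.0])
        trace = rmsd_trace(traj, REF4, range(4))
        assert trace[0] == pytest.approx(superpose(frame, REF4, range(4))[1])


def two_state_oscillation(amplitude, n_cycles=8):
    """Atom 0 alternates ±a along x; atoms 1-3 anchor the frame."""
    frames = []
    for k in range(2 * n_cycles):
        f = REF4.copy()
        f[0, 0] += amplitude if k % 2 == 0 else -amplitude
        frames.append(f)
    return Trajectory(frames=np.asarray(frames), times_ps=np.arange(2.0 * n_cycles))


class TestRmsf:
    def test_static_zero(self):
        traj = Trajectory(frames=np.repeat(REF4[None], 6, axis=0), times_ps=np.arange(6.0))
        out = rmsf(traj, {"all": range(4)}, window=(0.0, 1.0))
        assert out.rmsf["all"] == pytest.approx(0.0, abs=1e-12)

    def test_two_point_oscillator_closed_form(self):
        a = 0.8
        traj = two_state_oscillation(a)
        out = rmsf(traj, {"osc": [0]}, window=(0.0, 1.0))
        assert out.rmsf["osc"] == pytest.approx(a, rel=1e-12)

    def test_group_averaging_order(self):
        """One moving + one static atom: group rmsf = a/√2 (atom-mean of
        squared fluctuations, then root)."""
        a = 0.8
        traj = two_state_oscillation(a)
        out = rmsf(traj, {"pair": [0, 1]}, window=(0.0, 1.0))
        assert out.rmsf["pair"] == pytest.approx(a / np.sqrt(2), rel=1e-12)

    def test_empty_group_rejected(self):
        traj = two_state_oscillation(0.5)
        with pytest.raises(ValueError):
            rmsf(traj, {"none": []}, window=(0.0, 1.0))

    def test_rigid_motion_invariance_after_superposition(self):
        a = 0.3
        base = two_state_oscillation(a)
        rot = rotation_z(1.1)
        moved = Trajectory(
            frames=base.frames @ rot.T + np.array([4.0, 5.0, -6.0]),
            times_ps=base.times_ps,
        )
        out = rmsf(
            moved, {"osc": [0]}, window=(0.0, 1.0),
            superposition_set=[1, 2, 3], reference=REF4,
        )
        assert out.rmsf["osc"] == pytest.approx(a, rel=1e-9)


class TestCrossCorrelation:
    def _traj(self, disp_a, disp_b, n=40, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for k in range(n):
            f = np.vstack([REF4, REF4 + [10, 0, 0]])
            f[0] += disp_a(k, rng)
            f[4] += disp_b(k, rng)
            frames.append(f)
        return Trajectory(frames=np.asarray(frames), times_ps=np.arange(float(n)))

    def test_in_phase_unity(self):
        move = lambda k, _: np.array([0.5, 0, 0]) * (-1) ** k
        traj = self._traj(move, move)
        out = cross_correlation(traj, {"a": [0], "b": [4]}, window=(0.0, 1.0))
        assert out.correlation[0, 1] == pytest.approx(1.0)

    def test_anti_phase_minus_one(self):
        move = lambda k, _: np.array([0.5, 0, 0]) * (-1) ** k
        anti = lambda k, _: -move(k, _)
        out = cross_correlation(
            self._traj(move, anti), {"a": [0], "b": [4]}, window=(0.0, 1.0)
        )
        assert out.correlation[0, 1] == pytest.approx(-1.0)

    def test_independent_motions_decorrelate(self):
        rand_a = lambda k, rng: rng.normal(0, 0.4, 3)
        rand_b = lambda k, rng: rng.normal(0, 0.4, 3)
        out = cross_correlation(
            self._traj(rand_a, rand_b, n=10_000, seed=3),
            {"a": [0], "b": [4]},
            window=(0.0, 1.0),
        )
        assert abs(out.correlation[0, 1]) <= 0.05

    def test_matrix_properties(self):
        rng_move = lambda k, rng: rng.normal(0, 0.3, 3)
        out = cross_correlation(
            self._traj(rng_move, rng_move, n=50, seed=9),
            {"a": [0], "b": [4]},
            window=(0.0, 1.0),
        )
        c = out.correlation
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(c), 1.0, atol=1e-12)
        assert np.nanmax(np.abs(c)) <= 1.0 + 1e-12

    def test_zero_variance_group_flagged_not_propagated(self):
        static = lambda k, _: np.zeros(3)
        move = lambda k, _: np.array([0.4, 0, 0]) * (-1) ** k
        out = cross_correlation(
            self._traj(move, static), {"a": [0], "b": [4]}, window=(0.0, 1.0)
        )
        assert out.valid[0] and not out.valid[1]
        assert np.isnan(out.correlation[0, 1])
        assert out.correlation[0, 0] == 1.0


class TestMethodAgreement:
    def test_identical_profiles(self):
        p = [1.0, 2.0, 3.0, 2.5]
        assert method_agreement(p, p) == pytest.approx(1.0)

    def test_anti_ordered(self):
        a = np.array([1.0, 2.0, 3.0])
        assert method_agreement(a, -2 * a + 1) == pytest.approx(-1.0)

    def test_hand_listed_pair_matches_textbook_formula(self):
        a = np.array([0.3, 0.8, 1.5, 0.9, 0.4])
        b = np.array([0.5, 0.7, 1.2, 1.1, 0.6])
        expected = float(np.corrcoef(a, b)[0, 1])
        assert method_agreement(a, b) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            method_agreement([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
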