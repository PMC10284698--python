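"""Trajectory observables: selection, tilt, correlation, RMSD, flips."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sterolfilm import orientation as ori
from conftest import make_trajectory


def brute_force_correlation(traj, selection, bin_width, max_distance,
                            estimator="dot"):
    """All-pairs oracle: explicit loops, no vectorized shortcuts."""
    Lx, Ly = traj.box[0], traj.box[1]
    n_bins = int(round(max_distance / bin_width))
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    for f in range(traj.n_frames):
        for a in range(len(selection)):
            for b in range(a + 1, len(selection)):
                i, j = selection[a], selection[b]
                dx = traj.xy[f, i, 0] - traj.xy[f, j, 0]
                dy = traj.xy[f, i, 1] - traj.xy[f, j, 1]
                dx -= Lx * round(dx / Lx)
                dy -= Ly * round(dy / Ly)
                d = math.hypot(dx, dy)
                if d >= max_distance:
                    continue
                k = int(d // bin_width)
                dot = float(np.dot(traj.axes[f, i], traj.axes[f, j]))
                if estimator == "p2":
                    dot = 1.5 * dot**2 - 0.5
                sums[k] += dot
                counts[k] += 1
    return [s / c if c else None for s, c in zip(sums, counts)], counts


class TestSelectInterface:
    def test_rotor_default_selects_topmost_layer(self, chol_run):
        _, _, traj, _ = chol_run
        sel = ori.select_interface(traj)
        assert sel.size == 128
        assert np.all(traj.layer[sel] == 3)

    def test_cutoff_spanning_everything_selects_all(self):
        rng = np.random.default_rng(1)
        axes = rng.standard_normal((1, 10, 3))
        traj = make_trajectory(axes)
        traj.head_z[0] = rng.uniform(0, 5, 10)
        assert ori.select_interface(traj, cutoff=100.0).size == 10

    def test_selection_frozen_at_reference_frame(self):
        axes = np.tile([0.0, 0.0, 1.0], (2, 4, 1))
        traj = make_trajectory(axes)
        traj.head_z[0] = np.array([1.0, 1.0, 5.0, 5.0])
        traj.head_z[1] = np.array([5.0, 5.0, 1.0, 1.0])  # molecules swap z
        sel = ori.select_interface(traj, cutoff=0.5)
        assert set(sel) == {2, 3}


class TestTiltAngles:
    @pytest.mark.parametrize("axis,expected",
                             [((0, 0, 1), 0.0), ((1, 0, 0), 90.0),
                              ((0, 0, -1), 180.0)])
    def test_reference_directions(self, axis, expected):
        traj = make_trajectory(np.array([[axis]], dtype=float))
        ang = ori.tilt_angles(traj, np.array([0]))
        assert ang[0, 0] == pytest.approx(expected)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000), phi=st.floats(0.0, 2 * math.pi))
    def test_invariant_under_rotation_about_z(self, seed, phi):
        rng = np.random.default_rng(seed)
        axes = rng.standard_normal((1, 6, 3))
        traj = make_trajectory(axes)
        c, s = math.cos(phi), math.sin(phi)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        rotated = make_trajectory(axes @ R.T)
        sel = np.arange(6)
        assert np.allclose(ori.tilt_angles(traj, sel),
                           ori.tilt_angles(rotated, sel), atol=1e-9)


class TestOrientationCorrelation:
    def test_aligned_configuration_is_one_everywhere(self):
        axes = np.tile([0.0, 0.0, 1.0], (2, 12, 1))
        traj = make_trajectory(axes)
        curve = ori.orientation_correlation(traj, np.arange(12), 0.2, 4.0)
        ok = curve.pair_counts > 0
        assert ok.any()
        assert np.allclose(curve.values[ok], 1.0)

    def test_independent_axes_decorrelated(self):
        rng = np.random.default_rng(42)
        axes = rng.standard_normal((40, 30, 3))
        traj = make_trajectory(axes)
        curve = ori.orientation_correlation(traj, np.arange(30), 1.0, 5.0)
        ok = curve.pair_counts > 0
        bound = 3.0 / np.sqrt(curve.pair_counts[ok])
        assert np.all(np.abs(curve.values[ok]) < bound)

    @pytest.mark.parametrize("estimator", ["dot", "p2"])
    def test_matches_brute_force_oracle(self, estimator):
        rng = np.random.default_rng(7)
        axes = rng.standard_normal((5, 10, 3))
        traj = make_trajectory(axes, box=(6.0, 6.0, 50.0))
        traj.xy[:] = rng.uniform(0, 6.0, (10, 2))[None]
        sel = np.arange(10)
        curve = ori.orientation_correlation(traj, sel, 0.5, 3.0,
                                            estimator=estimator)
        oracle_vals, oracle_counts = brute_force_correlation(
            traj, sel, 0.5, 3.0, estimator)
        assert np.array_equal(curve.pair_counts,
                              np.array(oracle_counts, dtype=float))
        for v, o in zip(curve.values, oracle_vals):
            if o is None:
                assert np.isnan(v)
            else:
                assert v == pytest.approx(o, abs=1e-12)

    def test_empty_bins_flagged_not_zero(self):
        axes = np.tile([0.0, 0.0, 1.0], (1, 2, 1))
        traj = make_trajectory(axes)
        traj.xy[:] = np.array([[0.5, 0.5], [1.0, 0.5]])
        curve = ori.orientation_correlation(traj, np.arange(2), 0.1, 2.0)
        assert curve.empty_bins.size > 0
        assert np.isnan(curve.values[curve.empty_bins]).all()

    def test_bounds(self, chol_run):
        _, _, traj, _ = chol_run
        sel = ori.select_interface(traj)
        curve = ori.orientation_correlation(traj, sel, 0.1, 3.0)
        ok = curve.pair_counts > 0
        assert np.all(np.abs(curve.values[ok]) <= 1.0 + 1e-12)


class TestDecayDistance:
    @pytest.mark.parametrize("xi", [0.3, 0.5, 1.0, 2.0])
    def test_recovers_exponential_length(self, xi):
        centers = np.arange(0.05, 6.0, 0.1)
        curve = ori.CorrelationCurve(centers, np.exp(-centers / xi),
                                     np.zeros_like(centers),
                                     np.ones_like(centers))
        dec = ori.decay_distance(curve)
        assert not dec.censored
        # threshold is 1/e of the *first bin*, so expect first_bin + xi
        assert abs(dec.distance - (centers[0] + xi)) < 0.1

    def test_constant_curve_censored(self):
        centers = np.arange(0.05, 3.0, 0.1)
        curve = ori.CorrelationCurve(centers, np.full_like(centers, 0.7),
                                     np.zeros_like(centers),
                                     np.ones_like(centers))
        dec = ori.decay_distance(curve)
        assert dec.censored
        assert math.isinf(dec.distance)


class TestInterfaceZRmsd:
    def test_static_trajectory_zero(self):
        axes = np.tile([0.0, 0.0, 1.0], (4, 5, 1))
        traj = make_trajectory(axes)
        fl = ori.interface_z_rmsd(traj, np.arange(5))
        assert np.allclose(fl.rmsd, 0.0)

    def test_rigid_shift_gives_shift(self):
        axes = np.tile([0.0, 0.0, 1.0], (2, 5, 1))
        traj = make_trajectory(axes)
        traj.head_z[1] += 0.7
        fl = ori.interface_z_rmsd(traj, np.arange(5))
        assert fl.rmsd[1] == pytest.approx(0.7)

    def test_sem_across_trajectories(self):
        axes = np.tile([0.0, 0.0, 1.0], (3, 4, 1))
        t1 = make_trajectory(axes)
        t2 = make_trajectory(axes)
        t2.head_z[1:] += 0.5
        fl = ori.interface_z_rmsd([t1, t2], np.arange(4))
        assert fl.rmsd[1] == pytest.approx(0.25)
        assert fl.sem[1] > 0


class TestDetectFlips:
    def _scripted(self, angle_series):
        """Single-molecule trajectory following a scripted tilt series."""
        F = len(angle_series)
        axes = np.zeros((F, 1, 3))
        for f, ang in enumerate(angle_series):
            rad = math.radians(ang)
            axes[f, 0] = [math.sin(rad), 0.0, math.cos(rad)]
        return make_trajectory(axes)

    def test_single_recovery_event(self):
        traj = self._scripted([170, 150, 130, 110, 90, 70, 50, 20])
        ev = ori.detect_flips(traj, np.array([0]))
        ups = [e for e in ev.events if e.direction == "down_to_up"]
        assert len(ups) == 1
        assert ev.recovered_fraction == 1.0

    def test_oscillation_inside_hysteresis_band_ignored(self):
        traj = self._scripted([170, 119, 61, 119, 61, 119, 61])
        ev = ori.detect_flips(traj, np.array([0]))
        assert len(ev.events) == 0
        assert ev.recovered_fraction == 0.0

    def test_budget_limits_recovery(self):
        traj = self._scripted([170, 170, 170, 170, 170, 20])
        ev = ori.detect_flips(traj, np.array([0]), budget_frames=3)
        assert ev.recovered_fraction == 0.0

    def test_inverted_thresholds_rejected(self):
        traj = self._scripted([10, 20])
        with pytest.raises(ValueError):
            ori.detect_flips(traj, np.array([0]), aligned_threshold=120.0,
                             reverted_threshold=60.0)
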