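"""Kinematic and proximal force/torque metrics against closed forms and
geometric invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cathskill.proximal_metrics import (
    MetricError,
    PROXIMAL_METRICS,
    accel_stats,
    compute_proximal_metrics,
    directional_means,
    displacement_peaks,
    path_length,
    phase_max_summary,
    records_to_frame,
    smoothness,
    speed_stats,
)
from cathskill.trial_model import segment, synchronize

DT = 1 / 25.0


def _times(n):
    return np.arange(n) * DT


def _line(n, speed, direction=(1.0, 0.0, 0.0)):
    d = np.asarray(direction) / np.linalg.norm(direction)
    return np.outer(speed * _times(n), d)


class TestSpeedAccel:
    def test_constant_speed_line(self):
        pos = _line(251, 10.0)
        med, mx = speed_stats(pos, _times(251))
        assert med == pytest.approx(10.0)
        assert mx == pytest.approx(10.0)

    def test_stationary_tip(self):
        pos = np.zeros((100, 3))
        assert speed_stats(pos, _times(100)) == (0.0, 0.0)
        med_a, max_a = accel_stats(pos, _times(100))
        assert (med_a, max_a) == (0.0, 0.0)

    def test_sinusoid_max_speed_matches_derivative(self):
        A, omega = 20.0, 2 * np.pi * 0.5
        t = _times(2501)
        pos = np.column_stack([A * np.sin(omega * t), 0 * t, 0 * t])
        _, mx = speed_stats(pos, t)
        assert mx == pytest.approx(A * omega, rel=0.01)

    def test_sinusoid_max_accel(self):
        A, omega = 20.0, 2 * np.pi * 0.5
        t = _times(2501)
        pos = np.column_stack([A * np.sin(omega * t), 0 * t, 0 * t])
        _, mx = accel_stats(pos, t)
        assert mx == pytest.approx(A * omega**2, rel=0.02)

    def test_constant_acceleration_from_rest(self):
        a = 5.0
        t = _times(2501)
        pos = np.column_stack([0.5 * a * t**2, 0 * t, 0 * t])
        med, mx = accel_stats(pos, t)
        assert med == pytest.approx(a, rel=0.01)
        assert mx == pytest.approx(a, rel=0.01)

    def test_too_few_samples(self):
        with pytest.raises(MetricError):
            speed_stats(np.zeros((2, 3)), _times(2))
        with pytest.raises(MetricError):
            accel_stats(np.zeros((3, 3)), _times(3))


class TestSmoothness:
    def test_constant_speed_is_zero(self):
        # binary-exact steps: the speed sequence is constant to the last bit
        pos = np.outer(np.arange(500.0), [0.25, 0.0, 0.5])
        assert smoothness(pos, _times(500)) == 0.0

    def test_single_speed_step(self):
        # speed 2 mm/s then 5 mm/s: one slope change of 3 mm/s
        t = _times(200)
        x = np.where(t < 100 * DT, 2.0 * t, 2.0 * 100 * DT + 5.0 * (t - 100 * DT))
        pos = np.column_stack([x, 0 * t, 0 * t])
        assert smoothness(pos, t) == pytest.approx(3.0 / DT)

    def test_additivity_in_step_count(self):
        t = _times(400)
        one, two = [], []
        for steps in (1, 2):
            x = np.zeros_like(t)
            v = 2.0
            dx = np.full_like(t, v * DT)
            for k in range(steps):
                dx[(k + 1) * 100 :] += 3.0 * DT  # each step adds 3 mm/s
            x = np.concatenate([[0], np.cumsum(dx[:-1])])
            pos = np.column_stack([x, 0 * t, 0 * t])
            (one if steps == 1 else two).append(smoothness(pos, t))
        assert two[0] == pytest.approx(2 * one[0])


class TestDisplacementPeaks:
    def test_monotone_advance_has_no_peaks(self):
        assert displacement_peaks(_line(500, 5.0), _times(500)) == 0

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_counts_triangular_retractions(self, k):
        # advance at 5 mm/s with k triangular retractions of depth 5 mm
        t = _times(1500)
        v = np.full_like(t, 5.0)
        for i in range(k):
            t0 = 5.0 + 10.0 * i
            v[(t >= t0) & (t < t0 + 1.0)] = -5.0
            v[(t >= t0 + 1.0) & (t < t0 + 2.0)] = 5.0
        x = np.concatenate([[0], np.cumsum(v[:-1]) * DT])
        pos = np.column_stack([x, 0 * t, 0 * t])
        assert displacement_peaks(pos, t, prominence_mm=1.0) == k

    def test_sub_prominence_retraction_ignored(self):
        t = _times(1500)
        v = np.full_like(t, 5.0)
        v[(t >= 5.0) & (t < 5.1)] = -5.0  # 0.5 mm dip
        v[(t >= 5.1) & (t < 5.2)] = 5.0
        x = np.concatenate([[0], np.cumsum(v[:-1]) * DT])
        pos = np.column_stack([x, 0 * t, 0 * t])
        assert displacement_peaks(pos, t, prominence_mm=1.0) == 0


class TestPathLength:
    def test_straight_segment_any_sampling(self):
        pos = _line(77, 10.0)
        endpoints = np.linalg.norm(pos[-1] - pos[0])
        assert path_length(pos) == pytest.approx(endpoints)

    def test_closed_square(self):
        sq = np.array(
            [[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0], [0, 0, 0]], float
        )
        assert path_length(sq) == pytest.approx(40.0)

    def test_semicircle_arc_length(self):
        r = 50.0
        theta = np.linspace(0, np.pi, 2000)
        pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), 0 * theta])
        assert path_length(pos) == pytest.approx(np.pi * r, rel=1e-3)

    def test_triangle_inequality_vs_endpoints(self, rng):
        pos = rng.normal(size=(300, 3)).cumsum(axis=0)
        assert path_length(pos) >= np.linalg.norm(pos[-1] - pos[0])


class TestDirectionalMeans:
    def test_mixed_signs(self):
        assert directional_means([1.0, 1.0, -2.0]) == (1.0, 2.0)

    def test_all_positive(self):
        assert directional_means([2.0, 4.0]) == (3.0, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=30))
    def test_antisymmetry(self, xs):
        x = np.asarray(xs)
        p, n = directional_means(x)
        p2, n2 = directional_means(-x)
        assert (p, n) == pytest.approx((n2, p2))


class TestRigidMotionInvariance:
    def test_metrics_invariant_to_rotation_and_translation(self, rng):
        t = _times(400)
        pos = rng.normal(size=(400, 3)).cumsum(axis=0)
        from scipy.spatial.transform import Rotation

        R = Rotation.random(rng=rng).as_matrix()
        moved = pos @ R.T + np.array([5.0, -3.0, 11.0])
        assert speed_stats(moved, t) == pytest.approx(speed_stats(pos, t))
        assert accel_stats(moved, t) == pytest.approx(accel_stats(pos, t))
        assert path_length(moved) == pytest.approx(path_length(pos))
        assert smoothness(moved, t) == pytest.approx(smoothness(pos, t))


class TestComputeProximalMetrics:
    def test_record_cardinality_and_time_partition(self, proximal_lra_synced):
        trial = proximal_lra_synced[0]
        records = compute_proximal_metrics(trial)
        assert len(records) == 36  # 12 metrics x 3 phases
        frame = records_to_frame(records)
        times = frame.loc[frame.metric == "phase_time", "value"]
        assert times.sum() == pytest.approx(trial.duration)
        assert set(frame.metric) == set(PROXIMAL_METRICS)

    def test_missing_channel_named_in_error(self, distal_cohort_synced):
        # a distal trial has no tip_position channel
        with pytest.raises(MetricError, match="tip_position"):
            compute_proximal_metrics(distal_cohort_synced[0])

    def test_smoothing_flag_reduces_jitter_metrics(self, proximal_lra_synced):
        trial = proximal_lra_synced[0]
        raw = records_to_frame(compute_proximal_metrics(trial))
        smoothed = records_to_frame(
            compute_proximal_metrics(trial, smooth_window=5)
        )
        for metric in ("smoothness", "max_accel"):
            r = raw.loc[raw.metric == metric, "value"].sum()
            s = smoothed.loc[smoothed.metric == metric, "value"].sum()
            assert s < r

    def test_peak_and_smoothness_grow_with_reversals(self, profiles):
        import dataclasses

        from cathskill.synthetic_cohort import generate_trial

        expert, _ = profiles
        counts, smooths = [], []
        for rate in (0.0, 0.2, 0.6):
            p = dataclasses.replace(
                expert, reversal_rate_per_s=rate, position_noise_sd_mm=0.0
            )
            t = synchronize(
                generate_trial("LRA", p, (40, 30, 30), "proximal", seed=77)
            )
            ch = t.channels["tip_position"]
            counts.append(displacement_peaks(ch.values, ch.timestamps))
            smooths.append(smoothness(ch.values, ch.timestamps))
        assert counts == sorted(counts)
        assert smooths == sorted(smooths)


class TestPhaseMaxSummary:
    def test_single_trial_per_group_is_own_max(self, proximal_lra_synced):
        exp = next(t for t in proximal_lra_synced if t.skill == "expert")
        nov = next(t for t in proximal_lra_synced if t.skill == "novice")
        tab = phase_max_summary([exp, nov], "axial_force")
        seg = segment(exp)
        ch = exp.channels["axial_force"]
        m = seg.mask(ch.timestamps, "A")
        got = tab.loc[(tab.skill == "expert") & (tab.phase == "A"), "mean_of_max"]
        assert float(got.iloc[0]) == pytest.approx(np.abs(ch.values[m]).max())

    def test_mean_of_two_trials(self, proximal_lra_synced):
        trials = [t for t in proximal_lra_synced if t.skill == "novice"][:2]
        tab = phase_max_summary(trials, "torque")
        per_trial = []
        for t in trials:
            seg = segment(t)
            ch = t.channels["torque"]
            per_trial.append(np.abs(ch.values[seg.mask(ch.timestamps, "B")]).max())
        got = tab.loc[(tab.skill == "novice") & (tab.phase == "B"), "mean_of_max"]
        assert float(got.iloc[0]) == pytest.approx(np.mean(per_trial))
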