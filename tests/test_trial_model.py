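"""Trial data model: I/O round trips, synchronization, segmentation,
pivot calibration and tip-offset correction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cathskill.trial_model import (
    PhaseSegmentation,
    PivotPose,
    TimeSeriesChannel,
    Trial,
    ValidationError,
    apply_tip_offset,
    pivot_calibrate,
    read_trial,
    segment,
    synchronize,
    write_trial,
)


def _make_trial(span=60.0, bounds=(20.0, 40.0), rng=None):
    rng = rng or np.random.default_rng(7)
    t25 = np.arange(int(span * 25) + 1) / 25
    t40 = np.arange(int(span * 40) + 1) / 40
    channels = {
        "axial_force": TimeSeriesChannel(
            "axial_force", "N", t25, rng.normal(size=t25.size), 25.0
        ),
        "torque": TimeSeriesChannel(
            "torque", "N·mm", t25, rng.normal(size=t25.size), 25.0
        ),
        "tip_position": TimeSeriesChannel(
            "tip_position", "mm", t40, rng.normal(size=(t40.size, 3)), 40.0
        ),
    }
    return Trial("T001", "E01", "expert", "LRA", "proximal", channels, bounds)


class TestChannelAndTrialInvariants:
    def test_non_monotone_timestamps_rejected(self):
        with pytest.raises(ValidationError, match="bad_chan"):
            TimeSeriesChannel("bad_chan", "N", [0.0, 0.1, 0.1], [1.0, 2.0, 3.0])

    def test_sample_count_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            TimeSeriesChannel("f", "N", [0.0, 0.1], [1.0, 2.0, 3.0])

    def test_missing_required_channel_rejected(self):
        trial = _make_trial()
        channels = {k: v for k, v in trial.channels.items() if k != "torque"}
        with pytest.raises(ValidationError, match="torque"):
            Trial("T", "E01", "expert", "LRA", "proximal", channels, (20, 40))

    def test_bounds_outside_span_rejected(self):
        with pytest.raises(ValidationError, match="phase bounds"):
            _make_trial(bounds=(20.0, 70.0))
        with pytest.raises(ValidationError, match="phase bounds"):
            _make_trial(bounds=(40.0, 20.0))


class TestRoundTrip:
    def test_write_read_bit_exact(self, tmp_path, rng):
        trial = _make_trial(rng=rng)
        manifest = write_trial(trial, tmp_path)
        back = read_trial(manifest)
        assert back.trial_id == trial.trial_id
        assert back.skill == trial.skill
        assert back.phase_bounds == trial.phase_bounds
        assert set(back.channels) == set(trial.channels)
        for name, ch in trial.channels.items():
            np.testing.assert_array_equal(back.channels[name].timestamps, ch.timestamps)
            np.testing.assert_array_equal(back.channels[name].values, ch.values)
            assert back.channels[name].unit == ch.unit

    def test_csv_per_channel_plus_manifest(self, tmp_path):
        trial = _make_trial()
        write_trial(trial, tmp_path)
        assert len(list(tmp_path.glob("*.csv"))) == 3
        assert len(list(tmp_path.glob("*.json"))) == 1

    def test_missing_channel_file_errors(self, tmp_path):
        trial = _make_trial()
        manifest = write_trial(trial, tmp_path)
        next(tmp_path.glob("*_torque.csv")).unlink()
        with pytest.raises(FileNotFoundError):
            read_trial(manifest)


class TestSynchronize:
    def test_common_clock_sample_count(self):
        trial = _make_trial(span=10.0, bounds=(3.0, 7.0))
        synced = synchronize(trial, 25.0)
        for ch in synced.channels.values():
            assert ch.n_samples == 251
        clocks = [ch.timestamps for ch in synced.channels.values()]
        for c in clocks[1:]:
            np.testing.assert_array_equal(c, clocks[0])

    def test_linear_ramp_interpolated_exactly(self):
        # linear interpolation reproduces a linear function exactly
        trial = _make_trial(span=10.0, bounds=(3.0, 7.0))
        t40 = trial.channels["tip_position"].timestamps
        ramp = np.column_stack([2.0 * t40, -t40, 0.5 * t40 + 1])
        trial.channels["tip_position"] = TimeSeriesChannel(
            "tip_position", "mm", t40, ramp, 40.0
        )
        synced = synchronize(trial, 25.0)
        ch = synced.channels["tip_position"]
        expect = np.column_stack(
            [2.0 * ch.timestamps, -ch.timestamps, 0.5 * ch.timestamps + 1]
        )
        np.testing.assert_allclose(ch.values, expect, atol=1e-12)

    def test_channel_at_target_rate_unchanged(self):
        trial = _make_trial(span=10.0, bounds=(3.0, 7.0))
        synced = synchronize(trial, 25.0)
        np.testing.assert_array_equal(
            synced.channels["axial_force"].values,
            trial.channels["axial_force"].values[:251],
        )

    def test_idempotent(self):
        trial = _make_trial(span=10.0, bounds=(3.0, 7.0))
        once = synchronize(trial, 25.0)
        twice = synchronize(once, 25.0)
        for name in trial.channels:
            np.testing.assert_array_equal(
                once.channels[name].values, twice.channels[name].values
            )
            np.testing.assert_array_equal(
                once.channels[name].timestamps, twice.channels[name].timestamps
            )

    def test_no_overlap_errors(self):
        trial = _make_trial()
        t = trial.channels["axial_force"]
        trial.channels["axial_force"] = TimeSeriesChannel(
            "axial_force", "N", t.timestamps + 59.9, t.values, 25.0
        )
        # channels overlap for only 0.1 s
        with pytest.raises(ValidationError, match="overlap"):
            synchronize(Trial("T", "E01", "expert", "LRA", "proximal",
                              trial.channels, (59.92, 59.95)), 25.0)


class TestSegmentation:
    def test_three_contiguous_phases(self):
        trial = _make_trial(span=60.0, bounds=(10.0, 25.0))
        seg = segment(trial)
        assert seg.intervals["A"] == (0.0, 10.0)
        assert seg.intervals["B"] == (10.0, 25.0)
        assert seg.intervals["C"][0] == 25.0

    def test_masks_partition_samples(self):
        trial = _make_trial(span=60.0, bounds=(10.0, 25.0))
        seg = segment(trial)
        ts = trial.channels["axial_force"].timestamps
        total = sum(seg.mask(ts, p).sum() for p in "ABC")
        assert total == ts.size

    def test_empty_phase_rejected(self):
        with pytest.raises(ValidationError):
            PhaseSegmentation({"A": (0, 0), "B": (0, 25), "C": (25, 60)})


class TestPivotCalibration:
    @staticmethod
    def _poses(n, t_true, c, noise_sd, rng):
        poses = []
        for _ in range(n):
            R = Rotation.random(rng=rng).as_matrix()
            p = c - R @ t_true
            if noise_sd:
                p = p + rng.normal(0.0, noise_sd, 3)
            poses.append(PivotPose(R, p))
        return poses

    def test_noise_free_exact_recovery(self, rng):
        t_true = np.array([0.0, 0.0, 3.6])
        c = np.array([12.0, -5.0, 30.0])
        offset, pivot, rms = pivot_calibrate(self._poses(10, t_true, c, 0.0, rng))
        np.testing.assert_allclose(offset, t_true, atol=1e-9)
        np.testing.assert_allclose(pivot, c, atol=1e-9)
        assert rms < 1e-9

    def test_noisy_recovery_within_tenth_mm(self, rng):
        t_true = np.array([0.0, 0.0, 3.6])
        c = np.array([12.0, -5.0, 30.0])
        offset, _, rms = pivot_calibrate(self._poses(800, t_true, c, 0.3, rng))
        assert np.linalg.norm(offset - t_true) < 0.1
        assert rms > 0

    def test_residual_grows_with_noise(self, rng):
        t_true = np.array([1.0, -2.0, 3.6])
        c = np.zeros(3)
        rmss = []
        for sd in (0.0, 0.1, 0.3, 1.0):
            sub = np.random.default_rng(99)
            _, _, rms = pivot_calibrate(self._poses(200, t_true, c, sd, sub))
            rmss.append(rms)
        assert rmss == sorted(rmss)

    def test_identical_rotations_rank_deficient(self):
        R = np.eye(3)
        poses = [PivotPose(R, np.array([1.0, 2.0, 3.0])),
                 PivotPose(R, np.array([1.1, 2.0, 3.0])),
                 PivotPose(R, np.array([0.9, 2.1, 3.0]))]
        with pytest.raises(ValidationError, match="rank"):
            pivot_calibrate(poses)

    def test_too_few_poses(self, rng):
        poses = self._poses(2, np.array([0, 0, 3.6]), np.zeros(3), 0.0, rng)
        with pytest.raises(ValidationError):
            pivot_calibrate(poses)


class TestApplyTipOffset:
    @staticmethod
    def _line_trial():
        trial = _make_trial(span=10.0, bounds=(3.0, 7.0))
        t40 = trial.channels["tip_position"].timestamps
        direction = np.array([1.0, 2.0, 2.0]) / 3.0
        pos = np.outer(5.0 * t40, direction)
        trial.channels["tip_position"] = TimeSeriesChannel(
            "tip_position", "mm", t40, pos, 40.0
        )
        return trial, direction

    def test_zero_offset_identity(self):
        trial, _ = self._line_trial()
        out = apply_tip_offset(trial, 0.0)
        np.testing.assert_array_equal(
            out.channels["tip_position"].values,
            trial.channels["tip_position"].values,
        )

    def test_straight_line_shifted_along_line(self):
        trial, direction = self._line_trial()
        out = apply_tip_offset(trial, 3.6)
        shift = out.channels["tip_position"].values - trial.channels[
            "tip_position"
        ].values
        np.testing.assert_allclose(shift, np.tile(3.6 * direction, (shift.shape[0], 1)),
                                   atol=1e-9)

    def test_offset_then_inverse_recovers(self):
        trial, _ = self._line_trial()
        fwd = apply_tip_offset(trial, 3.6)
        back = apply_tip_offset(fwd, -3.6)
        np.testing.assert_allclose(
            back.channels["tip_position"].values,
            trial.channels["tip_position"].values,
            atol=1e-9,
        )

    def test_orientation_form(self, rng):
        trial, _ = self._line_trial()
        n = trial.channels["tip_position"].n_samples
        Rs = Rotation.random(n, rng=rng).as_matrix()
        off = np.array([0.0, 0.0, 3.6])
        out = apply_tip_offset(trial, off, orientations=Rs)
        expect = trial.channels["tip_position"].values + np.einsum(
            "nij,j->ni", Rs, off
        )
        np.testing.assert_allclose(out.channels["tip_position"].values, expect)
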