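"""Filtering, velocity, phase segmentation and DTW motor noise."""

import numpy as np
import pytest
from scipy.signal import butter, filtfilt

from motorstrat.kinematics import (
    MARKERS,
    SegmentBoundaries,
    TrialTrajectory,
    UnsegmentableTrial,
    dtw_distance,
    extract_segment,
    lowpass_filter,
    motor_noise,
    pairwise_dtw_matrix,
    score_subject,
    segment_phases,
    tangential_velocity,
)
from motorstrat.synthetic import (
    MINJERK_DP_TAU,
    KinematicSimConfig,
    minimum_jerk,
    simulate_reach_to_drop,
)

from _oracles import dtw_bruteforce


def _traj(data, fs=60.0):
    return TrialTrajectory("T", 1, data, fs)


# ---------------------------------------------------------------------------
# filtering


class TestLowpassFilter:
    def test_constant_signal_unchanged(self):
        t = _traj(np.full((60, 12), 5.0))
        out = lowpass_filter(t)
        np.testing.assert_allclose(out.data, t.data, atol=1e-9)

    @pytest.mark.parametrize(
        "freq, rel_tol",
        [(20.0, 0.05), (1.0, 0.02)],
    )
    def test_sinusoid_gain_matches_butterworth_magnitude(self, freq, rel_tol):
        # forward-backward 5th-order 8 Hz filter: |H(f)|^2 = 1/(1+(f/8)^10)
        fs, n = 60.0, 600
        tt = np.arange(n) / fs
        sig = np.sin(2 * np.pi * freq * tt)
        data = np.tile(sig[:, None], (1, 12))
        out = lowpass_filter(_traj(data), cutoff=8.0, order=5)
        mid = out.data[n // 4 : 3 * n // 4, 0]
        gain = mid.std() / sig[n // 4 : 3 * n // 4].std()
        expected = 1.0 / (1.0 + (freq / 8.0) ** 10)
        assert gain == pytest.approx(expected, rel=rel_tol, abs=1e-3)

    def test_short_trial_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            lowpass_filter(_traj(np.random.default_rng(0).normal(size=(15, 12))))

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError, match="sample rate"):
            lowpass_filter(_traj(np.zeros((60, 12)), fs=15.0))


# ---------------------------------------------------------------------------
# velocity


class TestTangentialVelocity:
    def test_uniform_motion_speed(self):
        data = np.zeros((40, 12))
        data[:, 3] = np.arange(40)  # wrist_ulnar x advances 1 mm/frame
        v = tangential_velocity(_traj(data))
        np.testing.assert_allclose(v.speed, 60.0)

    def test_stationary_marker(self):
        v = tangential_velocity(_traj(np.ones((30, 12))))
        np.testing.assert_allclose(v.speed, 0.0)

    def test_minimum_jerk_peak_speed(self):
        # peak speed of a minimum-jerk reach = 1.875 * A / T at tau = 0.5
        A, T, fs = 300.0, 1.0, 60.0
        n = int(T * fs)
        path = minimum_jerk(np.zeros(3), np.array([A, 0, 0]), n + 1)
        data = np.tile(path, (1, 4))
        v = tangential_velocity(_traj(data))
        assert v.speed.max() == pytest.approx(1.875 * A / T, rel=0.02)
        assert np.argmax(v.speed) == pytest.approx(n / 2, abs=1)


# ---------------------------------------------------------------------------
# segmentation


class TestSegmentPhases:
    def test_deceleration_peak_on_analytic_reach(self, noiseless_trials):
        t = lowpass_filter(noiseless_trials[0])
        b = segment_phases(tangential_velocity(t), t)
        n_reach = 60  # 1.0 s reach at 60 Hz
        assert b.deceleration_peak_frame == pytest.approx(MINJERK_DP_TAU * n_reach, abs=2)
        assert b.deceleration_peak_frame < b.reach_end_frame < b.trial_end_frame

    def test_grasp_at_interpeak_minimum(self, noiseless_trials):
        t = lowpass_filter(noiseless_trials[0])
        b = segment_phases(tangential_velocity(t), t)
        # generator dwells 2 frames at the ball: grasp within the dwell
        assert b.reach_end_frame == pytest.approx(61, abs=2)

    def test_monotone_speed_flagged_unsegmentable(self):
        data = np.zeros((60, 12))
        data[:, 3] = np.arange(60) ** 2  # ever-accelerating
        t = _traj(data)
        with pytest.raises(UnsegmentableTrial):
            segment_phases(tangential_velocity(t), t)

    def test_boundary_ordering_enforced(self):
        with pytest.raises(ValueError):
            SegmentBoundaries(deceleration_peak_frame=50, reach_end_frame=40, trial_end_frame=100)

    def test_segments_tile_the_trial(self, noiseless_trials):
        t = lowpass_filter(noiseless_trials[0])
        b = segment_phases(tangential_velocity(t), t)
        ff = extract_segment(t, b, "reach_feedforward")
        fb = extract_segment(t, b, "reach_feedback")
        drop = extract_segment(t, b, "drop")
        assert len(ff) + len(fb) + len(drop) == t.n_frames + 2  # shared boundary frames


# ---------------------------------------------------------------------------
# DTW


class TestDtw:
    def test_identity_and_symmetry(self, rng):
        a = rng.normal(size=(30, 12))
        b = rng.normal(size=(25, 12))
        assert dtw_distance(a, a) == 0.0
        assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a), abs=1e-12)

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(100):
            n, m = rng.integers(2, 7, size=2)
            d = int(rng.integers(1, 13))
            a, b = rng.normal(size=(n, d)), rng.normal(size=(m, d))
            assert dtw_distance(a, b) == pytest.approx(dtw_bruteforce(a, b), abs=1e-9)

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dtw_distance(np.empty((0, 12)), np.zeros((5, 12)))

    def test_time_dilation_robustness(self, noiseless_trials):
        # normalisation keeps the score nearly invariant to uniform 2x resampling
        cfg = KinematicSimConfig(seed=9, duration_jitter=0.0)
        trials = simulate_reach_to_drop(cfg, 2.0, "DIL")
        mats = [t.data for t in trials]
        up = [np.repeat(m, 2, axis=0) for m in mats]
        d1 = np.median(pairwise_dtw_matrix(mats)[np.triu_indices(10, 1)])
        d2 = np.median(pairwise_dtw_matrix(up)[np.triu_indices(10, 1)])
        assert abs(d2 - d1) / d1 < 0.10

    def test_whole_cost_bounds_segment_costs(self, rng):
        # cumulative (unnormalised) cost of the whole series dominates any prefix
        a = rng.normal(size=(40, 12)).cumsum(axis=0)
        b = rng.normal(size=(40, 12)).cumsum(axis=0)
        whole = dtw_distance(a, b, normalize=False)
        prefix = dtw_distance(a[:20], b[:20], normalize=False)
        assert whole >= prefix - 1e-9


class TestMotorNoise:
    def test_identical_trials_score_zero(self, noiseless_trials):
        mats = [t.data for t in noiseless_trials]
        assert motor_noise(mats, "Z").value == 0.0

    def test_translation_invariance_and_single_trial_sensitivity(self, rng):
        cfg = KinematicSimConfig(seed=5)
        trials = simulate_reach_to_drop(cfg, 1.0, "TR")
        mats = [t.data for t in trials]
        base = motor_noise(mats, "TR").value
        shifted_all = [m + 50.0 for m in mats]
        assert motor_noise(shifted_all, "TR").value == pytest.approx(base, abs=1e-9)
        one_off = [m.copy() for m in mats]
        one_off[0] = one_off[0] + 50.0
        assert motor_noise(one_off, "TR").value > base

    def test_incomplete_subject_excluded(self, noiseless_trials):
        with pytest.raises(ValueError, match="excluded"):
            motor_noise([t.data for t in noiseless_trials[:9]], "NINE")

    def test_score_subject_flags_unsegmentable_phases(self, noiseless_trials):
        # corrupt one trial into a monotone movement: whole still scored,
        # phase segments flagged rather than silently dropped
        trials = list(noiseless_trials)
        bad = np.zeros((80, 12))
        bad[:, 3] = np.arange(80) ** 2
        trials[4] = TrialTrajectory("NOISELESS", 5, bad, 60.0)
        res = score_subject(trials)
        assert "whole" in res.scores
        assert "reach_feedforward" in res.excluded_segments
        assert "unsegmentable" in res.excluded_segments["reach_feedforward"]
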