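import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from fixkit.affine import NormalizedPupilTrace
from fixkit.io import DEFAULT_EYE_MAP, LandmarkFrame
from fixkit.segment import (
    FixationSegmenter,
    ThresholdSearchConfig,
    binocular_mean,
    compute_ear,
    default_min_fix_frames,
    estimate_threshold,
    fixation_ratio_at,
    moving_average,
    pupil_displacement,
    valid_mask,
)
from fixkit.simulate import GazeSimConfig, simulate_recording


def make_trace(left, valid=None):
    left = np.asarray(left, dtype=float)
    T = left.shape[0]
    v = np.ones(T, bool) if valid is None else np.asarray(valid, bool)
    return NormalizedPupilTrace(
        frame_index=np.arange(T), left=left, right=left.copy(),
        valid_left=v, valid_right=v.copy(),
    )


class TestDisplacement:
    def test_stationary_pupil_zero(self):
        d = pupil_displacement(make_trace(np.tile([0.5, 0.5], (10, 1))), "left")
        assert np.isnan(d[0])
        np.testing.assert_array_equal(d[1:], 0.0)

    def test_pythagorean_step(self):
        d = pupil_displacement(make_trace([[0, 0], [0.3, 0.4]]), "left")
        assert d[1] == pytest.approx(0.5)

    def test_matches_pairwise_oracle_on_random_walk(self, rng):
        pos = np.cumsum(rng.normal(0, 0.01, (50, 2)), axis=0)
        d = pupil_displacement(make_trace(pos), "left")
        for t in range(1, 50):
            expect = np.sqrt((pos[t, 0] - pos[t - 1, 0]) ** 2 + (pos[t, 1] - pos[t - 1, 1]) ** 2)
            assert d[t] == pytest.approx(expect, abs=1e-15)

    def test_invalid_endpoints_undefined(self):
        valid = np.array([True, False, True, True])
        d = pupil_displacement(make_trace(np.zeros((4, 2)), valid), "left")
        assert np.isnan(d[1]) and np.isnan(d[2]) and d[3] == 0.0


class TestMovingAverage:
    def test_q_from_fps(self):
        np.testing.assert_allclose(moving_average(np.full(9, 4.2), fps=30.0), 4.2, rtol=1e-12)
        # fps=90 -> q=3 -> window 7
        out = moving_average(np.arange(9.0), fps=90.0)
        assert out[4] == pytest.approx(np.arange(1, 8).mean())

    def test_simple_window(self):
        out = moving_average([0.0, 3.0, 0.0], q=1)
        assert out[1] == pytest.approx(1.0)

    def test_nan_excluded_and_renormalized(self):
        out = moving_average([1.0, np.nan, 4.0], q=1)
        assert out[1] == pytest.approx(2.5)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30), st.integers(1, 4))
    def test_matches_naive_window_mean(self, values, q):
        v = np.asarray(values)
        out = moving_average(v, q=q)
        for i in range(v.size):
            window = v[max(0, i - q): i + q + 1]
            assert out[i] == pytest.approx(window.mean(), rel=1e-9, abs=1e-9)


class TestBinocularMean:
    def test_combinations(self):
        left = np.array([2.0, np.nan, np.nan])
        right = np.array([4.0, 6.0, np.nan])
        out = binocular_mean(left, right)
        assert out[0] == 3.0 and out[1] == 6.0 and np.isnan(out[2])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            binocular_mean([1.0], [1.0, 2.0])


class TestEar:
    def hand_frame(self, pts):
        ids = DEFAULT_EYE_MAP.right.ear
        return LandmarkFrame(0, {i: np.asarray(p, float) for i, p in zip(ids, pts)})

    def test_hand_arithmetic(self):
        f = self.hand_frame([(0, 0), (1, 1), (3, 1), (4, 0), (3, -1), (1, -1)])
        assert compute_ear(f, eye="right") == pytest.approx(0.5)

    def test_closed_eye_zero(self):
        f = self.hand_frame([(0, 0), (1, 0), (3, 0), (4, 0), (3, 0), (1, 0)])
        assert compute_ear(f, eye="right") == 0.0

    def test_similarity_invariant(self, rng):
        pts = np.array([(0, 0), (1, 1), (3, 1), (4, 0), (3, -1), (1, -1)], float)
        base = compute_ear(self.hand_frame(pts), eye="right")
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = 2.5 * pts @ R.T + [11, -3]
        assert compute_ear(self.hand_frame(moved), eye="right") == pytest.approx(base, abs=1e-12)

    def test_degenerate_width_nan(self):
        f = self.hand_frame([(0, 0), (1, 1), (3, 1), (0, 0), (3, -1), (1, -1)])
        assert np.isnan(compute_ear(f, eye="right"))


class TestValidMask:
    def test_blink_frames_invalid(self):
        cfg = GazeSimConfig(seed=5, duration_s=10.0, jitter_sd_px=0.0, blink_rate_hz=0.5)
        rec = simulate_recording(cfg)
        mask = valid_mask(rec.stream, ear_threshold=0.2)
        assert rec.blink_true.any()  # the fixture must actually blink
        np.testing.assert_array_equal(mask, ~rec.blink_true)

    def test_missing_landmark_invalid(self, quiet_recording):
        stream = quiet_recording.stream
        coords = stream.coords.copy()
        coords[4, 0, :] = np.nan
        mask = valid_mask(stream.with_coords(coords))
        assert not mask[4]


class TestFixationRatio:
    def test_all_zero_velocity_full_ratio(self):
        vel = np.zeros(100)
        vel[0] = np.nan
        ratio, runs = fixation_ratio_at(0.5, vel, np.ones(100, bool), 8)
        assert ratio == 1.0 and len(runs) == 1

    def test_minimum_persistence_eight_frames(self):
        vel = np.full(40, 10.0)
        vel[3:10] = 0.0   # 7 frames: too short
        vel[20:28] = 0.0  # 8 frames: counts
        ratio, runs = fixation_ratio_at(1.0, vel, np.ones(40, bool), default_min_fix_frames(30.0))
        assert runs == [(20, 27)]
        assert ratio == pytest.approx(8 / 40)

    def test_hand_built_trace_with_blink(self):
        # 100 frames: fixation 0-39, saccade 40-44, fixation 45-69,
        # blink 70-79 (invalid), fixation 80-99
        vel = np.full(100, 0.01)
        vel[40:45] = 5.0
        valid = np.ones(100, bool)
        valid[70:80] = False
        ratio, runs = fixation_ratio_at(1.0, vel, valid, 8)
        assert runs == [(0, 39), (45, 69), (80, 99)]
        assert ratio == pytest.approx((40 + 25 + 20) / 90)

    def test_no_valid_frames_is_error(self):
        with pytest.raises(ValueError):
            fixation_ratio_at(1.0, np.zeros(10), np.zeros(10, bool), 8)

    def test_ratio_monotone_in_threshold(self, rng):
        for _ in range(10):
            vel = np.abs(rng.normal(0, 1, 300))
            valid = rng.random(300) > 0.05
            prev = -1.0
            for thr in np.linspace(0, 3, 40):
                r, _ = fixation_ratio_at(thr, vel, valid, 8)
                assert r >= prev - 1e-15
                prev = r


class TestEstimateThreshold:
    def test_two_level_velocity_converges(self):
        # 0.1 on exactly 90% of frames in long runs, 10.0 elsewhere
        vel = np.concatenate([np.full(90, 0.1), np.full(10, 10.0)] * 5)
        fix = estimate_threshold(vel, np.ones(vel.size, bool), 30.0)
        assert fix.converged
        assert fix.ratio == pytest.approx(0.90, abs=0.0025)
        assert 0.1 < fix.threshold < 10.0

    def test_all_zero_velocity_never_converges(self):
        fix = estimate_threshold(np.zeros(60), np.ones(60, bool), 30.0)
        assert not fix.converged
        assert fix.ratio == 1.0

    def test_converged_ratio_within_band(self, rng):
        vel = np.abs(np.repeat(rng.normal(0, 1, 60), 10)) + rng.normal(0, 0.01, 600) ** 2
        fix = estimate_threshold(vel, np.ones(600, bool), 30.0)
        if fix.converged:
            assert 0.8975 <= fix.ratio <= 0.9025

    def test_fixation_only_on_valid_frames(self, rng):
        vel = np.abs(rng.normal(0, 0.1, 300))
        valid = rng.random(300) > 0.1
        fix = estimate_threshold(vel, valid, 30.0)
        assert not np.any(fix.fixation & ~fix.valid)
        # every run respects the minimum persistence
        from fixkit.features import extract_segments
        for seg in extract_segments(fix, 30.0):
            assert seg.n_frames >= default_min_fix_frames(30.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ThresholdSearchConfig(target_ratio=1.5)
        with pytest.raises(ValueError):
            ThresholdSearchConfig(tolerance=0.0)


class TestSegmenterEstimator:
    def test_fit_predict_roundtrip(self, rng):
        vel = np.abs(np.repeat(rng.normal(0, 1, 40), 15))
        seg = FixationSegmenter(fps=30.0)
        assert clone(seg).get_params()["target_ratio"] == 0.90
        seg.fit(vel)
        assert hasattr(seg, "threshold_") and hasattr(seg, "converged_")
        fix = seg.predict(vel)
        np.testing.assert_array_equal(fix, seg.result_.fixation)
        assert seg.min_fix_frames_ == 8
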