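"""Feature pipeline: standardization, smoothing, speeds and normalization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posefall import (
    FeatureMatrix,
    GeneratorConfig,
    KalmanParams,
    NormalizationParams,
    apply_minmax,
    build_features,
    central_point,
    default_kalman_params,
    fit_minmax,
    generate_clip,
    invert_minmax,
    kalman_smooth,
    minmax_from_pairs,
    prepare_features,
    speed_series,
    standard_frame_count,
    subsample_frames,
)
from posefall.schema import Clip, ClipDataset, Landmark, PoseFrame
from tests.conftest import REFERENCE_NOSE_ROWS


def _stub_clip(n_frames: int, clip_id: str = "stub") -> Clip:
    frame = PoseFrame(frame_index=1, landmarks=[Landmark(i, 0.5, 0.5, 0.0) for i in range(33)])
    frames = [PoseFrame(frame_index=t + 1, landmarks=frame.landmarks) for t in range(n_frames)]
    return Clip(clip_id=clip_id, label="standing", frames=frames)


class TestFrameStandardization:
    def test_minimum_over_lengths(self):
        ds = ClipDataset(clips=[_stub_clip(n, str(n)) for n in (12, 9, 30)])
        assert standard_frame_count(ds) == 9

    def test_equal_lengths(self):
        ds = ClipDataset(clips=[_stub_clip(20, str(i)) for i in range(3)])
        assert standard_frame_count(ds) == 20

    def test_matches_brute_force_min(self):
        rng = np.random.default_rng(8)
        lengths = rng.integers(5, 80, size=100)
        ds = ClipDataset(clips=[_stub_clip(int(n), str(i)) for i, n in enumerate(lengths)])
        assert standard_frame_count(ds) == min(lengths)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            standard_frame_count(ClipDataset(clips=[]))


class TestSubsample:
    def test_full_length_is_identity(self):
        clip = _stub_clip(6)
        out = subsample_frames(clip, 6, np.random.default_rng(0))
        assert [f.frame_index for f in out.frames] == [f.frame_index for f in clip.frames]

    def test_order_preserved(self):
        clip = _stub_clip(5)
        for seed in range(20):
            out = subsample_frames(clip, 2, np.random.default_rng(seed))
            idx = [f.frame_index for f in out.frames]
            assert len(idx) == 2 and idx[0] < idx[1]
            assert set(idx) <= {1, 2, 3, 4, 5}

    def test_upsampling_refused(self):
        with pytest.raises(ValueError):
            subsample_frames(_stub_clip(4), 5, np.random.default_rng(0))

    def test_two_of_four_subsets_are_uniform(self):
        """Each of the 6 possible 2-of-4 subsets should appear with
        frequency 1/6 within +/- 0.02 over 10,000 seeded draws."""
        clip = _stub_clip(4)
        rng = np.random.default_rng(2024)
        counts: dict[tuple[int, ...], int] = {}
        n_draws = 10_000
        for _ in range(n_draws):
            out = subsample_frames(clip, 2, rng)
            key = tuple(f.frame_index for f in out.frames)
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        for key, n in counts.items():
            assert abs(n / n_draws - 1 / 6) < 0.02, key


class TestCentralPoint:
    def _frame(self, p1, p2, p3, p4):
        frame = PoseFrame(frame_index=1, landmarks=[Landmark(i, 0.0, 0.0, 0.0) for i in range(33)])
        for idx, p in ((11, p1), (24, p2), (12, p3), (23, p4)):
            frame.landmarks[idx] = Landmark(idx, *p)
        return frame

    def test_coincident_points(self):
        frame = self._frame(*[(0.4, 0.6, 0.1)] * 4)
        np.testing.assert_allclose(central_point(frame), [0.4, 0.6, 0.1])

    def test_worked_example(self):
        frame = self._frame((0, 0, 0), (1, 1, 1), (1, 0, 0), (0, 1, 1))
        np.testing.assert_allclose(central_point(frame), [0.5, 0.5, 0.5])

    def test_equals_mean_of_four_landmarks(self):
        rng = np.random.default_rng(77)
        for _ in range(1000):
            pts = rng.normal(size=(4, 3))
            frame = self._frame(*pts)
            np.testing.assert_allclose(central_point(frame), pts.mean(axis=0), atol=1e-12)


class TestKalman:
    def test_zero_measurement_noise_is_identity(self):
        params = default_kalman_params(r=0.0)
        rng = np.random.default_rng(1)
        z = rng.normal(size=(40, 3))
        np.testing.assert_allclose(kalman_smooth(z, params), z, atol=1e-9)

    def test_zero_process_noise_constant_series(self):
        params = default_kalman_params(q=0.0)
        z = np.full((30, 2), 0.37)
        np.testing.assert_allclose(kalman_smooth(z, params), z, atol=1e-9)

    def test_reduces_mse_on_noisy_sine(self):
        rng = np.random.default_rng(3)
        t = np.arange(200)
        truth = 0.5 + 0.1 * np.sin(2 * np.pi * t / 60)
        noisy = truth + rng.normal(0, 0.01, size=200)
        smoothed = kalman_smooth(noisy, default_kalman_params(r=1e-4))
        mse_raw = np.mean((noisy - truth) ** 2)
        mse_smooth = np.mean((smoothed - truth) ** 2)
        assert mse_smooth < mse_raw

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            KalmanParams(A=np.eye(2), H=np.array([[1.0, 0.0]]), Q=np.eye(3), R=np.eye(1))
        with pytest.raises(ValueError):
            KalmanParams(A=np.eye(2), H=np.array([[1.0, 0.0]]), Q=np.eye(2), R=-np.eye(1))


class TestSpeedSeries:
    def test_single_position_gives_zero(self):
        np.testing.assert_array_equal(speed_series(np.array([[0.1, 0.2, 0.3]])), [0.0])

    def test_three_four_five(self):
        np.testing.assert_allclose(speed_series(np.array([[0, 0, 0], [3, 4, 0]])), [0.0, 5.0])

    def test_matches_brute_force_norms(self):
        rng = np.random.default_rng(9)
        walk = rng.normal(size=(50, 3)).cumsum(axis=0)
        expected = [0.0] + [float(np.sqrt(((walk[t] - walk[t - 1]) ** 2).sum())) for t in range(1, 50)]
        np.testing.assert_allclose(speed_series(walk), expected, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_nonnegative_and_translation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(20, 3))
        shift = rng.normal(size=3)
        s = speed_series(pts)
        assert (s >= 0).all()
        np.testing.assert_allclose(s, speed_series(pts + shift), atol=1e-12)


class TestBuildFeatures:
    def test_static_clip_has_zero_speeds(self):
        cfg = GeneratorConfig(clips_per_class=1, coordinate_noise_sd=0.0, occlusion_rate=0.0)
        clip = generate_clip("sleeping", cfg, np.random.default_rng(0))
        m = build_features(clip, len(clip))
        speeds = m.values[:, -3:]
        assert np.abs(speeds[1:]).max() < 1e-9
        assert np.all(speeds[0] == 0.0)

    def test_channel_counts(self):
        cfg = GeneratorConfig(clips_per_class=1)
        clip = generate_clip("standing", cfg, np.random.default_rng(0))
        assert build_features(clip, 10).values.shape[1] == 33 * 3 + 3
        assert build_features(clip, 10, include_nose_speed=True).values.shape[1] == 33 * 3 + 4
        assert (
            build_features(clip, 10, include_visibility=True, include_nose_speed=True).values.shape[1]
            == 33 * 4 + 4
        )

    def test_falling_speed_channel_exceeds_sleeping(self):
        cfg = GeneratorConfig(clips_per_class=1, seed=0)
        fall = generate_clip("falling", cfg, np.random.default_rng(5))
        sleep = generate_clip("sleeping", cfg, np.random.default_rng(5))
        n = min(len(fall), len(sleep))
        f = build_features(fall, n, rng=np.random.default_rng(1))
        s = build_features(sleep, n, rng=np.random.default_rng(1))
        central = f.channel_names.index("Central_Body_Speed")
        assert f.values[:, central].max() > s.values[:, central].max()

    def test_prepare_features_standardizes_length(self, small_dataset, small_features):
        T = standard_frame_count(small_dataset)
        assert all(m.values.shape[0] == T for m in small_features)


class TestMinMax:
    def test_single_channel_min_max(self):
        m = FeatureMatrix("a", "standing", np.array([[2.0], [4.0], [6.0]]), ["c"])
        p = fit_minmax([m])
        assert p.x_min[0] == 2.0 and p.x_max[0] == 6.0

    def test_speed_channels_have_zero_min(self, small_features):
        p = fit_minmax(small_features)
        for name in ("Central_Body_Speed", "Left_Knee_Speed", "Right_Knee_Speed"):
            assert p.x_min[p.channel_names.index(name)] == 0.0

    def test_matches_brute_force_scan(self, small_features):
        p = fit_minmax(small_features)
        flat = np.vstack([m.values for m in small_features])
        np.testing.assert_array_equal(p.x_min, flat.min(axis=0))
        np.testing.assert_array_equal(p.x_max, flat.max(axis=0))

    def test_extremes_map_to_zero_and_one(self):
        m = FeatureMatrix("a", "standing", np.array([[2.0], [4.0], [6.0]]), ["c"])
        p = fit_minmax([m])
        out = apply_minmax(m, p).values[:, 0]
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0])

    def test_constant_channel_maps_to_zero_and_no_clipping(self):
        train = FeatureMatrix("a", "standing", np.array([[1.0, 5.0], [3.0, 5.0]]), ["v", "const"])
        p = fit_minmax([train])
        other = FeatureMatrix("b", "standing", np.array([[5.0, 5.0]]), ["v", "const"])
        out = apply_minmax(other, p).values
        assert out[0, 0] == 2.0  # outside the fitted range, deliberately unclipped
        assert out[0, 1] == 0.0

    def test_train_set_lands_in_unit_interval(self, small_features):
        p = fit_minmax(small_features)
        span = p.x_max - p.x_min
        normed = np.vstack([apply_minmax(m, p).values for m in small_features])
        assert normed.min() >= 0.0 and normed.max() <= 1.0
        attained_min = normed.min(axis=0)[span > 0]
        attained_max = normed.max(axis=0)[span > 0]
        np.testing.assert_allclose(attained_min, 0.0, atol=1e-12)
        np.testing.assert_allclose(attained_max, 1.0, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_apply_invert_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(scale=10, size=(8, 5))
        m = FeatureMatrix("r", "standing", values, [f"c{i}" for i in range(5)])
        p = fit_minmax([m])
        back = invert_minmax(apply_minmax(m, p), p)
        np.testing.assert_allclose(back.values, values, atol=1e-10)

    def test_channel_mismatch_rejected(self):
        m = FeatureMatrix("a", "standing", np.zeros((2, 1)), ["c"])
        p = NormalizationParams(np.zeros(1), np.ones(1), ["other"])
        with pytest.raises(ValueError):
            apply_minmax(m, p)

    @pytest.mark.parametrize("axis,tol", [("x", 1e-5), ("y", 1e-4), ("z", 1e-4)])
    def test_two_point_affine_map_predicts_reference_row(self, axis, tol):
        """Solving the min-max map from two (raw, normalized) reference pairs
        reproduces the third frame's normalized nose coordinate."""
        raw = REFERENCE_NOSE_ROWS[axis]["raw"]
        norm = REFERENCE_NOSE_ROWS[axis]["norm"]
        x_min, x_max = minmax_from_pairs(raw[:2], norm[:2])
        p = NormalizationParams(np.array([x_min]), np.array([x_max]), ["c"])
        m = FeatureMatrix("ref", "falling", np.array([[raw[2]]]), ["c"])
        assert apply_minmax(m, p).values[0, 0] == pytest.approx(norm[2], abs=tol)
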