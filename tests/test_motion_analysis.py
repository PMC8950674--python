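import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from cardiobeat.motion_analysis import (
    DistanceProfile,
    GridSpec,
    LostPointError,
    TrackedPoint,
    block_matching_track,
    distance_profile,
    place_reference_grid,
    profiles_to_frame,
    track_points,
)
from cardiobeat.video_io import DegenerateInputError, VideoClip


def _texture(h, w, seed=0, scale=2.5):
    rng = np.random.default_rng(seed)
    t = ndimage.gaussian_filter(rng.normal(size=(h, w)), scale)
    t = 128 + 45 * t / t.std()
    return np.clip(t, 0, 255)


def _translation_clip(speed=1, n=10, h=96, w=96, seed=3):
    """Rigid integer translation via a sliding crop of a wide texture:
    content moves left by `speed` px/frame, with no wrap seam."""
    wide = _texture(h, w + speed * n, seed)
    frames = np.stack(
        [wide[:, t * speed : t * speed + w] for t in range(n)]
    ).astype(np.uint8)
    return VideoClip(frames=frames, frame_rate=30.0)


class TestReferenceGrid:
    def test_100px_frame_spacing20_gives_25_points(self):
        pts = place_reference_grid(100, 100, GridSpec(spacing=20, margin=10))
        assert pts.shape == (25, 2)
        # row-major: x varies fastest
        np.testing.assert_array_equal(pts[:5, 0], [10, 30, 50, 70, 90])
        np.testing.assert_array_equal(pts[:5, 1], [10] * 5)

    def test_single_lattice_site(self):
        pts = place_reference_grid(20, 20, GridSpec(spacing=20, margin=10))
        np.testing.assert_array_equal(pts, [[10.0, 10.0]])

    def test_too_small_frame_errors(self):
        with pytest.raises(DegenerateInputError):
            place_reference_grid(5, 5, GridSpec(spacing=20, margin=10))

    def test_default_margin_is_half_spacing(self):
        pts = place_reference_grid(40, 40, GridSpec(spacing=20))
        assert pts[0, 0] == 10.0


class TestTrackPoints:
    def test_static_video_keeps_points_at_origin(self):
        base = _texture(64, 64)
        frames = np.repeat(base[None].astype(np.uint8), 6, axis=0)
        clip = VideoClip(frames=frames, frame_rate=30.0)
        pts = place_reference_grid(64, 64, GridSpec(spacing=20, margin=12))
        tracked = track_points(clip, pts)
        for tp in tracked:
            assert tp.status == "tracked"
            drift = np.linalg.norm(tp.trajectory - tp.trajectory[0], axis=1)
            assert drift.max() < 0.1

    @pytest.mark.parametrize("speed", [1, 3, 5])
    def test_translation_matches_block_matching_oracle(self, speed):
        """Optical flow agrees with exhaustive integer search on noise-free
        rigid translations up to 5 px/frame."""
        clip = _translation_clip(speed=speed)
        pts = np.array([[60.0, 40.0], [68.0, 56.0], [76.0, 40.0]])
        flow = track_points(clip, pts)
        brute = block_matching_track(clip, pts, search=5)
        for tp_f, tp_b in zip(flow, brute):
            assert tp_f.status == "tracked" and tp_b.status == "tracked"
            diff = np.linalg.norm(tp_f.trajectory - tp_b.trajectory, axis=1)
            assert diff.max() <= 0.5

    def test_translation_positions_track_ground_truth(self):
        clip = _translation_clip(speed=1)
        pts = np.array([[40.0, 40.0]])
        (tp,) = track_points(clip, pts)
        for t in range(clip.n_frames):
            assert abs(tp.trajectory[t, 0] - (40.0 - t)) <= 0.5
            assert abs(tp.trajectory[t, 1] - 40.0) <= 0.5

    def test_intensity_scale_invariance(self):
        clip = _translation_clip(speed=2)
        scaled = VideoClip(
            frames=np.clip(clip.frames.astype(float) * 1.4, 0, 255).astype(np.uint8),
            frame_rate=30.0,
        )
        pts = np.array([[48.0, 40.0], [56.0, 48.0]])
        for tp_a, tp_b in zip(track_points(clip, pts), track_points(scaled, pts)):
            d_a = np.linalg.norm(tp_a.trajectory - tp_a.trajectory[0], axis=1)
            d_b = np.linalg.norm(tp_b.trajectory - tp_b.trajectory[0], axis=1)
            assert np.abs(d_a - d_b).max() <= 0.5

    def test_even_window_rejected(self):
        clip = _translation_clip()
        with pytest.raises(ValueError):
            track_points(clip, np.array([[40.0, 40.0]]), window=20)

    def test_origin_outside_frame_rejected(self):
        clip = _translation_clip()
        with pytest.raises(ValueError):
            track_points(clip, np.array([[200.0, 40.0]]))


class TestDistanceProfile:
    def test_three_four_five_triangle(self):
        tp = TrackedPoint(0, (0.0, 0.0), np.array([[0.0, 0.0], [3.0, 4.0]]))
        prof = distance_profile(tp, alpha=0.0)
        np.testing.assert_allclose(prof.d, [0.0, 5.0])

    def test_pure_jitter_fully_suppressed(self):
        steps = np.array([[0.2, 0.0], [0.0, 0.2], [-0.2, 0.0], [0.0, -0.2]] * 5)
        traj = np.vstack([[0, 0], np.cumsum(steps, axis=0)]).astype(float)
        prof = distance_profile(TrackedPoint(0, (0.0, 0.0), traj), alpha=0.5)
        np.testing.assert_allclose(prof.d, 0.0)

    def test_alpha_zero_is_identity(self, rng):
        traj = np.cumsum(rng.normal(0, 1, (50, 2)), axis=0)
        tp = TrackedPoint(0, tuple(traj[0]), traj)
        prof = distance_profile(tp, alpha=0.0)
        np.testing.assert_allclose(prof.d, np.linalg.norm(traj - traj[0], axis=1))

    def test_lost_point_rejected(self):
        tp = TrackedPoint(0, (0.0, 0.0), np.zeros((3, 2)), status="lost")
        with pytest.raises(LostPointError):
            distance_profile(tp)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        steps=st.lists(
            st.tuples(
                st.floats(-2, 2, allow_nan=False), st.floats(-2, 2, allow_nan=False)
            ),
            min_size=2,
            max_size=30,
        ),
        alphas=st.tuples(st.floats(0, 1), st.floats(0, 1)),
    )
    def test_path_variation_nonincreasing_in_alpha(self, steps, alphas):
        # the rebuilt position path only ever drops steps as alpha grows,
        # so its total travelled length cannot increase
        traj = np.vstack([[0.0, 0.0], np.cumsum(np.asarray(steps), axis=0)])
        mags = np.linalg.norm(np.diff(traj, axis=0), axis=1)
        a_small, a_big = sorted(alphas)
        assert mags[mags >= a_big].sum() <= mags[mags >= a_small].sum() + 1e-9
        # and alpha = 0 reproduces the raw profile exactly
        tp = TrackedPoint(0, (0.0, 0.0), traj)
        np.testing.assert_allclose(
            distance_profile(tp, 0.0).d, np.linalg.norm(traj - traj[0], axis=1)
        )


def test_profiles_long_format_export():
    tp = TrackedPoint(3, (0.0, 0.0), np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]))
    df = profiles_to_frame([distance_profile(tp, alpha=0.0)], frame_rate=10.0)
    assert list(df.columns) == ["point_id", "frame", "t_seconds", "d_px"]
    np.testing.assert_allclose(df["t_seconds"], [0.0, 0.1, 0.2])
    np.testing.assert_allclose(df["d_px"], [0.0, 1.0, 2.0])
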