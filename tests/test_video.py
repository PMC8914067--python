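"""Video reading, trimming, stabilization and resizing."""

import numpy as np
import pytest
from skimage.registration import phase_cross_correlation

from tonguekin.fixtures import apply_jitter, generate_clip, write_fixture
from tonguekin.video import (
    FrameSequence,
    StabilizationParams,
    read_video,
    stabilize,
    standardize,
    trim_clip,
    write_video,
)


def flat_clip(n=10, h=48, w=64, fps=30.0, value=128):
    return FrameSequence(np.full((n, h, w, 3), value, dtype=np.uint8), fps)


class TestReadWrite:
    def test_lossless_avi_round_trip(self, simple_clip, tmp_path):
        clip, _ = simple_clip
        path = write_video(clip, tmp_path / "clip.avi")
        back = read_video(path)
        assert np.array_equal(back.frames, clip.frames)
        assert back.fps == clip.fps

    def test_fixture_writer_outputs_sidecar(self, simple_spec, tmp_path):
        video_path, sidecar = write_fixture(simple_spec, tmp_path)
        assert video_path.exists() and sidecar.exists()
        back = read_video(video_path)
        assert back.n_frames == simple_spec.n_frames

    def test_missing_file(self, tmp_path):
        with pytest.raises(IOError, match="not found"):
            read_video(tmp_path / "nope.avi")

    def test_garbage_file(self, tmp_path):
        bad = tmp_path / "bad.avi"
        bad.write_bytes(b"not a video at all")
        with pytest.raises(IOError):
            read_video(bad)


class TestTrim:
    @pytest.mark.parametrize(
        "n_in, fps, n_out", [(360, 30, 150), (150, 30, 150), (125, 25, 125)]
    )
    def test_first_five_seconds(self, n_in, fps, n_out):
        trimmed = trim_clip(flat_clip(n=n_in, fps=fps), 5.0)
        assert trimmed.n_frames == n_out
        assert trimmed.fps == fps

    def test_keeps_leading_frames(self):
        frames = np.zeros((200, 8, 8, 3), dtype=np.uint8)
        frames[:, 0, 0, 0] = np.arange(200) % 256
        trimmed = trim_clip(FrameSequence(frames, 30.0), 5.0)
        assert np.array_equal(trimmed.frames, frames[:150])

    def test_idempotent(self):
        once = trim_clip(flat_clip(n=400), 5.0)
        twice = trim_clip(once, 5.0)
        assert np.array_equal(once.frames, twice.frames)

    def test_short_clip_advises_rerecording(self):
        with pytest.raises(ValueError, match="[Rr]ecord"):
            trim_clip(flat_clip(n=100, fps=30), 5.0)


class TestStabilize:
    def test_static_clip_unchanged(self, simple_clip):
        clip, _ = simple_clip
        out = stabilize(clip, StabilizationParams())
        assert np.array_equal(out.frames, clip.frames)

    def test_single_frame_degenerate(self):
        clip = flat_clip(n=1)
        assert stabilize(clip) is clip

    def test_preserves_shape_and_fps(self, simple_clip):
        clip, _ = simple_clip
        jittered = apply_jitter(clip, 4, seed=11)
        out = stabilize(jittered)
        assert out.frames.shape == clip.frames.shape
        assert out.fps == clip.fps

    def test_residual_translation_below_one_pixel(self, simple_clip):
        # jitter amplitude 5, then stabilize: compare each output frame with
        # its unjittered twin by phase correlation and average the residual
        clip, _ = simple_clip
        jittered = apply_jitter(clip, 5, seed=7)
        out = stabilize(jittered, StabilizationParams())
        residuals = []
        for a, b in zip(out.frames, clip.frames):
            shift, _, _ = phase_cross_correlation(
                a.mean(axis=-1), b.mean(axis=-1), upsample_factor=10,
                normalization=None,
            )
            residuals.append(np.hypot(*shift))
        assert np.mean(residuals) < 1.0

    def test_affine_model_runs_and_reduces_jitter(self, simple_spec):
        clip, _ = generate_clip(simple_spec)
        short = FrameSequence(clip.frames[:20], clip.fps)
        jittered = apply_jitter(short, 4, seed=5)
        out = stabilize(jittered, StabilizationParams(model="affine"))
        err_before = np.abs(
            jittered.frames.astype(int) - short.frames.astype(int)
        ).mean()
        err_after = np.abs(out.frames.astype(int) - short.frames.astype(int)).mean()
        assert out.frames.shape == short.frames.shape
        assert err_after < err_before


class TestStandardize:
    def test_two_thirds_scale(self):
        out = standardize(flat_clip(n=2, h=720, w=960), 480)
        assert (out.height, out.width) == (480, 640)

    def test_identity_at_target_height(self):
        clip = flat_clip(h=480, w=640)
        assert standardize(clip, 480) is clip

    def test_width_rounded_to_even(self):
        out = standardize(flat_clip(n=1, h=540, w=721), 480)
        # 721 * 480/540 = 640.9 -> nearest even width
        assert out.width == 640
        assert out.height == 480

    def test_rejects_tiny_target(self):
        with pytest.raises(ValueError):
            standardize(flat_clip(), 32)


class TestJitter:
    def test_amplitude_zero_is_identity(self, simple_clip):
        clip, _ = simple_clip
        assert apply_jitter(clip, 0, seed=1) is clip

    def test_seeded_reproducibility(self, simple_clip):
        clip, _ = simple_clip
        a = apply_jitter(clip, 5, seed=42)
        b = apply_jitter(clip, 5, seed=42)
        c = apply_jitter(clip, 5, seed=43)
        assert np.array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_offsets_bounded_by_amplitude(self, simple_clip):
        clip, _ = simple_clip
        jittered = apply_jitter(clip, 3, seed=9)
        # every jittered frame matches some integer shift of the original
        # within the amplitude (checked via phase correlation)
        for a, b in zip(jittered.frames[:10], clip.frames[:10]):
            shift, _, _ = phase_cross_correlation(
                a.mean(axis=-1), b.mean(axis=-1), normalization=None
            )
            assert np.abs(shift).max() <= 3
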