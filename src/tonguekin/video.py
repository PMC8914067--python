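"""Video reading and pre-processing.

Clips are standardised before any feature extraction: trimmed to their
first five seconds, stabilised against handheld camera motion, and
resized to a common height.  The in-memory unit throughout the pipeline
is :class:`FrameSequence` -- an ordered stack of 8-bit RGB frames plus
the frame rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import color, feature, measure, registration, transform

from ._avi import read_avi, write_avi

__all__ = [
    "FrameSequence",
    "StabilizationParams",
    "read_video",
    "write_video",
    "trim_clip",
    "stabilize",
    "standardize",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrameSequence:
    """Ordered RGB frames with a frame rate.

    ``frames`` is an (n_frames, height, width, 3) uint8 array; all video
    stages consume and produce this shape.
    """

    frames: np.ndarray
    fps: float
    source_path: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 4 or f.shape[-1] != 3:
            raise ValueError("frames must have shape (n, height, width, 3)")
        if f.dtype != np.uint8:
            raise ValueError("frames must be 8-bit (uint8)")
        if f.shape[0] < 1:
            raise ValueError("a clip needs at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def height(self) -> int:
        return int(self.frames.shape[1])

    @property
    def width(self) -> int:
        return int(self.frames.shape[2])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass(frozen=True)
class StabilizationParams:
    """Camera-motion compensation settings.

    The inter-frame motion is estimated from tracked image structure and
    the cumulative camera trajectory is smoothed with a centred moving
    average; the correction removes the jitter around that smooth path.
    """

    max_corners: int = 200
    min_feature_quality: float = 0.01
    smoothing_window_frames: int = 30
    model: str = "translation"  # or "affine"

    def __post_init__(self) -> None:
        if self.smoothing_window_frames < 1:
            raise ValueError("smoothing_window_frames must be >= 1")
        if self.max_corners < 10:
            raise ValueError("max_corners must be >= 10")
        if self.model not in ("translation", "affine"):
            raise ValueError("model must be 'translation' or 'affine'")


def read_video(path: str | Path) -> FrameSequence:
    """Decode a video file into a :class:`FrameSequence`.

    Uncompressed AVI (the package's own lossless format) is read
    natively; other containers (MP4/MOV) are dispatched to imageio and
    require an ffmpeg plugin in the environment.
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"video file not found: {p}")
    suffix = p.suffix.lower()
    if suffix == ".avi":
        frames, fps = read_avi(p)
        return FrameSequence(frames, fps, source_path=str(p))
    try:
        import imageio.v2 as iio

        reader = iio.get_reader(str(p))
        meta = reader.get_meta_data()
        frames = np.stack([np.asarray(f)[..., :3] for f in reader])
        reader.close()
    except Exception as exc:  # pragma: no cover - depends on plugins present
        raise IOError(
            f"cannot decode {p}: no codec available for '{suffix}' "
            "(install an ffmpeg backend, or use uncompressed .avi)"
        ) from exc
    if frames.shape[0] == 0:
        raise IOError(f"no frames decoded from {p}")
    fps = float(meta.get("fps", 0) or 0)
    if fps <= 0:
        raise IOError(f"no frame rate recorded in {p}")
    return FrameSequence(frames.astype(np.uint8), fps, source_path=str(p))


def write_video(clip: FrameSequence, path: str | Path) -> Path:
    """Write a clip; ``.avi`` is lossless, other suffixes need imageio codecs."""
    p = Path(path)
    if p.suffix.lower() == ".avi":
        write_avi(p, clip.frames, clip.fps)
        return p
    import imageio.v2 as iio  # pragma: no cover - plugin-dependent

    iio.mimwrite(str(p), list(clip.frames), fps=clip.fps)  # pragma: no cover
    return p  # pragma: no cover


def trim_clip(clip: FrameSequence, duration_s: float = 5.0) -> FrameSequence:
    """Keep exactly the first ``floor(duration_s * fps)`` frames.

    A clip shorter than the requested duration is rejected: the task
    protocol requires at least five seconds of correct movement, so the
    remedy is re-recording, not padding.
    """
    n_keep = math.floor(duration_s * clip.fps)
    if clip.n_frames < n_keep:
        raise ValueError(
            f"clip has {clip.n_frames} frames but {n_keep} are required "
            f"({duration_s} s at {clip.fps} fps); record at least "
            f"{duration_s} s of movement"
        )
    if clip.n_frames == n_keep:
        return clip
    return replace(clip, frames=clip.frames[:n_keep].copy())


def _to_gray(frame: np.ndarray) -> np.ndarray:
    return color.rgb2gray(frame)


def _pairwise_translation(prev: np.ndarray, cur: np.ndarray) -> np.ndarray:
    """Estimate (dx, dy) moving ``prev`` onto ``cur`` by phase correlation."""
    shift, _, _ = registration.phase_cross_correlation(
        cur, prev, upsample_factor=10, normalization=None
    )
    # skimage returns (row, col) = (dy, dx)
    return np.array([shift[1], shift[0]], dtype=float)


def _pairwise_affine(
    prev: np.ndarray, cur: np.ndarray, params: StabilizationParams
) -> np.ndarray | None:
    """Affine motion from corner features displaced by dense optical flow.

    Large displacements are first removed with a coarse translation
    (phase correlation); local flow then refines per-feature motion.
    Returns a 3x3 matrix mapping prev -> cur coordinates, or ``None``
    when fewer than four trackable features survive.
    """
    corners = feature.corner_peaks(
        feature.corner_shi_tomasi(prev),
        min_distance=7,
        threshold_rel=params.min_feature_quality,
        num_peaks=params.max_corners,
    )
    if corners.shape[0] < 4:
        return None
    coarse = _pairwise_translation(prev, cur)  # (dx, dy)
    dxi, dyi = int(round(coarse[0])), int(round(coarse[1]))
    pre = np.roll(prev, (dyi, dxi), axis=(0, 1))
    flow = registration.optical_flow_ilk(pre, cur, radius=7)
    rows, cols = corners[:, 0], corners[:, 1]
    src = np.column_stack([cols, rows]).astype(float)  # (x, y)
    rows_p = np.clip(rows + dyi, 0, prev.shape[0] - 1)
    cols_p = np.clip(cols + dxi, 0, prev.shape[1] - 1)
    dst = src + np.array([dxi, dyi], dtype=float) + np.column_stack(
        [flow[1][rows_p, cols_p], flow[0][rows_p, cols_p]]
    )
    try:
        model, inliers = measure.ransac(
            (src, dst),
            transform.AffineTransform,
            min_samples=3,
            residual_threshold=1.0,
            max_trials=100,
        )
    except Exception:
        return None
    if model is None or inliers is None or inliers.sum() < 4:
        return None
    return np.asarray(model.params, dtype=float)


def _smooth_trajectory(traj: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average along axis 0, edges shrunk symmetrically."""
    n = traj.shape[0]
    out = np.empty_like(traj)
    half = window // 2
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = traj[lo:hi].mean(axis=0)
    return out


def _shift_frame(frame: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Translate by integer pixels, edge-replicating exposed borders."""
    h, w = frame.shape[:2]
    padded = np.pad(
        frame, ((abs(dy), abs(dy)), (abs(dx), abs(dx)), (0, 0)), mode="edge"
    )
    y0 = abs(dy) - dy
    x0 = abs(dx) - dx
    return padded[y0 : y0 + h, x0 : x0 + w]


def stabilize(
    clip: FrameSequence, params: StabilizationParams | None = None
) -> FrameSequence:
    """Compensate camera motion while preserving intended subject motion.

    Inter-frame camera motion is estimated for every consecutive frame
    pair, accumulated into a trajectory, and the trajectory is smoothed
    with a centred moving average; each frame is then warped by the
    difference between the smooth and the raw trajectory.  Frame count,
    dimensions and frame rate are unchanged.  Pairs where motion cannot
    be estimated fall back to the identity with a warning.
    """
    params = params or StabilizationParams()
    if clip.n_frames < 2:
        return clip

    grays = [_to_gray(f) for f in clip.frames]

    if params.model == "translation":
        deltas = np.zeros((clip.n_frames, 2))
        for i in range(1, clip.n_frames):
            deltas[i] = _pairwise_translation(grays[i - 1], grays[i])
        traj = np.cumsum(deltas, axis=0)
        smooth = _smooth_trajectory(traj, params.smoothing_window_frames)
        corrections = smooth - traj
        out = np.empty_like(clip.frames)
        for i, frame in enumerate(clip.frames):
            dx = int(round(corrections[i, 0]))
            dy = int(round(corrections[i, 1]))
            out[i] = _shift_frame(frame, dx, dy) if (dx or dy) else frame
        return replace(clip, frames=out)

    # affine model: accumulate 3x3 transforms, smooth matrix entries
    mats = np.tile(np.eye(3), (clip.n_frames, 1, 1))
    for i in range(1, clip.n_frames):
        pair = _pairwise_affine(grays[i - 1], grays[i], params)
        if pair is None:
            log.warning("stabilize: <4 trackable features at frame %d; identity", i)
            pair = np.eye(3)
        mats[i] = pair @ mats[i - 1]
    flat = mats.reshape(clip.n_frames, 9)
    smooth = _smooth_trajectory(flat, params.smoothing_window_frames)
    out = np.empty_like(clip.frames)
    for i, frame in enumerate(clip.frames):
        correction = smooth[i].reshape(3, 3) @ np.linalg.inv(mats[i])
        warped = transform.warp(
            frame.astype(float) / 255.0,
            transform.AffineTransform(matrix=correction).inverse,
            mode="edge",
            preserve_range=False,
        )
        out[i] = np.clip(warped * 255.0, 0, 255).astype(np.uint8)
    return replace(clip, frames=out)


def standardize(clip: FrameSequence, target_height_px: int = 480) -> FrameSequence:
    """Resize every frame to a common height, preserving aspect ratio.

    The width is rounded to the nearest even integer (codec-friendly).
    Already-conforming clips pass through untouched.
    """
    if target_height_px < 64:
        raise ValueError("target_height_px must be >= 64")
    if clip.height == target_height_px:
        return clip
    scale = target_height_px / clip.height
    target_width = int(round(clip.width * scale / 2.0)) * 2
    out = np.empty(
        (clip.n_frames, target_height_px, target_width, 3), dtype=np.uint8
    )
    for i, frame in enumerate(clip.frames):
        resized = transform.resize(
            frame,
            (target_height_px, target_width),
            anti_aliasing=scale < 1,
            preserve_range=True,
        )
        out[i] = np.clip(np.rint(resized), 0, 255).astype(np.uint8)
    return replace(clip, frames=out)
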