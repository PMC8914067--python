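"""Synthetic tongue-movement clips with exact ground truth.

Real recordings of the lateral tongue-movement task (tongue moving
repeatedly between the mouth commissures, mouth half-open) cannot be
redistributed, so every pipeline stage is exercised on schematic clips
instead: a flat-colour background, a skin-tone face ellipse, a dark
half-open mouth, and a high-chroma tongue blob that jumps between a
left and a right station inside the mouth on a known dwell schedule.

Each generated clip carries a JSON sidecar with the per-frame tongue
side, the face and mouth boxes, and the kinematic features implied by
the schedule, so downstream stages can be tested against exact truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import color as _skcolor

from . import kinematics as _kin
from .roi import Box
from .video import FrameSequence, write_video

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_clip",
    "apply_jitter",
    "write_fixture",
    "load_ground_truth",
    "random_spec",
]

# default palette (RGB).  The tongue hue sits near 330 deg -- far from the
# skin, lip and background hues -- so a chroma threshold recovers it exactly.
BACKGROUND_RGB = (70, 110, 160)
FACE_RGB = (215, 180, 150)
MOUTH_RGB = (42, 34, 38)  # near-neutral dark cavity (low saturation)
TONGUE_HSV = (330.0, 0.9, 0.9)


def _hsv_to_rgb8(hsv: tuple[float, float, float]) -> np.ndarray:
    arr = np.array([[[hsv[0] / 360.0, hsv[1], hsv[2]]]], dtype=float)
    rgb = _skcolor.hsv2rgb(arr)[0, 0]
    return np.clip(np.rint(rgb * 255), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic clip.

    The dwell schedule is the primary control: an alternating sequence of
    (side, dwell_frames) entries.  ``pause_insertions`` lengthen chosen
    dwells to emulate participant errors (a stalled movement); jitter
    emulates handheld camera shake.  The clip duration is implied by the
    schedule, so there is no independent duration parameter.
    """

    sweep_schedule: tuple[tuple[str, int], ...]
    fps: float = 30.0
    frame_width_px: int = 256
    frame_height_px: int = 192
    tongue_hsv: tuple[float, float, float] = TONGUE_HSV
    face_box: Box = field(default=None)  # type: ignore[assignment]
    mouth_box: Box = field(default=None)  # type: ignore[assignment]
    pause_insertions: tuple[tuple[int, int], ...] = ()
    jitter_amplitude_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not self.sweep_schedule:
            raise ValueError("sweep schedule must contain at least one dwell")
        for side, dwell in self.sweep_schedule:
            if side not in ("L", "R"):
                raise ValueError(f"schedule side must be 'L' or 'R', got {side!r}")
            if dwell < 1:
                raise ValueError("all dwell_frames must be >= 1")
        for (a, _), (b, _) in zip(self.sweep_schedule, self.sweep_schedule[1:]):
            if a == b:
                raise ValueError("consecutive schedule entries must alternate side")
        for idx, extra in self.pause_insertions:
            if not 0 <= idx < len(self.sweep_schedule):
                raise ValueError(f"pause insertion index {idx} out of range")
            if extra < 1:
                raise ValueError("pause insertion must add >= 1 frame")
        if self.jitter_amplitude_px < 0:
            raise ValueError("jitter amplitude must be >= 0")
        w, h = self.frame_width_px, self.frame_height_px
        if self.face_box is None:
            object.__setattr__(
                self, "face_box", _default_face_box(w, h)
            )
        if self.mouth_box is None:
            object.__setattr__(
                self, "mouth_box", _default_mouth_box(self.face_box)
            )
        fb, mb = self.face_box, self.mouth_box
        if not (0 <= fb.x_min < fb.x_max <= w and 0 <= fb.y_min < fb.y_max <= h):
            raise ValueError("face box must lie inside the frame")
        if not (
            fb.x_min < mb.x_min < mb.x_max < fb.x_max
            and fb.y_min < mb.y_min < mb.y_max < fb.y_max
        ):
            raise ValueError("mouth box must lie strictly inside the face box")

    @property
    def run_lengths(self) -> list[int]:
        """Realised dwell lengths after pause insertions."""
        lengths = [dwell for _, dwell in self.sweep_schedule]
        for idx, extra in self.pause_insertions:
            lengths[idx] += extra
        return lengths

    @property
    def n_frames(self) -> int:
        return sum(self.run_lengths)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


def _default_face_box(w: int, h: int) -> Box:
    return Box(
        int(0.1875 * w), int(0.125 * h), int(0.8125 * w), int(0.9167 * h)
    )


def _default_mouth_box(face: Box) -> Box:
    fw = face.x_max - face.x_min
    fh = face.y_max - face.y_min
    return Box(
        face.x_min + int(0.25 * fw),
        face.y_min + int(0.55 * fh),
        face.x_max - int(0.25 * fw),
        face.y_min + int(0.80 * fh),
    )


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-frame and summary truth for one synthetic clip."""

    per_frame_side: str
    true_sweep_count: int
    true_mean_sweep_duration_s: float | None
    true_error_count: int
    face_boxes: tuple[Box, ...]
    mouth_boxes: tuple[Box, ...]
    fps: float

    def __post_init__(self) -> None:
        if len(self.per_frame_side) != len(self.face_boxes) or len(
            self.face_boxes
        ) != len(self.mouth_boxes):
            raise ValueError("per-frame truth lists must share one length")

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_frame_side": self.per_frame_side,
                "true_sweep_count": self.true_sweep_count,
                "true_mean_sweep_duration_s": self.true_mean_sweep_duration_s,
                "true_error_count": self.true_error_count,
                "face_boxes": [list(b) for b in self.face_boxes],
                "mouth_boxes": [list(b) for b in self.mouth_boxes],
                "fps": self.fps,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            per_frame_side=d["per_frame_side"],
            true_sweep_count=d["true_sweep_count"],
            true_mean_sweep_duration_s=d["true_mean_sweep_duration_s"],
            true_error_count=d["true_error_count"],
            face_boxes=tuple(Box(*b) for b in d["face_boxes"]),
            mouth_boxes=tuple(Box(*b) for b in d["mouth_boxes"]),
            fps=d["fps"],
        )


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float):
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _tongue_geometry(spec: SyntheticSpec) -> dict[str, float]:
    mb = spec.mouth_box
    mw = mb.x_max - mb.x_min
    mh = mb.y_max - mb.y_min
    return {
        "cy": (mb.y_min + mb.y_max) / 2.0,
        "cx_mid": (mb.x_min + mb.x_max) / 2.0,
        "offset": 0.25 * mw,  # station distance from the mouth midline
        "ry": 0.32 * mh,
        "rx": 0.18 * mw,
    }


def _render_base_frame(spec: SyntheticSpec) -> np.ndarray:
    """The static scene: background, face ellipse, open mouth."""
    h, w = spec.frame_height_px, spec.frame_width_px
    frame = np.empty((h, w, 3), dtype=np.uint8)
    frame[:] = BACKGROUND_RGB
    fb = spec.face_box
    face = _ellipse_mask(
        h, w,
        (fb.y_min + fb.y_max) / 2.0, (fb.x_min + fb.x_max) / 2.0,
        (fb.y_max - fb.y_min) / 2.0, (fb.x_max - fb.x_min) / 2.0,
    )
    frame[face] = FACE_RGB
    mb = spec.mouth_box
    frame[mb.y_min : mb.y_max, mb.x_min : mb.x_max] = MOUTH_RGB
    # simple eyes so the face has trackable structure for stabilization
    fw, fh = fb.x_max - fb.x_min, fb.y_max - fb.y_min
    eye_y = fb.y_min + int(0.3 * fh)
    for ex in (fb.x_min + int(0.3 * fw), fb.x_min + int(0.7 * fw)):
        eye = _ellipse_mask(h, w, eye_y, ex, 0.05 * fh, 0.08 * fw)
        frame[eye] = (40, 40, 45)
    return frame


def _render_frame(spec: SyntheticSpec, base: np.ndarray, side: str) -> np.ndarray:
    frame = base.copy()
    g = _tongue_geometry(spec)
    cx = g["cx_mid"] + (g["offset"] if side == "R" else -g["offset"])
    blob = _ellipse_mask(
        frame.shape[0], frame.shape[1], g["cy"], cx, g["ry"], g["rx"]
    )
    frame[blob] = _hsv_to_rgb8(spec.tongue_hsv)
    return frame


def generate_clip(spec: SyntheticSpec) -> tuple[FrameSequence, GroundTruth]:
    """Render a clip from its spec and derive the exact ground truth.

    The per-frame side is read directly off the realised schedule.  The
    summary features are those the kinematic rules imply for that
    record: sweeps = dwells - 1, sweep lengths from half-dwell to
    half-dwell, errors from the pooled dwell-outlier rule with k = 2.
    """
    lengths = spec.run_lengths
    sides = [side for side, _ in spec.sweep_schedule]
    per_frame = "".join(s * n for s, n in zip(sides, lengths))

    runs = [
        _kin.Run(side=s, start_frame=int(np.sum(lengths[:i])), length_frames=n)
        for i, (s, n) in enumerate(zip(sides, lengths))
    ]
    n_sweeps, sweep_lengths = _kin.count_sweeps(runs)
    truth = GroundTruth(
        per_frame_side=per_frame,
        true_sweep_count=n_sweeps,
        true_mean_sweep_duration_s=_kin.mean_sweep_duration(sweep_lengths, spec.fps),
        true_error_count=_kin.detect_errors(runs, k=2.0),
        face_boxes=tuple([spec.face_box] * len(per_frame)),
        mouth_boxes=tuple([spec.mouth_box] * len(per_frame)),
        fps=spec.fps,
    )

    base = _render_base_frame(spec)
    frame_by_side = {s: _render_frame(spec, base, s) for s in ("L", "R")}
    frames = np.stack([frame_by_side[s] for s in per_frame])
    clip = FrameSequence(frames, spec.fps, source_path="<synthetic>")
    if spec.jitter_amplitude_px > 0:
        clip = apply_jitter(clip, spec.jitter_amplitude_px, spec.seed)
    return clip, truth


def apply_jitter(
    clip: FrameSequence, amplitude_px: float, seed: int
) -> FrameSequence:
    """Translate each frame by a seeded random integer offset per axis.

    Offsets are drawn uniformly from [-amplitude, +amplitude]; exposed
    borders are edge-replicated (visually: the camera wobbles over a
    scene larger than the frame).  Amplitude zero is the identity.
    """
    if amplitude_px < 0:
        raise ValueError("amplitude must be >= 0")
    a = int(round(amplitude_px))
    if a == 0:
        return clip
    from .video import _shift_frame  # shared integer-shift helper

    rng = np.random.default_rng(seed)
    offsets = rng.integers(-a, a + 1, size=(clip.n_frames, 2))
    out = np.stack(
        [
            _shift_frame(f, int(dx), int(dy))
            for f, (dx, dy) in zip(clip.frames, offsets)
        ]
    )
    return FrameSequence(out, clip.fps, source_path=clip.source_path)


def write_fixture(
    spec: SyntheticSpec, out_dir: str | Path, name: str = "clip"
) -> tuple[Path, Path]:
    """Write ``<name>.avi`` (lossless) plus ``<name>.truth.json`` sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clip, truth = generate_clip(spec)
    video_path = out / f"{name}.avi"
    write_video(clip, video_path)
    sidecar = out / f"{name}.truth.json"
    sidecar.write_text(truth.to_json())
    return video_path, sidecar


def load_ground_truth(video_path: str | Path) -> GroundTruth:
    """Load the ``.truth.json`` sidecar next to a fixture video."""
    p = Path(video_path)
    sidecar = p.with_suffix("").with_suffix(".truth.json")
    if not sidecar.exists():
        sidecar = Path(str(p) + ".truth.json")
    if not sidecar.exists():
        raise IOError(f"no ground-truth sidecar found for {p}")
    return GroundTruth.from_json(sidecar.read_text())


def random_spec(
    rng: np.random.Generator,
    n_runs_range: tuple[int, int] = (5, 16),
    dwell_range: tuple[int, int] = (3, 15),
    fps: float = 30.0,
    jitter_amplitude_px: float = 0.0,
    with_pause: bool = False,
) -> SyntheticSpec:
    """Draw a valid random clip spec (alternating schedule, dwell >= 3)."""
    n_runs = int(rng.integers(n_runs_range[0], n_runs_range[1] + 1))
    first = "L" if rng.integers(2) else "R"
    schedule = tuple(
        (("LR"[(i + ("LR".index(first))) % 2]),
         int(rng.integers(dwell_range[0], dwell_range[1] + 1)))
        for i in range(n_runs)
    )
    pauses: tuple[tuple[int, int], ...] = ()
    if with_pause:
        idx = int(rng.integers(n_runs))
        pauses = ((idx, int(rng.integers(25, 40))),)
    return SyntheticSpec(
        sweep_schedule=schedule,
        fps=fps,
        pause_insertions=pauses,
        jitter_amplitude_px=jitter_amplitude_px,
        seed=int(rng.integers(2**31 - 1)),
    )
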