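"""Face and mouth regions of interest.

The pipeline locates the face in every frame, takes the union of the
per-frame boxes (componentwise coordinate extremes) so one fixed crop
covers the face in *all* frames, and repeats the procedure for the
mouth inside the face crop.  A single crop geometry per video keeps the
mouth midline fixed, which the kinematic left/right classification
relies on.

Detectors are pluggable: any object with a ``detect(frame, index)``
method returning a face box and mouth-corner landmarks satisfies the
contract.  The ground-truth (oracle) backend reads a fixture sidecar;
adapters for pretrained face networks can be slotted in the same way,
but none is bundled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterator, Protocol, Sequence

import numpy as np

from .video import FrameSequence

if TYPE_CHECKING:  # pragma: no cover
    from .fixtures import GroundTruth

__all__ = [
    "Box",
    "RoiTrack",
    "DetectorBackend",
    "OracleDetector",
    "VideoQualityError",
    "detect_face_track",
    "detect_mouth_track",
    "union_box",
    "extract_roi",
]

MAX_MISSING_FRAC = 0.20  # quality rule: reject if the face is lost more often


class VideoQualityError(ValueError):
    """The clip fails the full-face-visible-in-all-frames inclusion rule."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned pixel rectangle, 0-based, half-open on both axes."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box: {self}")
        if self.x_min < 0 or self.y_min < 0:
            raise ValueError(f"box coordinates must be non-negative: {self}")

    def __iter__(self) -> Iterator[int]:
        yield from (self.x_min, self.y_min, self.x_max, self.y_max)

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    def contains(self, other: "Box") -> bool:
        return (
            self.x_min <= other.x_min
            and self.y_min <= other.y_min
            and self.x_max >= other.x_max
            and self.y_max >= other.y_max
        )

    def scaled(self, factor: float) -> "Box":
        """Box in a frame resized by ``factor`` (rounded outward)."""
        import math

        return Box(
            math.floor(self.x_min * factor),
            math.floor(self.y_min * factor),
            math.ceil(self.x_max * factor),
            math.ceil(self.y_max * factor),
        )

    def shifted(self, dx: int, dy: int) -> "Box":
        return Box(self.x_min + dx, self.y_min + dy,
                   self.x_max + dx, self.y_max + dy)

    def iou(self, other: "Box") -> float:
        ix = max(0, min(self.x_max, other.x_max) - max(self.x_min, other.x_min))
        iy = max(0, min(self.y_max, other.y_max) - max(self.y_min, other.y_min))
        inter = ix * iy
        union = self.width * self.height + other.width * other.height - inter
        return inter / union if union else 0.0


@dataclass(frozen=True)
class RoiTrack:
    """Per-frame detections plus their across-frames union box."""

    per_frame: tuple[Box | None, ...]
    union: Box
    n_missing: int

    def __post_init__(self) -> None:
        present = [b for b in self.per_frame if b is not None]
        if self.n_missing != len(self.per_frame) - len(present):
            raise ValueError("n_missing inconsistent with per_frame entries")
        for b in present:
            if not self.union.contains(b):
                raise ValueError(f"union {self.union} does not contain {b}")

    def to_dict(self) -> dict:
        return {
            "per_frame": [list(b) if b else None for b in self.per_frame],
            "union": list(self.union),
            "n_missing": self.n_missing,
        }


class DetectorBackend(Protocol):
    """Contract for face/landmark detectors."""

    name: str

    def detect(
        self, frame: np.ndarray, index: int
    ) -> tuple[Box | None, np.ndarray | None]:
        """Return (face box or None, mouth-corner landmarks (k, 2) xy or None)."""
        ...


class OracleDetector:
    """Detector backed by a fixture's ground-truth sidecar.

    ``scale`` maps sidecar coordinates (original fixture geometry) into
    the processed frame when the clip was resized; ``crop_offset`` maps
    them into a face crop when detecting the mouth.  ``missing_frames``
    lets tests emulate detection dropouts.
    """

    name = "oracle"

    def __init__(
        self,
        truth: "GroundTruth",
        scale: float = 1.0,
        crop_offset: tuple[int, int] = (0, 0),
        missing_frames: Sequence[int] = (),
    ) -> None:
        self._truth = truth
        self._scale = scale
        self._offset = crop_offset
        self._missing = frozenset(missing_frames)

    def _box(self, box: Box) -> Box:
        b = box.scaled(self._scale) if self._scale != 1.0 else box
        return b.shifted(-self._offset[0], -self._offset[1])

    def detect(
        self, frame: np.ndarray, index: int
    ) -> tuple[Box | None, np.ndarray | None]:
        if index in self._missing or index >= len(self._truth.face_boxes):
            return None, None
        face = self._box(self._truth.face_boxes[index])
        mouth = self._box(self._truth.mouth_boxes[index])
        landmarks = np.array(
            [
                [mouth.x_min, mouth.y_min],
                [mouth.x_max, mouth.y_min],
                [mouth.x_min, mouth.y_max],
                [mouth.x_max, mouth.y_max],
            ],
            dtype=float,
        )
        return face, landmarks

    def for_face_crop(self, face_union: Box) -> "OracleDetector":
        """The same oracle expressed in face-crop coordinates."""
        return OracleDetector(
            self._truth,
            scale=self._scale,
            crop_offset=(
                self._offset[0] + face_union.x_min,
                self._offset[1] + face_union.y_min,
            ),
            missing_frames=self._missing,
        )


def union_box(boxes: Sequence[Box]) -> Box:
    """Smallest box containing every input: componentwise extremes."""
    if len(boxes) == 0:
        raise ValueError("union_box needs at least one box")
    return Box(
        min(b.x_min for b in boxes),
        min(b.y_min for b in boxes),
        max(b.x_max for b in boxes),
        max(b.y_max for b in boxes),
    )


def _track(
    boxes: list[Box | None], clip: FrameSequence, what: str
) -> RoiTrack:
    present = [b for b in boxes if b is not None]
    n_missing = len(boxes) - len(present)
    if n_missing > MAX_MISSING_FRAC * len(boxes):
        raise VideoQualityError(
            f"{what} undetected in {n_missing}/{len(boxes)} frames "
            f"(> {MAX_MISSING_FRAC:.0%}); the full face must be visible "
            "in all frames -- exclude or re-record this video"
        )
    # clip the union to the frame so borderline detections stay usable
    u = union_box(present)
    u = Box(
        max(0, u.x_min), max(0, u.y_min),
        min(clip.width, u.x_max), min(clip.height, u.y_max),
    )
    clipped = [
        b if b is None or u.contains(b)
        else Box(max(b.x_min, u.x_min), max(b.y_min, u.y_min),
                 min(b.x_max, u.x_max), min(b.y_max, u.y_max))
        for b in boxes
    ]
    return RoiTrack(per_frame=tuple(clipped), union=u, n_missing=n_missing)


def detect_face_track(clip: FrameSequence, backend: DetectorBackend) -> RoiTrack:
    """One face-detection attempt per frame; misses recorded, never filled."""
    boxes: list[Box | None] = []
    for i, frame in enumerate(clip.frames):
        face, _ = backend.detect(frame, i)
        boxes.append(face)
    return _track(boxes, clip, "face")


def detect_mouth_track(
    face_clip: FrameSequence,
    backend: DetectorBackend,
    margin_frac: float = 0.15,
) -> RoiTrack:
    """Mouth box per frame from mouth-corner landmarks, then the union rule.

    The landmark bounding box is expanded by ``margin_frac`` of the face
    crop's width/height on each side (landmarks mark the lip corners; the
    tongue can protrude past them), then clipped to the crop.
    """
    boxes: list[Box | None] = []
    h, w = face_clip.height, face_clip.width
    mx = int(round(margin_frac * w))
    my = int(round(margin_frac * h))
    for i, frame in enumerate(face_clip.frames):
        _, landmarks = backend.detect(frame, i)
        if landmarks is None or len(landmarks) == 0:
            boxes.append(None)
            continue
        x0 = int(np.floor(landmarks[:, 0].min())) - mx
        x1 = int(np.ceil(landmarks[:, 0].max())) + mx
        y0 = int(np.floor(landmarks[:, 1].min())) - my
        y1 = int(np.ceil(landmarks[:, 1].max())) + my
        x0, y0 = max(0, x0), max(0, y0)
        x1, y1 = min(w, x1), min(h, y1)
        if x1 <= x0:
            x1 = min(w, x0 + 1)
        if y1 <= y0:
            y1 = min(h, y0 + 1)
        boxes.append(Box(x0, y0, x1, y1))
    return _track(boxes, face_clip, "mouth landmarks")


def extract_roi(clip: FrameSequence, box: Box) -> FrameSequence:
    """Crop every frame to the same box; fps unchanged."""
    if box.x_max > clip.width or box.y_max > clip.height:
        raise ValueError(
            f"box {tuple(box)} exceeds frame size {clip.width}x{clip.height}"
        )
    frames = clip.frames[:, box.y_min : box.y_max, box.x_min : box.x_max, :]
    return FrameSequence(frames.copy(), clip.fps, source_path=clip.source_path)
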