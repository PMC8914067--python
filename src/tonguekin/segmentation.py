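"""Per-frame binary tongue masks from the mouth crop.

Segmentation is a pluggable backend: any callable object with a
``segment(frame) -> binary mask`` method.  The bundled reference backend
thresholds hue and saturation -- exact on the synthetic fixtures, whose
tongue hue is far from every other hue in the scene -- followed by
morphological cleanup and a largest-connected-component filter.  A
trained segmentation network can be slotted in through the same
interface via :class:`ExternalMaskBackend` (masks precomputed by an
external model runner); no network weights are bundled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np
from skimage import color, measure, morphology

from .video import FrameSequence

__all__ = [
    "MaskSequence",
    "SegmentationBackend",
    "ChromaParams",
    "ChromaBackend",
    "ExternalMaskBackend",
    "chroma_segment",
    "segment_clip",
]


@dataclass(frozen=True)
class ChromaParams:
    """Hue/saturation gate for the reference tongue segmenter.

    ``hue_range`` is in degrees on the 0-360 colour circle and may wrap
    (e.g. (300, 20) covers magenta through red-orange).
    """

    hue_range: tuple[float, float] = (300.0, 355.0)
    min_saturation: float = 0.5
    morph_radius_px: int = 1

    def __post_init__(self) -> None:
        if self.morph_radius_px < 0:
            raise ValueError("morph_radius_px must be >= 0")
        lo, hi = self.hue_range
        if lo == hi:
            raise ValueError("hue_range must be a non-empty interval")


@dataclass(frozen=True)
class MaskSequence:
    """Binary tongue masks aligned to the mouth crop, plus the frame rate."""

    masks: np.ndarray  # (n, h, w) bool
    fps: float
    min_area_frac: float = 0.005

    def __post_init__(self) -> None:
        m = np.asarray(self.masks)
        if m.ndim != 3 or m.dtype != bool:
            raise ValueError("masks must be a (n, h, w) boolean array")
        if self.fps <= 0:
            raise ValueError("fps must be positive")


class SegmentationBackend(Protocol):
    name: str

    def segment(self, frame: np.ndarray) -> np.ndarray:
        """Binary mask with the same height/width as ``frame``."""
        ...


def chroma_segment(frame: np.ndarray, params: ChromaParams) -> np.ndarray:
    """Threshold hue/saturation, clean up, keep the largest component."""
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError("frame must be an RGB raster")
    hsv = color.rgb2hsv(frame)
    hue_deg = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    lo, hi = params.hue_range
    if lo <= hi:
        in_hue = (hue_deg >= lo) & (hue_deg <= hi)
    else:  # wrapped interval
        in_hue = (hue_deg >= lo) | (hue_deg <= hi)
    mask = in_hue & (sat >= params.min_saturation)
    if params.morph_radius_px > 0 and mask.any():
        footprint = morphology.disk(params.morph_radius_px)
        mask = morphology.opening(mask, footprint)
        mask = morphology.closing(mask, footprint)
    if mask.any():
        labels = measure.label(mask, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == int(counts.argmax())
    return mask


class ChromaBackend:
    """Reference segmenter: pure colour thresholding."""

    def __init__(self, params: ChromaParams | None = None) -> None:
        self.params = params or ChromaParams()
        self.name = "chroma"

    def segment(self, frame: np.ndarray) -> np.ndarray:
        return chroma_segment(frame, self.params)


class ExternalMaskBackend:
    """Adapter for masks produced by an external segmentation model.

    Reads one ``.npy`` boolean stack per clip (frames x height x width),
    the documented exchange layout for external model runners.
    """

    def __init__(self, mask_stack_path: str | Path) -> None:
        self._masks = np.load(Path(mask_stack_path)).astype(bool)
        self._cursor = 0
        self.name = f"external:{mask_stack_path}"

    def segment(self, frame: np.ndarray) -> np.ndarray:
        mask = self._masks[self._cursor % len(self._masks)]
        self._cursor += 1
        return mask


def segment_clip(
    mouth_clip: FrameSequence,
    backend: SegmentationBackend,
    min_area_frac: float = 0.005,
) -> MaskSequence:
    """Run the backend on every frame of the mouth crop.

    Masks whose foreground covers less than ``min_area_frac`` of the
    crop are zeroed: a few stray pixels are treated as tongue-absent,
    not as a location measurement.
    """
    h, w = mouth_clip.height, mouth_clip.width
    min_area = min_area_frac * h * w
    masks = np.zeros((mouth_clip.n_frames, h, w), dtype=bool)
    for i, frame in enumerate(mouth_clip.frames):
        m = np.asarray(backend.segment(frame)).astype(bool)
        if m.shape != (h, w):
            raise ValueError(
                f"backend {backend.name!r} returned mask of shape {m.shape}, "
                f"expected {(h, w)}"
            )
        if m.sum() >= min_area:
            masks[i] = m
    return MaskSequence(masks=masks, fps=mouth_clip.fps, min_area_frac=min_area_frac)
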