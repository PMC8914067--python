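"""Tongue-movement kinematics from per-frame location records.

The segmentation stage reduces each video frame to a binary tongue mask
inside the mouth crop.  This module turns those masks into a *location
record* -- one symbol per frame, ``L`` or ``R`` for the side of the mouth
midline the tongue centroid falls on, ``U`` when no tongue was detected --
and computes the three kinematic features that summarise a clip:

* number of sweeps -- a sweep runs from halfway through one dwell on a
  side to halfway through the next dwell on the opposite side, so every
  transition between adjacent dwell runs counts one sweep;
* mean sweep duration in seconds (frames / frame rate);
* number of errors -- dwell runs abnormally longer than the average dwell,
  indicating a pause or spasm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .segmentation import MaskSequence

__all__ = [
    "LocationRecord",
    "Run",
    "SweepProfile",
    "KinematicsParams",
    "UnusableVideoError",
    "locate_tongue",
    "run_length_encode",
    "count_sweeps",
    "mean_sweep_duration",
    "detect_errors",
    "profile",
]

_SYMBOLS = frozenset("LRU")


class UnusableVideoError(ValueError):
    """Raised when a record carries no usable tongue locations."""


@dataclass(frozen=True)
class LocationRecord:
    """Per-frame tongue side: ``L``, ``R``, or ``U`` (undetected)."""

    symbols: str
    fps: float

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise ValueError("location record must contain at least one frame")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        bad = set(self.symbols) - _SYMBOLS
        if bad:
            raise ValueError(f"invalid location symbols: {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class Run:
    """A maximal block of consecutive frames with the tongue on one side."""

    side: str
    start_frame: int
    length_frames: int

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError("run side must be 'L' or 'R'")
        if self.length_frames < 1:
            raise ValueError("run length must be >= 1")


@dataclass(frozen=True)
class KinematicsParams:
    """Tunable parameters of the record -> features reduction.

    gap_tolerance_frames
        An undetected (``U``) gap of at most this many frames flanked by
        the *same* side is absorbed into that dwell run; longer gaps only
        interrupt detection, they never fabricate a transition.
    error_sd_multiplier
        ``k`` in the dwell-outlier rule: a run is an error iff its length
        exceeds mean + k * SD of all run lengths (both sides pooled).
    midline_frac
        Horizontal midline position as a fraction of the mouth-crop width.
    """

    gap_tolerance_frames: int = 3
    error_sd_multiplier: float = 2.0
    midline_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_tolerance_frames < 0:
            raise ValueError("gap_tolerance_frames must be >= 0")
        if self.error_sd_multiplier <= 0:
            raise ValueError("error_sd_multiplier must be > 0")
        if not 0.0 < self.midline_frac < 1.0:
            raise ValueError("midline_frac must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class SweepProfile:
    """The kinematic summary of one video clip."""

    n_sweeps: int
    sweep_lengths_frames: tuple[float, ...]
    mean_sweep_duration_s: float | None
    n_errors: int
    n_runs: int
    n_undetected_frames: int
    fps: float

    def __post_init__(self) -> None:
        if self.n_sweeps != max(self.n_runs - 1, 0):
            raise ValueError("n_sweeps must equal max(n_runs - 1, 0)")
        if self.n_errors > self.n_runs:
            raise ValueError("n_errors cannot exceed n_runs")
        if self.n_sweeps > 0:
            expect = float(np.mean(self.sweep_lengths_frames)) / self.fps
            if not math.isclose(self.mean_sweep_duration_s, expect, rel_tol=1e-9):
                raise ValueError("mean_sweep_duration_s inconsistent with lengths")
        elif self.mean_sweep_duration_s is not None:
            raise ValueError("mean duration must be flagged absent with no sweeps")


def locate_tongue(masks: "MaskSequence", midline_frac: float = 0.5) -> LocationRecord:
    """Classify each frame's tongue side from its binary mask.

    An empty mask yields ``U``.  Otherwise the mask centroid's x
    coordinate is compared with ``midline_frac * crop_width``: left of it
    is ``L``, right of it is ``R``.  A centroid exactly on the midline
    inherits the previous frame's side (``U`` at the first frame).
    """
    if len(masks.masks) == 0:
        raise ValueError("mask sequence is empty")
    width = masks.masks[0].shape[1]
    midline = midline_frac * width
    symbols: list[str] = []
    prev = "U"
    for mask in masks.masks:
        ys, xs = np.nonzero(mask)
        if xs.size == 0:
            symbols.append("U")
            continue
        cx = float(xs.mean()) + 0.5  # pixel-centre convention
        if cx < midline:
            side = "L"
        elif cx > midline:
            side = "R"
        else:
            side = prev
        symbols.append(side)
        prev = side
    return LocationRecord("".join(symbols), fps=masks.fps)


def run_length_encode(
    record: LocationRecord, gap_tolerance_frames: int = 3
) -> list[Run]:
    """Compress a location record into alternating dwell runs.

    ``U`` gaps of length <= ``gap_tolerance_frames`` flanked by the same
    side are absorbed into that run (their frames count toward the dwell).
    Longer gaps, gaps with discordant flanks, and leading/trailing gaps
    are dropped; runs of the same side left adjacent by a dropped gap are
    concatenated, so an undetected stretch never creates a transition.
    """
    # raw symbol runs
    raw: list[tuple[str, int, int]] = []  # (symbol, start, length)
    for i, sym in enumerate(record.symbols):
        if raw and raw[-1][0] == sym:
            s, st, ln = raw[-1]
            raw[-1] = (s, st, ln + 1)
        else:
            raw.append((sym, i, 1))

    runs: list[Run] = []
    pending_gap: tuple[int, int] | None = None  # (start, length) of held U run
    for sym, start, length in raw:
        if sym == "U":
            pending_gap = (start, length) if runs else None  # leading gaps drop
            continue
        if runs and runs[-1].side == sym:
            prev = runs[-1]
            if pending_gap is not None and pending_gap[1] <= gap_tolerance_frames:
                # absorb the short same-flanked gap: frames join the dwell
                merged = prev.length_frames + pending_gap[1] + length
            else:
                # long gap interrupts detection; same-side runs concatenate
                merged = prev.length_frames + length
            runs[-1] = Run(sym, prev.start_frame, merged)
        else:
            runs.append(Run(sym, start, length))
        pending_gap = None
    return runs


def count_sweeps(runs: Sequence[Run]) -> tuple[int, list[float]]:
    """Count sweeps and measure each sweep's length in frames.

    A sweep spans from the midpoint of one dwell run to the midpoint of
    the next (the tongue passes mouth centre mid-dwell), so ``n_sweeps``
    is the number of adjacent run pairs and sweep *i* is half of run *i*
    plus half of run *i+1*, fractional halves kept exact.
    """
    for a, b in zip(runs, runs[1:]):
        if a.side == b.side:
            raise ValueError("runs must alternate sides")
    n = max(len(runs) - 1, 0)
    lengths = [
        runs[i].length_frames / 2.0 + runs[i + 1].length_frames / 2.0
        for i in range(n)
    ]
    return n, lengths


def mean_sweep_duration(
    sweep_lengths_frames: Sequence[float], fps: float
) -> float | None:
    """Mean sweep duration in seconds; ``None`` when there are no sweeps."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    if len(sweep_lengths_frames) == 0:
        return None
    return float(np.mean(sweep_lengths_frames)) / fps


def detect_errors(runs: Sequence[Run], k: float = 2.0) -> int:
    """Count dwell-run outliers: runs longer than mean + k * SD.

    Mean and sample SD are pooled over both sides.  With fewer than two
    runs, or zero spread, no run can be an outlier.
    """
    if len(runs) < 1:
        raise ValueError("need at least one run")
    if len(runs) < 2:
        return 0
    lengths = np.array([r.length_frames for r in runs], dtype=float)
    s = float(lengths.std(ddof=1))
    if s == 0.0:
        return 0
    threshold = float(lengths.mean()) + k * s
    return int((lengths > threshold).sum())


def profile(
    record: LocationRecord, params: KinematicsParams | None = None
) -> SweepProfile:
    """Full reduction of a location record to its kinematic features."""
    params = params or KinematicsParams()
    runs = run_length_encode(record, params.gap_tolerance_frames)
    if not runs:
        raise UnusableVideoError(
            "no tongue detected in any frame; clip fails quality inspection"
        )
    n_sweeps, lengths = count_sweeps(runs)
    return SweepProfile(
        n_sweeps=n_sweeps,
        sweep_lengths_frames=tuple(lengths),
        mean_sweep_duration_s=mean_sweep_duration(lengths, record.fps),
        n_errors=detect_errors(runs, params.error_sd_multiplier),
        n_runs=len(runs),
        n_undetected_frames=record.symbols.count("U"),
        fps=record.fps,
    )
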