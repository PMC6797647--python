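"""Frame sequences, spatiotemporal cropping and region-of-interest location.

A recording is held as a :class:`FrameSequence`: an ordered stack of 8-bit
RGB frames with a frame rate.  Analysis crops the sequence in time (the
first seconds of a recording typically contain automatic camera gain
adjustments, the last seconds anticipatory movement) and in space to a
fixed region of interest containing skin.  Face location is pluggable: any
callable that maps a frame to a bounding box (e.g. a cascade detector) can
be injected, and a manually chosen box always works.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .avi import read_rgb_avi

__all__ = ["FrameSequence", "BBox", "load_frames", "crop_time", "crop_roi", "locate_face"]

logger = logging.getLogger(__name__)

#: A face/ROI detector: frame (H, W, 3) uint8 -> BBox or None if no face found.
FaceDetector = Callable[[np.ndarray], Optional["BBox"]]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned pixel box, 0-based, half-open [x, x+w) x [y, y+h)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError(f"box extent must be >= 1 pixel, got w={self.w}, h={self.h}")
        if self.x < 0 or self.y < 0:
            raise ValueError(f"box origin must be non-negative, got ({self.x}, {self.y})")

    def fits(self, height: int, width: int) -> bool:
        return self.x + self.w <= width and self.y + self.h <= height


@dataclass(frozen=True)
class FrameSequence:
    """Ordered 8-bit RGB frames with a frame rate.

    frames : (n, H, W, 3) uint8 array, channel order R, G, B
    fps    : frames per second, finite and > 0
    t0     : time of the first frame in seconds (advanced by temporal crops)
    """

    frames: np.ndarray = field(repr=False)
    fps: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        f = self.frames
        if f.ndim != 4 or f.shape[-1] != 3:
            raise ValueError(f"frames must be (n, H, W, 3), got shape {f.shape}")
        if f.shape[0] < 1:
            raise ValueError("a FrameSequence needs at least one frame")
        if f.dtype != np.uint8:
            raise ValueError(f"frames must be uint8, got {f.dtype}")
        if not (np.isfinite(self.fps) and self.fps > 0):
            raise ValueError(f"fps must be finite and > 0, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


def load_frames(path: str | Path, fps_override: float | None = None) -> FrameSequence:
    """Read a video file into a FrameSequence.

    Channel order is normalised to R, G, B regardless of the container's
    storage convention.  If the container reports no frame rate,
    ``fps_override`` is required; when both are present the override wins.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"video file not found: {path}")
    try:
        frames, fps = read_rgb_avi(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with the path
        raise IOError(f"could not decode video {path}: {exc}") from exc
    if frames.shape[0] == 0:
        raise ValueError(f"video {path} contains no frames")
    if fps_override is not None:
        if fps:
            logger.info("overriding container fps %.3f with %.3f for %s", fps, fps_override, path)
        fps = float(fps_override)
    if not fps:
        raise ValueError(
            f"video {path} reports no frame rate; pass fps_override"
        )
    return FrameSequence(frames=frames, fps=float(fps))


def crop_time(seq: FrameSequence, head_s: float = 3.0, tail_s: float = 3.0) -> FrameSequence:
    """Drop the first ``head_s`` and last ``tail_s`` seconds.

    Frame counts are rounded up (ceil), guaranteeing at least the stated
    seconds are removed on each side.
    """
    if seq.duration_s <= head_s + tail_s:
        raise ValueError(
            f"sequence of {seq.duration_s:.2f}s too short for temporal crop; "
            f"need strictly more than {head_s + tail_s:.2f}s"
        )
    head = math.ceil(head_s * seq.fps)
    tail = math.ceil(tail_s * seq.fps)
    frames = seq.frames[head : seq.n_frames - tail]
    return replace(seq, frames=frames, t0=seq.t0 + head_s)


def crop_roi(seq: FrameSequence, box: BBox) -> FrameSequence:
    """Crop every frame to ``box``; fps and t0 unchanged."""
    h, w = seq.frame_shape
    if not box.fits(h, w):
        raise ValueError(f"ROI {box} exceeds frame bounds {h}x{w}")
    frames = seq.frames[:, box.y : box.y + box.h, box.x : box.x + box.w]
    return replace(seq, frames=frames)


def locate_face(
    seq: FrameSequence,
    detector: FaceDetector | None = None,
    manual: BBox | None = None,
) -> BBox:
    """One fixed face/ROI box for the whole sequence.

    A manual box passes through unchanged; otherwise the injected detector
    runs on the first frame.  The box is fixed for the sequence — the
    method assumes a stabilised subject, not per-frame tracking.
    """
    if manual is not None:
        h, w = seq.frame_shape
        if not manual.fits(h, w):
            raise ValueError(f"manual ROI {manual} exceeds frame bounds {h}x{w}")
        return manual
    if detector is None:
        raise ValueError("no face detector injected and no manual ROI given")
    box = detector(seq.frames[0])
    if box is None:
        raise RuntimeError(
            "face detection failed on the first frame; supply a manual ROI "
            "(e.g. --roi x,y,w,h)"
        )
    return box
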