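"""Skin-pixel selection inside a region of interest.

Two methods, matching common practice in camera-based pulse measurement:

* **auto (k-means)** — cluster the ROI's pixels in the chromatic (a, b)
  plane of CIELAB (lightness is deliberately ignored, so shading does not
  split the skin), then keep the cluster holding the most pixels in the
  central part of the box, where the face is expected to dominate.
* **manual (wedge)** — keep pixels whose hue lies within an angular wedge
  and whose saturation lies within a radial band of the hue–saturation
  plane.  The wedge is set once on the first frame and reused.

Both return a boolean :class:`SkinMask` over the ROI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Literal, Sequence

import numpy as np
from skimage.color import rgb2hsv, rgb2lab
from sklearn.cluster import KMeans

from .video import BBox, FrameSequence

__all__ = [
    "SkinMask",
    "WedgeSpec",
    "kmeans_skin_mask",
    "wedge_skin_mask",
    "mask_per_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SkinMask:
    """Boolean pixel selection over an ROI."""

    mask: np.ndarray = field(repr=False)
    frame_shape: tuple[int, int]
    method: Literal["auto_kmeans", "manual_wedge", "full_box"]
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.dtype != bool or m.shape != tuple(self.frame_shape):
            raise ValueError(
                f"mask must be boolean with shape {self.frame_shape}, "
                f"got {m.dtype} {m.shape}"
            )

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def to_png(self, path) -> None:
        """Write the mask as an 8-bit PNG (selected=255) for inspection."""
        from PIL import Image

        Image.fromarray(self.mask.astype(np.uint8) * 255, mode="L").save(path)


@dataclass(frozen=True)
class WedgeSpec:
    """Angular hue wedge plus saturation band in the hue–saturation plane.

    hue_center and hue_halfwidth are in degrees (hue is circular, [0, 360));
    saturations are fractions in [0, 1].  The defaults bracket typical
    facial skin under indoor illumination (mean facial RGB around
    (208, 150, 136), i.e. hue near 12 degrees).
    """

    hue_center: float = 15.0
    hue_halfwidth: float = 25.0
    sat_min: float = 0.15
    sat_max: float = 0.80

    def __post_init__(self) -> None:
        if not 0 <= self.hue_center < 360:
            raise ValueError(f"hue_center must be in [0, 360), got {self.hue_center}")
        if not 0 < self.hue_halfwidth <= 180:
            raise ValueError(f"hue_halfwidth must be in (0, 180], got {self.hue_halfwidth}")
        if not (0 <= self.sat_min < self.sat_max <= 1):
            raise ValueError(
                f"need 0 <= sat_min < sat_max <= 1, got [{self.sat_min}, {self.sat_max}]"
            )


def _roi_view(frame: np.ndarray, box: BBox) -> np.ndarray:
    h, w = frame.shape[:2]
    if not box.fits(h, w):
        raise ValueError(f"box {box} exceeds frame bounds {h}x{w}")
    return frame[box.y : box.y + box.h, box.x : box.x + box.w]


def _central_region(box_h: int, box_w: int) -> tuple[slice, slice]:
    """Central window of half the ROI's height and width, centered."""
    ch, cw = max(1, box_h // 2), max(1, box_w // 2)
    y0 = (box_h - ch) // 2
    x0 = (box_w - cw) // 2
    return slice(y0, y0 + ch), slice(x0, x0 + cw)


def kmeans_skin_mask(
    frame: np.ndarray,
    box: BBox,
    k: int = 4,
    max_iter: int = 100,
    seed: int = 0,
) -> SkinMask:
    """Automatic skin selection by k-means in CIELAB (a, b).

    Pixels in the box are converted sRGB -> CIELAB (D65 white point) and
    clustered on their (a, b) chromaticity with squared Euclidean distance.
    The winning cluster is the one with the most member pixels inside the
    central half-size window of the box; ties break toward the cluster
    whose centroid is closest to that window's mean chromaticity.

    A chromatically uniform ROI cannot be split into k clusters; in that
    degenerate case the whole box is selected and a warning is issued.
    """
    if k < 2:
        raise ValueError(f"need k >= 2 clusters, got {k}")
    roi = _roi_view(frame, box)
    lab = rgb2lab(roi.astype(np.float64) / 255.0)
    ab = lab[..., 1:].reshape(-1, 2)
    params = {"k": k, "max_iter": max_iter, "seed": seed}

    n_unique = np.unique(ab, axis=0).shape[0]
    if n_unique < k:
        warnings.warn(
            f"ROI has only {n_unique} distinct chromaticities; k-means with "
            f"k={k} is degenerate — selecting the whole box",
            stacklevel=2,
        )
        return SkinMask(
            mask=np.ones(roi.shape[:2], dtype=bool),
            frame_shape=roi.shape[:2],
            method="full_box",
            params=params,
        )

    km = KMeans(n_clusters=k, n_init=1, max_iter=max_iter, random_state=seed)
    labels = km.fit_predict(ab).reshape(roi.shape[:2])

    ys, xs = _central_region(*roi.shape[:2])
    central_labels = labels[ys, xs]
    counts = np.bincount(central_labels.ravel(), minlength=k)
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if len(tied) > 1:
        center_mean = lab[ys, xs, 1:].reshape(-1, 2).mean(axis=0)
        dists = np.linalg.norm(km.cluster_centers_[tied] - center_mean, axis=1)
        winner = int(tied[np.argmin(dists)])
    else:
        winner = int(tied[0])

    return SkinMask(
        mask=labels == winner,
        frame_shape=roi.shape[:2],
        method="auto_kmeans",
        params=params,
    )


def circular_hue_distance(a: float | np.ndarray, b: float | np.ndarray) -> np.ndarray:
    """Shortest angular distance between hues in degrees."""
    d = np.abs(np.asarray(a, dtype=float) - b) % 360.0
    return np.minimum(d, 360.0 - d)


def wedge_skin_mask(frame: np.ndarray, box: BBox, wedge: WedgeSpec) -> SkinMask:
    """Manual skin selection: hue within the wedge AND saturation in band."""
    roi = _roi_view(frame, box)
    hsv = rgb2hsv(roi.astype(np.float64) / 255.0)
    hue_deg = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    mask = (circular_hue_distance(hue_deg, wedge.hue_center) <= wedge.hue_halfwidth) & (
        (sat >= wedge.sat_min) & (sat <= wedge.sat_max)
    )
    if not mask.any():
        raise ValueError(
            "wedge selected no pixels; widen hue_halfwidth or the saturation band"
        )
    return SkinMask(
        mask=mask,
        frame_shape=roi.shape[:2],
        method="manual_wedge",
        params={
            "hue_center": wedge.hue_center,
            "hue_halfwidth": wedge.hue_halfwidth,
            "sat_min": wedge.sat_min,
            "sat_max": wedge.sat_max,
        },
    )


def mask_per_frame(
    seq: FrameSequence,
    box: BBox,
    method: Literal["auto", "wedge"] = "auto",
    *,
    wedge: WedgeSpec | None = None,
    k: int = 4,
    max_iter: int = 100,
    seed: int = 0,
) -> list[SkinMask]:
    """Apply the chosen skin-selection method to every frame.

    The automatic method re-clusters each frame with the same seed and
    parameters (robust to slow illumination drift); the manual method
    reapplies the wedge set for the first frame.
    """
    if method == "wedge" and wedge is None:
        wedge = WedgeSpec()
    masks: list[SkinMask] = []
    for i in range(seq.n_frames):
        try:
            if method == "auto":
                m = kmeans_skin_mask(seq.frames[i], box, k=k, max_iter=max_iter, seed=seed)
            elif method == "wedge":
                m = wedge_skin_mask(seq.frames[i], box, wedge)  # type: ignore[arg-type]
            else:
                raise ValueError(f"unknown skin method {method!r}")
        except ValueError as exc:
            raise ValueError(f"skin selection failed at frame {i}: {exc}") from exc
        masks.append(m)
    return masks
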