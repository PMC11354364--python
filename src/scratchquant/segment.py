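"""Wound segmentation: threshold the entropy map, clean up, keep wound components.

Pipeline (deterministic): local entropy -> 8-bit rescale -> candidate wound =
pixels BELOW the integer threshold (a cell-free scratch is texture-poor) ->
morphological closing then opening with a small disk -> connected components
-> drop components smaller than a fraction of the frame -> union of the
survivors.  Per-cell-line presets carry the disc size and threshold pairs
used for TOV-21G (20, 92) and SK-OV-3 (50, 92).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage import morphology
from skimage.draw import polygon2mask
from skimage.measure import label

from .entropy import local_entropy, make_disk, rescale_entropy
from .image_io import GrayImage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the wound segmentation pipeline.

    ``disc_size`` is interpreted as the disk RADIUS in pixels (the dominant
    rank-filter convention); set ``disc_is_diameter`` to treat it as a
    diameter instead.  ``cleanup_radius`` defaults to ceil(disc_size/4),
    tying the morphological cleanup to the texture scale.
    """

    disc_size: int = 20
    threshold: int = 92
    entropy_scale: str = "per_image_max"
    min_component_frac: float = 0.005
    cleanup_radius: int | None = None
    connectivity: int = 8
    disc_is_diameter: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.threshold <= 255):
            raise ValueError("threshold must be in [0, 255]")
        if self.disc_size < 1:
            raise ValueError("disc_size must be >= 1")
        if not (0 <= self.min_component_frac < 1):
            raise ValueError("min_component_frac must be in [0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.entropy_scale not in ("per_image_max", "fixed_8bit"):
            raise ValueError(f"unknown entropy_scale {self.entropy_scale!r}")

    @property
    def radius(self) -> int:
        """Effective disk radius in pixels."""
        return max(1, self.disc_size // 2) if self.disc_is_diameter else self.disc_size

    @property
    def effective_cleanup_radius(self) -> int:
        if self.cleanup_radius is not None:
            return self.cleanup_radius
        return math.ceil(self.radius / 4)


#: Per-cell-line parameter presets (disc size, threshold).
PRESETS: dict[str, SegmentationParams] = {
    "tov21g": SegmentationParams(disc_size=20, threshold=92),
    "skov3": SegmentationParams(disc_size=50, threshold=92),
}


@dataclass(frozen=True)
class WoundMask:
    """Boolean wound region (True = wound) plus derived area quantities."""

    pixels: np.ndarray
    n_components_kept: int = 1
    overridden: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("mask must be a non-empty 2-D boolean grid")
        object.__setattr__(self, "pixels", px)

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def area_frac(self) -> float:
        return self.area_px / self.pixels.size

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


def candidate_wound(img: GrayImage, params: SegmentationParams) -> np.ndarray:
    """Raw below-threshold low-entropy candidate mask, before any cleanup."""
    emap = local_entropy(img, make_disk(params.radius))
    rescaled = rescale_entropy(emap, params.entropy_scale)
    return rescaled.pixels < params.threshold


def segment_wound(img: GrayImage, params: SegmentationParams) -> WoundMask:
    """Segment the cell-free wound region of a micrograph.

    Deterministic.  Emits a warning (but proceeds) when the frame is
    smaller than 3x the disc size per axis, where the entropy texture
    statistic becomes unreliable.
    """
    h, w = img.pixels.shape
    if h < 3 * params.radius or w < 3 * params.radius:
        logger.warning(
            "frame %dx%d is smaller than 3x disc size (%d); segmentation may be unreliable",
            h, w, params.radius,
        )
    cand = candidate_wound(img, params)
    cr = params.effective_cleanup_radius
    if cr > 0:
        fp = morphology.disk(cr)
        cand = morphology.closing(cand, fp)
        cand = morphology.opening(cand, fp)
    lab, n = label(cand, connectivity=1 if params.connectivity == 4 else 2, return_num=True)
    min_area = params.min_component_frac * cand.size
    kept = 0
    out = np.zeros_like(cand)
    if n:
        areas = np.bincount(lab.ravel())[1:]
        keep_ids = np.flatnonzero(areas >= min_area) + 1
        kept = len(keep_ids)
        if kept:
            out = np.isin(lab, keep_ids)
    return WoundMask(pixels=out, n_components_kept=kept)


def apply_override(mask: WoundMask, roi, mode: str = "replace") -> WoundMask:
    """Apply a supervisor-supplied region of interest to a wound mask.

    ``roi`` is either a raster boolean mask of the same shape or an
    (N, 2) array of (row, col) polygon vertices lying inside the frame.
    ``mode`` is ``replace``, ``intersect`` or ``union``; the returned mask
    carries ``overridden=True`` and recomputed areas.
    """
    if mode not in ("replace", "intersect", "union"):
        raise ValueError(f"unknown override mode {mode!r}")
    roi = np.asarray(roi)
    if roi.ndim == 2 and roi.dtype != bool and roi.shape[1] == 2:
        h, w = mask.shape
        if roi.size and (
            roi[:, 0].min() < 0 or roi[:, 0].max() > h or roi[:, 1].min() < 0 or roi[:, 1].max() > w
        ):
            raise ValueError("polygon roi vertices fall outside the frame bounds")
        roi_mask = polygon2mask(mask.shape, roi)
    else:
        roi_mask = roi.astype(bool)
        if roi_mask.shape != mask.shape:
            raise ValueError(
                f"raster roi shape {roi_mask.shape} does not match frame {mask.shape}"
            )
    if mode == "replace":
        out = roi_mask
    elif mode == "intersect":
        out = mask.pixels & roi_mask
    else:
        out = mask.pixels | roi_mask
    n = label(out, connectivity=2, return_num=True)[1]
    return WoundMask(pixels=out, n_components_kept=n, overridden=True)
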