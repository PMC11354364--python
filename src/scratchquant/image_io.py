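"""Raster I/O: canonical 8-bit grayscale images, mask PNGs, CSV reports.

Micrographs arrive as 8- or 16-bit TIFF/PNG, single channel or RGB; they
are canonicalized to an 8-bit grayscale :class:`GrayImage` before any
entropy computation so that the integer thresholds used downstream have a
fixed meaning.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

#: Rec.601 luma weights for RGB collapse.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2-D 8-bit grayscale image, the unit of segmentation input.

    Parameters
    ----------
    pixels
        2-D uint8 array of intensities in [0, 255].
    source_id
        Free-text provenance label (file path, generator spec, ...).
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("GrayImage requires a non-empty 2-D pixel grid")
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise ValueError("GrayImage pixels must be integers in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _collapse_rgb(arr: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) raster to luminance, preserving input dtype."""
    if arr.ndim == 3:
        if arr.shape[2] >= 3:
            arr = arr[:, :, :3].astype(np.float64) @ _LUMA
            arr = np.rint(arr)
        else:  # single-channel stored with a trailing axis
            arr = arr[:, :, 0].astype(np.float64)
    return arr


def load_gray(path: str | os.PathLike, bit_policy: str = "minmax") -> GrayImage:
    """Read a raster image as a canonical 8-bit :class:`GrayImage`.

    RGB inputs are collapsed to integer-rounded Rec.601 luminance.  16-bit
    inputs are mapped to [0, 255] per ``bit_policy``:

    - ``minmax``: linear stretch, image min -> 0 and max -> 255 (a
      zero-dynamic-range image maps to all zeros with a logged warning);
    - ``fixed_shift``: each value right-shifted by 8 bits, preserving
      cross-image comparability.

    8-bit inputs pass through unchanged.
    """
    if bit_policy not in ("minmax", "fixed_shift"):
        raise ValueError(f"unknown bit_policy {bit_policy!r}")
    try:
        arr = iio.imread(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {os.fspath(path)!r}: {exc}") from exc

    raw16 = arr.dtype == np.uint16
    arr = _collapse_rgb(np.asarray(arr))
    if raw16 or arr.max(initial=0) > 255:
        arr = arr.astype(np.float64)
        if bit_policy == "minmax":
            lo, hi = arr.min(), arr.max()
            if hi == lo:
                logger.warning(
                    "zero-dynamic-range 16-bit image %s: mapping all pixels to 0",
                    path,
                )
                arr = np.zeros_like(arr)
            else:
                arr = np.rint(255.0 * (arr - lo) / (hi - lo))
        else:  # fixed_shift
            arr = np.floor(arr).astype(np.int64) >> 8
    out = np.clip(np.rint(np.asarray(arr, dtype=np.float64)), 0, 255).astype(np.uint8)
    return GrayImage(out, source_id=os.fspath(path))


def save_mask(mask, path: str | os.PathLike) -> None:
    """Write a wound mask as a lossless single-channel PNG (wound=255)."""
    px = np.asarray(mask.pixels, dtype=bool)
    if px.ndim != 2 or px.size == 0:
        raise ValueError("mask dimensions must be positive")
    try:
        iio.imwrite(os.fspath(path), (px.astype(np.uint8) * 255), extension=".png")
    except OSError as exc:
        raise OSError(f"cannot write mask to {os.fspath(path)!r}: {exc}") from exc


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Read back a mask PNG written by :func:`save_mask` as a boolean array."""
    arr = iio.imread(os.fspath(path))
    arr = _collapse_rgb(np.asarray(arr))
    return np.asarray(arr) > 127


def write_report(rows: list[dict], path: str | os.PathLike, fieldnames: list[str] | None = None) -> None:
    """Write labeled measurement records as a UTF-8 CSV with a header row.

    All rows must share one schema; numeric fields are serialized with at
    least 6 significant digits and a '.' decimal separator.
    """
    import csv

    if fieldnames is None:
        fieldnames = list(rows[0].keys()) if rows else []
    for i, row in enumerate(rows):
        extra = set(row) - set(fieldnames)
        missing = set(fieldnames) - set(row)
        if extra or missing:
            raise ValueError(
                f"row {i} does not match the report schema: "
                f"unexpected fields {sorted(extra)}, missing fields {sorted(missing)}"
            )

    def _fmt(v):
        if isinstance(v, bool) or not isinstance(v, (int, float, np.integer, np.floating)):
            return v
        if isinstance(v, (int, np.integer)):
            return int(v)
        return f"{float(v):.9g}"

    with open(os.fspath(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: _fmt(v) for k, v in row.items()})
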