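"""Local Shannon entropy over a disk neighborhood.

This is the texture statistic the whole segmentation rests on: for every
pixel, the 256-bin intensity histogram of the disk-shaped neighborhood is
formed (out-of-frame positions filled by reflect padding) and its Shannon
entropy H = -sum p_i log2 p_i, in bits, is returned.  A confluent cell
monolayer in phase contrast is texture-rich (H high); a cell-free scratch
is flat (H near zero), which is what makes a single threshold on H separate
the two.

The filter is implemented as a numba-compiled sliding-histogram pass: the
disk histogram is updated incrementally as the window moves along a row
(one column of pixels enters, one leaves per disk row), together with a
running value of S = sum c_i log2 c_i, so each output pixel costs
O(disk diameter) rather than O(disk area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np


@dataclass(frozen=True)
class DiskNeighborhood:
    """All integer lattice offsets (dy, dx) with dy^2 + dx^2 <= radius^2."""

    radius: int
    offsets: tuple  # tuple of (dy, dx) pairs, row-major order

    @property
    def size(self) -> int:
        return len(self.offsets)

    @property
    def footprint(self) -> np.ndarray:
        """The disk as a (2r+1, 2r+1) boolean stencil."""
        r = self.radius
        fp = np.zeros((2 * r + 1, 2 * r + 1), dtype=bool)
        for dy, dx in self.offsets:
            fp[dy + r, dx + r] = True
        return fp

    @property
    def half_widths(self) -> np.ndarray:
        """For each dy in [-r, r], the maximal |dx| inside the disk."""
        r = self.radius
        return np.array(
            [int(np.floor(np.sqrt(r * r - dy * dy))) for dy in range(-r, r + 1)],
            dtype=np.int64,
        )


@dataclass(frozen=True)
class EntropyMap:
    """Per-pixel local entropy in bits, same shape as the source image."""

    values: np.ndarray
    radius_used: int

    @property
    def shape(self) -> tuple:
        return self.values.shape


def make_disk(radius: int) -> DiskNeighborhood:
    """Enumerate the closed Euclidean disk of the given integer radius.

    The offset set always contains (0, 0) and is centrosymmetric.
    """
    if not float(radius).is_integer() or radius < 1:
        raise ValueError(f"disk radius must be an integer >= 1, got {radius!r}")
    radius = int(radius)
    r2 = radius * radius
    offs = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= r2
    ]
    return DiskNeighborhood(radius=radius, offsets=tuple(offs))


def _pad_reflect(pixels: np.ndarray, r: int) -> np.ndarray:
    """Reflect-pad by r on each side; chunked so r may exceed the frame size."""
    out = pixels
    remaining = r
    while remaining > 0:
        step = min(remaining, min(out.shape) - 1)
        if step < 1:
            raise ValueError("image too small to reflect-pad (needs >= 2 px per axis)")
        out = np.pad(out, step, mode="reflect")
        remaining -= step
    return out


@numba.njit(cache=True)
def _entropy_pass(padded, half_widths, r, n, clog2c, out):  # pragma: no cover - compiled
    height, width = out.shape
    log2n = np.log2(n)
    hist = np.zeros(256, dtype=np.int64)
    for y in range(height):
        hist[:] = 0
        # build the initial histogram for x = 0
        for i in range(2 * r + 1):
            w = half_widths[i]
            row = padded[y + i]
            for dx in range(-w, w + 1):
                hist[row[r + dx]] += 1
        s = 0.0
        for v in range(256):
            s += clog2c[hist[v]]
        h0 = log2n - s / n
        # snap float residue (~1e-15 on single-bin histograms) to exact zero
        out[y, 0] = h0 if h0 > 1e-12 else 0.0
        for x in range(1, width):
            for i in range(2 * r + 1):
                w = half_widths[i]
                row = padded[y + i]
                old = row[x - 1 + r - w]
                c = hist[old]
                s += clog2c[c - 1] - clog2c[c]
                hist[old] = c - 1
                new = row[x + r + w]
                c = hist[new]
                s += clog2c[c + 1] - clog2c[c]
                hist[new] = c + 1
            h = log2n - s / n
            out[y, x] = h if h > 1e-12 else 0.0
    return out


def local_entropy(img, disk: DiskNeighborhood, padding: str = "reflect") -> EntropyMap:
    """Local Shannon entropy (bits) of ``img`` over ``disk``, reflect-padded.

    Deterministic; the result has the same shape as the image and values in
    [0, min(8, log2(|disk|))].
    """
    if padding != "reflect":
        raise ValueError("only reflect padding is supported")
    pixels = np.asarray(img.pixels if hasattr(img, "pixels") else img, dtype=np.uint8)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError("image must be a non-empty 2-D grid")
    r = disk.radius
    padded = _pad_reflect(pixels, r)
    n = disk.size
    counts = np.arange(n + 1, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        clog2c = counts * np.log2(counts)
    clog2c[0] = 0.0
    out = np.empty(pixels.shape, dtype=np.float64)
    _entropy_pass(padded, disk.half_widths, r, float(n), clog2c, out)
    return EntropyMap(values=out, radius_used=r)


def rescale_entropy(emap: EntropyMap, mode: str = "per_image_max"):
    """Map an entropy map onto the 8-bit scale used for integer thresholding.

    ``per_image_max`` sends the image's own maximum to 255 (an all-zero map
    stays all-zero); ``fixed_8bit`` uses the absolute 0-8 bit range so maps
    are comparable across images.
    """
    from .image_io import GrayImage

    v = np.asarray(emap.values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("entropy map is empty")
    if mode == "per_image_max":
        vmax = v.max()
        scaled = np.zeros_like(v) if vmax == 0 else 255.0 * v / vmax
    elif mode == "fixed_8bit":
        scaled = 255.0 * v / 8.0
    else:
        raise ValueError(f"unknown rescale mode {mode!r}")
    return GrayImage(
        np.clip(np.rint(scaled), 0, 255).astype(np.uint8),
        source_id=f"entropy[{mode},r={emap.radius_used}]",
    )
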