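"""Synthetic inputs with exact ground truth for every pipeline stage.

The scratch-image generator emulates what the entropy segmentation relies
on: a texture-rich "monolayer" (i.i.d. uniform intensities by default, the
highest-entropy 8-bit texture) interrupted by a flat, noisy "wound" band of
known geometry with ragged random-walk edges.  The plate generator draws
absorbances from a four-parameter logistic (4PL) dose-response with a known
GI50; the Cq generator builds tables whose true fold changes are known by
construction.  Every generator is a pure function of (spec, seed): identical
inputs give bitwise-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assays import CqTable, WellReading
from .image_io import GrayImage
from .kinetics import ScratchSeries
from .segment import WoundMask


def _two_fold_dilutions(top: float = 200.0, n: int = 8) -> tuple:
    return tuple(top / 2.0 ** k for k in range(n))


@dataclass(frozen=True)
class ScratchSpec:
    """Geometry, texture and noise of one synthetic scratched-monolayer image."""

    height: int = 256
    width: int = 256
    wound_frac: float = 0.3
    orientation: str = "vertical"  # wound band runs vertically or horizontally
    edge_roughness: int = 3  # px amplitude of the band-edge random walk
    cell_texture: str = "iid_uniform"  # or "speckle"
    speckle_p: float = 0.5
    wound_level: int = 128
    wound_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.wound_frac < 1):
            raise ValueError("wound_frac must be in [0, 1)")
        if self.orientation not in ("vertical", "horizontal"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.cell_texture not in ("iid_uniform", "speckle"):
            raise ValueError(f"unknown cell_texture {self.cell_texture!r}")
        if not (0 <= self.wound_level <= 255):
            raise ValueError("wound_level must be in [0, 255]")


@dataclass(frozen=True)
class PlateSpec:
    """A 4PL dose-response microplate with known GI50 and serial dilutions."""

    gi50_true: float = 25.0
    hill: float = 1.0
    top: float = 100.0  # viability % plateau at zero dose
    bottom: float = 0.0  # viability % plateau at saturating dose
    dilutions: tuple = field(default_factory=_two_fold_dilutions)  # uM, decreasing
    noise_sd: float = 0.0  # absorbance units
    blank: float = 0.05  # shared background absorbance offset
    control_signal: float = 1.0  # control (C - Cc) absorbance
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.dilutions)
        if len(d) < 8 or any(b >= a for a, b in zip(d, d[1:])) or any(x <= 0 for x in d):
            raise ValueError("dilutions must be >= 8 strictly decreasing positive values")
        object.__setattr__(self, "dilutions", d)

    def viability_at(self, conc: float) -> float:
        """Noise-free 4PL viability % at a concentration."""
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (conc / self.gi50_true) ** self.hill
        )


def _band_edges(spec: ScratchSpec, band_px: int, length: int, rng: np.random.Generator):
    """Left/right (or top/bottom) edge positions per cross-section row.

    Each edge follows an independent +-1 random walk clipped to the
    roughness amplitude, mimicking the ragged edge a pipette tip leaves.
    """
    extent = spec.width if spec.orientation == "vertical" else spec.height
    lo = (extent - band_px) // 2
    hi = lo + band_px
    if spec.edge_roughness > 0 and band_px > 0:
        amp = spec.edge_roughness
        walk_lo = np.clip(np.cumsum(rng.choice((-1, 1), size=length)), -amp, amp)
        walk_hi = np.clip(np.cumsum(rng.choice((-1, 1), size=length)), -amp, amp)
        left = np.clip(lo + walk_lo, 0, extent)
        right = np.clip(hi + walk_hi, 0, extent)
        right = np.maximum(right, left)  # never negative-width
    else:
        left = np.full(length, lo)
        right = np.full(length, hi)
    return left, right


def _texture(spec: ScratchSpec, rng: np.random.Generator) -> np.ndarray:
    shape = (spec.height, spec.width)
    if spec.cell_texture == "iid_uniform":
        return rng.integers(0, 256, size=shape, dtype=np.int64)
    # speckle: two-level salt texture, high with probability p
    return np.where(rng.random(shape) < spec.speckle_p, 255, 0).astype(np.int64)


def make_scratch_image(
    spec: ScratchSpec, closure_frac: float = 1.0
) -> tuple[GrayImage, WoundMask]:
    """Render one scratched-monolayer image and its exact truth mask.

    ``closure_frac`` scales the wound band width (1.0 = the freshly made
    scratch) while reusing the same seeded texture and noise streams, so a
    closing time-series shares its background.  The returned truth mask is
    the realized band, exact by construction.
    """
    if not (0 <= closure_frac <= 1):
        raise ValueError("closure_frac must be in [0, 1]")
    rng_tex = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    rng_geom = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    rng_noise = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))

    img = _texture(spec, rng_tex)
    extent = spec.width if spec.orientation == "vertical" else spec.height
    length = spec.height if spec.orientation == "vertical" else spec.width
    band_px = round(spec.wound_frac * extent * closure_frac)
    truth = np.zeros((spec.height, spec.width), dtype=bool)
    if band_px > 0:
        left, right = _band_edges(spec, band_px, length, rng_geom)
        cols = np.arange(extent)
        in_band = (cols[None, :] >= left[:, None]) & (cols[None, :] < right[:, None])
        if spec.orientation == "horizontal":
            in_band = in_band.T
        truth = in_band
        wound = spec.wound_level + rng_noise.normal(
            0.0, spec.wound_noise_sd, size=truth.shape
        )
        img = np.where(truth, np.rint(wound), img)
    pixels = np.clip(img, 0, 255).astype(np.uint8)
    gray = GrayImage(pixels, source_id=f"synth[seed={spec.seed},cf={closure_frac:g}]")
    return gray, WoundMask(pixels=truth)


def make_series(
    spec: ScratchSpec, closure_fracs: tuple, times_h: tuple
) -> tuple[tuple, ScratchSeries]:
    """A closing time-series of scratch images plus the exact truth masks.

    Timepoint k reuses the spec's texture seed with the band scaled to
    ``wound_frac * closure_fracs[k]``.  The first closure fraction must be
    1.0 (the T0 frame).  Returns the images and a :class:`ScratchSeries`
    whose masks are the exact truths.
    """
    closure_fracs = tuple(closure_fracs)
    times_h = tuple(times_h)
    if len(closure_fracs) != len(times_h):
        raise ValueError("closure_fracs and times_h must have equal length")
    if not closure_fracs or closure_fracs[0] != 1.0:
        raise ValueError("closure_fracs must start at 1.0 (the T0 frame)")
    images, truths = [], []
    for cf in closure_fracs:
        img, truth = make_scratch_image(spec, closure_frac=cf)
        images.append(img)
        truths.append(truth)
    truth_series = ScratchSeries(
        well_id=f"synth-{spec.seed}",
        timepoints=tuple(zip(times_h, truths)),
    )
    return tuple(images), truth_series


def make_plate(spec: PlateSpec) -> list[WellReading]:
    """Simulate a dual-wavelength MTT plate from a 4PL dose-response.

    Treated 570 nm absorbance is blank + viability/100 * control signal
    (+ Gaussian noise); the 630 nm background is the blank (+ noise).
    Control and background wells are included.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 10]))

    def noisy(x: float) -> float:
        return float(x + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0))

    wells: list[WellReading] = []
    for _ in range(spec.n_replicates):
        wells.append(
            WellReading(
                a570=noisy(spec.blank + spec.control_signal),
                a630=noisy(spec.blank),
                role="control",
            )
        )
    for conc in sorted(spec.dilutions):
        v = spec.viability_at(conc)
        for _ in range(spec.n_replicates):
            wells.append(
                WellReading(
                    a570=noisy(spec.blank + v / 100.0 * spec.control_signal),
                    a630=noisy(spec.blank),
                    role="treated",
                    concentration=conc,
                )
            )
    return wells


def make_cq_table(
    true_folds: dict[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    reference_gene: str = "HPRT1",
    n_replicates: int = 3,
) -> CqTable:
    """Build a Cq table whose true per-gene fold changes are known.

    The reference gene's Cq is held equal across samples; each target
    gene's control dCq is drawn once, and the treated dCq is the control
    dCq minus log2(fold), so ddCq inversion recovers the fold exactly in
    the noiseless case.  Replicate noise of ``noise_sd`` cycles is added
    to every Cq measurement.
    """
    if any(f <= 0 for f in true_folds.values()):
        raise ValueError("true fold changes must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20]))
    ref_cq = 20.0
    records = []

    def reps(mean_cq: float) -> tuple:
        noise = rng.normal(0.0, noise_sd, size=n_replicates) if noise_sd > 0 else np.zeros(n_replicates)
        return tuple(float(mean_cq + e) for e in noise)

    records.append((reference_gene, "control", reps(ref_cq)))
    records.append((reference_gene, "treated", reps(ref_cq)))
    for gene, fold in true_folds.items():
        d_control = float(rng.uniform(2.0, 8.0))
        d_treated = d_control - math.log2(fold)
        records.append((gene, "control", reps(ref_cq + d_control)))
        records.append((gene, "treated", reps(ref_cq + d_treated)))
    return CqTable(records=tuple(records), reference_gene=reference_gene)
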