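"""Plate-based assay calculations: MTT viability and GI levels, fluorescence
ratios, and delta-delta-Cq fold change.

MTT viability uses the dual-wavelength formula

    viability % = 100 * (T - Tc) / (C - Cc)

with T/C the 570 nm absorbances of treated/control wells and Tc/Cc the
matching 630 nm background readings.  GI50/GI25/GI10 are the compound
concentrations causing 50/25/10 % growth inhibition (viability 50/75/90 %),
found by linear interpolation in log10(concentration) on the measured
dose-response curve.  Relative qPCR expression uses fold = 2^(-ddCq), with
dCq = Cq(target) - Cq(reference gene) per sample and ddCq the treated-minus-
control difference of dCq.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class WellReading:
    """One microplate well: 570 nm signal, 630 nm background, role."""

    a570: float
    a630: float
    role: str  # 'treated' or 'control'
    concentration: float | None = None  # uM; None for control wells

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a570) and math.isfinite(self.a630)):
            raise ValueError("absorbances must be finite")
        if self.role not in ("treated", "control"):
            raise ValueError(f"unknown well role {self.role!r}")
        if self.role == "treated" and not (self.concentration and self.concentration > 0):
            raise ValueError("treated wells need a positive concentration")


@dataclass(frozen=True)
class DoseResponseCurve:
    """Ordered (concentration uM, viability %) pairs, concentrations increasing."""

    points: tuple  # tuple of (concentration, viability_pct)

    def __post_init__(self) -> None:
        pts = tuple((float(c), float(v)) for c, v in self.points)
        concs = [c for c, _ in pts]
        if any(c <= 0 for c in concs):
            raise ValueError("concentrations must be positive")
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError("concentrations must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points])

    @property
    def viability(self) -> np.ndarray:
        return np.array([v for _, v in self.points])


@dataclass(frozen=True)
class GIEstimate:
    """A growth-inhibition level: the concentration, or why it is undefined."""

    level: float  # % growth inhibition (50, 25, 10)
    concentration: float | None
    status: str = "ok"  # ok | below_range | above_range | non_monotone_ambiguous


@dataclass(frozen=True)
class FluorescencePair:
    """Mean green/orange intensities of one condition for a dual-color stain."""

    mean_green: float
    mean_orange: float
    stain: str  # AO_PI | JC1 | NAO

    def __post_init__(self) -> None:
        if self.mean_green < 0 or self.mean_orange < 0:
            raise ValueError("fluorescence intensities must be >= 0")
        if self.stain not in ("AO_PI", "JC1", "NAO"):
            raise ValueError(f"unknown stain {self.stain!r}")


@dataclass(frozen=True)
class CqTable:
    """Replicate Cq values per (gene, sample), with a designated reference gene."""

    records: tuple  # tuple of (gene, sample, cq_replicates tuple)
    reference_gene: str = "HPRT1"

    def __post_init__(self) -> None:
        recs = []
        for gene, sample, cqs in self.records:
            cqs = tuple(float(c) for c in cqs)
            if not cqs:
                raise ValueError(f"({gene}, {sample}) has no Cq replicates")
            if any(not (0 < c < 50) for c in cqs):
                raise ValueError(f"({gene}, {sample}) has Cq values outside (0, 50)")
            if sample not in ("treated", "control"):
                raise ValueError(f"unknown sample label {sample!r}")
            recs.append((gene, sample, cqs))
        object.__setattr__(self, "records", tuple(recs))

    def mean_cq(self, gene: str, sample: str) -> float:
        for g, s, cqs in self.records:
            if g == gene and s == sample:
                return float(np.mean(cqs))
        raise ValueError(f"missing Cq cell for gene {gene!r}, sample {sample!r}")


def viability_percent(T: float, Tc: float, C: float, Cc: float) -> float:
    """MTT viability %: 100*(T-Tc)/(C-Cc). Growth inhibition % is 100 minus this."""
    denom = C - Cc
    if denom <= 0:
        raise ValueError("control signal not above background (C - Cc <= 0)")
    # ratio first: keeps the T=C/Tc=Cc and (T-Tc)=k*(C-Cc) cases exact
    return 100.0 * ((T - Tc) / denom)


def plate_to_curve(readings: list[WellReading]) -> DoseResponseCurve:
    """Reduce raw well readings to a dose-response curve.

    Control wells are pooled (mean 570 and 630 nm); treated wells sharing a
    concentration are averaged, then converted to viability %.
    """
    controls = [w for w in readings if w.role == "control"]
    treated = [w for w in readings if w.role == "treated"]
    if not controls or not treated:
        raise ValueError("plate needs both control and treated wells")
    C = float(np.mean([w.a570 for w in controls]))
    Cc = float(np.mean([w.a630 for w in controls]))
    by_conc: dict[float, list[WellReading]] = {}
    for w in treated:
        by_conc.setdefault(w.concentration, []).append(w)
    pts = []
    for conc in sorted(by_conc):
        T = float(np.mean([w.a570 for w in by_conc[conc]]))
        Tc = float(np.mean([w.a630 for w in by_conc[conc]]))
        pts.append((conc, viability_percent(T, Tc, C, Cc)))
    return DoseResponseCurve(points=tuple(pts))


def gi_level(curve: DoseResponseCurve, level: float) -> GIEstimate:
    """Concentration causing ``level`` % growth inhibition, by log-linear
    interpolation of the dose-response curve.

    The target viability is v* = 100 - level.  Walking the curve along
    increasing concentration, the first adjacent pair that brackets v* on a
    locally decreasing segment is interpolated linearly in
    log10(concentration) vs viability.  Status values cover a v* that the
    curve never reaches (``above_range`` when every viability stays above
    it, ``below_range`` when the curve starts already below it) and curves
    crossing v* only while locally increasing (``non_monotone_ambiguous``).
    """
    if len(curve.points) < 2:
        raise ValueError("dose-response curve needs at least 2 points")
    v_star = 100.0 - level
    conc, viab = curve.concentrations, curve.viability
    # exact node hits take precedence over interpolation
    hits = np.flatnonzero(viab == v_star)
    if hits.size:
        return GIEstimate(level=level, concentration=float(conc[hits[0]]), status="ok")
    crossed_increasing = False
    for i in range(len(conc) - 1):
        v0, v1 = viab[i], viab[i + 1]
        if (v0 - v_star) * (v1 - v_star) < 0:
            if v0 > v1:  # decreasing: the physiologically meaningful crossing
                f = (v0 - v_star) / (v0 - v1)
                logc = math.log10(conc[i]) + f * (math.log10(conc[i + 1]) - math.log10(conc[i]))
                return GIEstimate(level=level, concentration=10.0 ** logc, status="ok")
            crossed_increasing = True
    if crossed_increasing:
        return GIEstimate(level=level, concentration=None, status="non_monotone_ambiguous")
    if viab.min() > v_star:
        return GIEstimate(level=level, concentration=None, status="above_range")
    return GIEstimate(level=level, concentration=None, status="below_range")


def fluorescence_ratio(pair: FluorescencePair) -> float:
    """Stain-appropriate readout of a green/orange intensity pair.

    AO_PI -> green/orange (viability proxy); JC1 -> orange/green (membrane
    potential proxy); NAO -> mean green passed through (mitochondrial mass
    proxy).  A zero denominator raises with status ``undefined_ratio``.
    """
    if pair.stain == "NAO":
        return pair.mean_green
    if pair.stain == "AO_PI":
        num, den = pair.mean_green, pair.mean_orange
    else:  # JC1
        num, den = pair.mean_orange, pair.mean_green
    if den == 0:
        raise ZeroDivisionError(f"undefined_ratio: zero denominator for stain {pair.stain}")
    return num / den


def ddcq_fold_change(table: CqTable, target_gene: str) -> float:
    """Relative expression fold change of ``target_gene`` by the ddCq method.

    Replicate Cq values are averaged arithmetically; dCq = Cq(target) -
    Cq(reference) per sample; ddCq = dCq(treated) - dCq(control); the
    returned fold change is 2^(-ddCq), assuming 100 % amplification
    efficiency.
    """
    ref = table.reference_gene
    d_treated = table.mean_cq(target_gene, "treated") - table.mean_cq(ref, "treated")
    d_control = table.mean_cq(target_gene, "control") - table.mean_cq(ref, "control")
    return 2.0 ** (-(d_treated - d_control))
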