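"""Wound-closure kinetics: percentage of the wound still open relative to T0.

Every timepoint's wound area is expressed as a percentage of the initial
wound area at T0, the frame taken immediately after scratching.  Values
above 100% (wound expansion, usually detachment or an artifact) are kept
uncapped and flagged rather than clipped, so the supervisor sees them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segment import WoundMask


@dataclass(frozen=True)
class ScratchSeries:
    """Ordered (time in hours, wound mask) observations of one well."""

    well_id: str
    timepoints: tuple  # tuple of (time_h: float, mask: WoundMask)

    def __post_init__(self) -> None:
        tps = tuple(self.timepoints)
        if not tps:
            raise ValueError("series needs at least one timepoint")
        times = [t for t, _ in tps]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("timepoint times must be strictly increasing")
        shapes = {m.shape for _, m in tps}
        if len(shapes) > 1:
            raise ValueError(f"all masks must share one frame size, got {shapes}")
        object.__setattr__(self, "timepoints", tps)

    @property
    def t0_index(self) -> int:
        return 0


@dataclass(frozen=True)
class ClosureResult:
    """Per-timepoint open/closed percentages relative to the T0 wound."""

    well_id: str
    times_h: tuple
    open_pct: tuple
    flags: tuple = ()

    @property
    def closure_pct(self) -> tuple:
        return tuple(100.0 - p for p in self.open_pct)


def open_wound_percent(series: ScratchSeries) -> ClosureResult:
    """Percent of the T0 wound area still open at each timepoint.

    open_pct(t) = 100 * area_px(t) / area_px(T0); exactly 100 at T0.
    Raises if no wound was detected at T0 (a manual override of the T0
    mask is the usual remedy).
    """
    t0_area = series.timepoints[series.t0_index][1].area_px
    if t0_area == 0:
        raise ValueError(
            f"no initial wound detected at T0 for well {series.well_id!r}; "
            "consider a manual override"
        )
    times, pcts, flags = [], [], []
    for t, mask in series.timepoints:
        pct = 100.0 * mask.area_px / t0_area
        times.append(t)
        pcts.append(pct)
        flags.append("EXPANDED" if pct > 100.0 else "")
    return ClosureResult(
        well_id=series.well_id,
        times_h=tuple(times),
        open_pct=tuple(pcts),
        flags=tuple(flags),
    )


def compare_conditions(grouped: dict[str, list[ClosureResult]]) -> pd.DataFrame:
    """Summarize open_pct per condition and timepoint: mean, sd, n.

    ``grouped`` maps a condition label to its replicate closure results.
    The sample standard deviation is reported as 0 when n = 1.
    """
    rows = []
    for condition, results in grouped.items():
        if not results:
            raise ValueError(f"condition {condition!r} has no results")
        for res in results:
            for t, p in zip(res.times_h, res.open_pct):
                rows.append({"condition": condition, "time_h": t, "open_pct": p})
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["condition", "time_h"], sort=True)["open_pct"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    return out
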