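"""Wound-closure timecourse analytics.

Closure at a visit is the percent reduction of wound area relative to the
first visit::

    closure(%) = 100 · (area_day0 − area_t) / area_day0

Negative closure (the wound grew, typical of untreated diabetic wounds in the
first days) is preserved, not clipped. The per-day closure rate has no single
standard definition; two conventions are provided:

* ``"final"`` (default) — closure at the last visit divided by elapsed days;
* ``"ols"`` — least-squares slope of closure versus day.

Both agree exactly when closure is linear in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WoundSeries",
    "ClosureRecord",
    "closure_percent",
    "closure_series",
    "closure_rate_per_day",
    "group_closure_table",
    "area_from_mask",
]


@dataclass
class WoundSeries:
    """One animal's wound-area measurements by day (areas in mm²)."""

    animal_id: str
    group: str
    days: list[int]
    areas: list[float]
    clipped: bool = False

    def __post_init__(self) -> None:
        if len(self.days) != len(self.areas):
            raise ValueError("days and areas must have equal length")
        if not self.days or self.days[0] != 0:
            raise ValueError("series must start at day 0")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(a < 0 for a in self.areas):
            raise ValueError("areas must be non-negative")


@dataclass(frozen=True)
class ClosureRecord:
    animal_id: str
    group: str
    day: int
    area: float
    closure_pct: float


def area_from_mask(mask: np.ndarray, mm_per_pixel: float, method: str = "grid",
                   grid=None, rng: np.random.Generator | None = None) -> float:
    """Wound area in mm² from a binary photograph mask.

    ``method="grid"`` (default) overlays a point grid and applies
    ``A = ΣP · a/p`` — the same estimator used on the printed photographs;
    ``method="pixel"`` counts mask pixels directly. The mask is row-major with
    the top-left origin; the mm-per-pixel scale comes from the ruler
    calibration and is supplied by the caller.
    """
    from .estimators import PointGrid, estimate_area
    mask = np.asarray(mask, dtype=bool)
    if not mm_per_pixel > 0:
        raise ValueError("mm_per_pixel must be positive")
    if method == "pixel":
        return float(mask.sum()) * mm_per_pixel ** 2
    if method == "grid":
        g = grid if grid is not None else PointGrid(spacing=1.0)
        return estimate_area(g.count_points_in_mask(mask, mm_per_pixel, rng), g)
    raise ValueError(f"unknown method {method!r}")


def closure_percent(area_day0: float, area_t: float) -> float:
    """Percent wound closure relative to the first visit; negative if grown."""
    if not area_day0 > 0:
        raise ValueError(f"initial area must be positive, got {area_day0}")
    if area_t < 0:
        raise ValueError(f"area must be non-negative, got {area_t}")
    return 100.0 * (area_day0 - area_t) / area_day0


def closure_series(series: WoundSeries) -> list[ClosureRecord]:
    """Per-visit closure records for one animal."""
    a0 = series.areas[0]
    return [
        ClosureRecord(series.animal_id, series.group, d, a, closure_percent(a0, a))
        for d, a in zip(series.days, series.areas)
    ]


def closure_rate_per_day(series: WoundSeries, convention: str = "final") -> float:
    """Average closure rate in %/day.

    ``"final"``: closure at the last visit over elapsed days. ``"ols"``:
    slope of the closure-vs-day regression through all visits.
    """
    if len(series.days) < 2:
        raise ValueError("per-day rate needs at least two visits")
    records = closure_series(series)
    if convention == "final":
        return records[-1].closure_pct / (series.days[-1] - series.days[0])
    if convention == "ols":
        days = np.asarray(series.days, dtype=float)
        cl = np.asarray([r.closure_pct for r in records])
        slope = np.polyfit(days, cl, 1)[0]
        return float(slope)
    raise ValueError(f"unknown rate convention {convention!r}")


def _mean_sd(values: np.ndarray) -> tuple[float, float, bool]:
    """Sample mean and n−1 SD; SD reported as 0 (flagged) when n == 1."""
    if len(values) == 1:
        return float(values[0]), 0.0, True
    return float(np.mean(values)), float(np.std(values, ddof=1)), False


def group_closure_table(series: list[WoundSeries],
                        convention: str = "final") -> dict[str, pd.DataFrame]:
    """Group-level summaries of a wound cohort.

    Returns three tidy tables: ``initial`` (mean ± SD of day-0 areas),
    ``closure`` (mean ± SD closure per group × day) and ``rate`` (mean ± SD
    per-day rate). Groups with a single animal carry ``degenerate_n=True``
    and SD 0.
    """
    if not series:
        raise ValueError("no series supplied")
    groups: dict[str, list[WoundSeries]] = {}
    for s in series:
        groups.setdefault(s.group, []).append(s)

    initial_rows, closure_rows, rate_rows = [], [], []
    for g, members in groups.items():
        a0 = np.array([m.areas[0] for m in members])
        mean, sd, flag = _mean_sd(a0)
        initial_rows.append({"group": g, "n": len(members), "mean_mm2": mean,
                             "sd_mm2": sd, "degenerate_n": flag})
        rates = np.array([closure_rate_per_day(m, convention) for m in members])
        mean, sd, flag = _mean_sd(rates)
        rate_rows.append({"group": g, "n": len(members), "mean_pct_per_day": mean,
                          "sd_pct_per_day": sd, "degenerate_n": flag})
        by_day: dict[int, list[float]] = {}
        for m in members:
            for rec in closure_series(m):
                by_day.setdefault(rec.day, []).append(rec.closure_pct)
        for day in sorted(by_day):
            mean, sd, flag = _mean_sd(np.asarray(by_day[day]))
            closure_rows.append({"group": g, "day": day, "n": len(by_day[day]),
                                 "mean_closure_pct": mean, "sd_closure_pct": sd,
                                 "degenerate_n": flag})
    return {
        "initial": pd.DataFrame(initial_rows),
        "closure": pd.DataFrame(closure_rows),
        "rate": pd.DataFrame(rate_rows),
    }
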