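"""Summary pharmacokinetic quantities of a concentration trajectory.

Covers the steady-state (plateau) concentration, weekly AUC, and
therapeutic-window statistics: how long the serum level stays inside the
contraceptively effective band, and the maximal intervals spent below it
(pregnancy-risk windows) or above it (overexposure windows).

The plateau concentration is defined as the time average over the third
wear week (hours 336–504), when the weekly pattern is fully established;
the weekly AUC is reported per week and as the mean over the three-week
cycle.  Both window conventions are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .model import ConcentrationSeries

__all__ = ["PkSummary", "css", "auc", "weekly_aucs", "range_crossings",
           "RangeReport", "summarize"]

_WEEK = 168.0
DEFAULT_PLATEAU_WINDOW = (336.0, 504.0)


@dataclass(frozen=True)
class RangeReport:
    """Therapeutic-band occupancy of a trajectory over an analysed span."""

    low: float
    high: float
    span: tuple[float, float]
    risk_windows: list[tuple[float, float]]
    over_windows: list[tuple[float, float]]
    time_in_range: float


@dataclass(frozen=True)
class PkSummary:
    """Headline PK quantities for one hormone."""

    name: str
    unit: str
    c_ss: float
    auc_weekly: list[float]
    auc_0_168: float  # mean weekly AUC over the cycle
    t_half: float
    time_in_range: float
    risk_windows: list[tuple[float, float]]

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def _window_values(series: ConcentrationSeries, start: float, end: float):
    """Grid times/values restricted to [start, end], with interpolated edges."""
    if end <= start:
        raise ValueError("window must have positive length")
    if start < series.times[0] or end > series.times[-1]:
        raise ValueError("window outside series range")
    inner = (series.times > start) & (series.times < end)
    t = np.concatenate(([start], series.times[inner], [end]))
    v = np.concatenate(([series.at(start)], series.values[inner], [series.at(end)]))
    return t, v


def auc(series: ConcentrationSeries, start: float, end: float) -> float:
    """Trapezoidal area under the curve over [start, end] (unit · h)."""
    t, v = _window_values(series, start, end)
    return float(np.trapezoid(v, t))


def css(series: ConcentrationSeries,
        window: tuple[float, float] = DEFAULT_PLATEAU_WINDOW) -> float:
    """Time-averaged (trapezoidal mean) concentration over the window."""
    start, end = window
    return auc(series, start, end) / (end - start)


def weekly_aucs(series: ConcentrationSeries, n_weeks: int = 3,
                week_h: float = _WEEK) -> list[float]:
    """AUC of each consecutive 168 h wear week from t = 0."""
    return [auc(series, i * week_h, (i + 1) * week_h) for i in range(n_weeks)]


def _merge(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for a, b in intervals:
        if merged and abs(a - merged[-1][1]) < 1e-12:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged if b > a]


def range_crossings(series: ConcentrationSeries, low: float, high: float,
                    span: tuple[float, float] | None = None) -> RangeReport:
    """Locate sub-therapeutic and supra-therapeutic intervals.

    Crossing times are found by linear interpolation between adjacent
    grid points, consistent with the first-order accuracy of the
    integration scheme.  Returns maximal intervals with C < low (risk
    windows), C > high (overexposure windows), and the total time with
    low <= C <= high.
    """
    if not low < high:
        raise ValueError("low must be below high")
    if span is None:
        span = (float(series.times[0]), float(series.times[-1]))
    t, v = _window_values(series, span[0], span[1])

    # refine the polyline so no sub-interval straddles a threshold
    refined_t = [t[0]]
    refined_v = [v[0]]
    for i in range(len(t) - 1):
        t0, t1, v0, v1 = t[i], t[i + 1], v[i], v[i + 1]
        cuts = []
        for thr in (low, high):
            if (v0 - thr) * (v1 - thr) < 0:
                cuts.append(t0 + (thr - v0) / (v1 - v0) * (t1 - t0))
        for tc in sorted(cuts):
            refined_t.append(tc)
            refined_v.append(v0 + (v1 - v0) * (tc - t0) / (t1 - t0))
        refined_t.append(t1)
        refined_v.append(v1)

    below, above = [], []
    in_range = 0.0
    for i in range(len(refined_t) - 1):
        a, b = refined_t[i], refined_t[i + 1]
        if b <= a:
            continue
        mid = 0.5 * (refined_v[i] + refined_v[i + 1])
        if mid < low:
            below.append((a, b))
        elif mid > high:
            above.append((a, b))
        else:
            in_range += b - a
    return RangeReport(low, high, span, _merge(below), _merge(above), in_range)


def summarize(series: ConcentrationSeries, low: float, high: float,
              k_elim: float,
              plateau_window: tuple[float, float] = DEFAULT_PLATEAU_WINDOW,
              n_weeks: int = 3) -> PkSummary:
    """Assemble the full :class:`PkSummary` for a simulated trajectory."""
    weekly = weekly_aucs(series, n_weeks=n_weeks)
    report = range_crossings(series, low, high)
    return PkSummary(
        name=series.name,
        unit=series.unit,
        c_ss=css(series, plateau_window),
        auc_weekly=weekly,
        auc_0_168=float(np.mean(weekly)),
        t_half=float(np.log(2.0) / k_elim),
        time_in_range=report.time_in_range,
        risk_windows=report.risk_windows,
    )
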