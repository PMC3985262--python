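"""One-compartment serum kinetics of patch-delivered hormones.

The serum pool gains drug by absorption from the patch and loses it by
first-order elimination:

    dC/dt = f(t) * (k_o / V_d) * exp(-a * s(t)) - k_elim * C

where ``f(t)`` is the attached-area fraction, ``s(t)`` the age of the
currently worn patch (the release rate resets whenever a patch is
replaced), and ``a`` the absorption attenuation constant.

Two solvers are provided.  :func:`simulate_difference` is the explicit
forward-difference scheme the model is formulated in; it is first-order
accurate in the step size.  :func:`simulate_analytic` evaluates the exact
piecewise solution of the linear ODE between regimen events and serves
as the accuracy oracle for the difference scheme.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .params import DrugParams
from .regimen import Regimen, Segment

__all__ = [
    "SimulationGrid",
    "ConcentrationSeries",
    "absorption_rate",
    "elimination_rate",
    "simulate_difference",
    "simulate_analytic",
    "analytic_concentrations",
    "InstabilityError",
]

logger = logging.getLogger(__name__)

#: relative threshold below which |k_elim - decay_const| switches the
#: closed form to its confluent (k == a) limit
_CONFLUENT_RTOL = 1e-10


class InstabilityError(RuntimeError):
    """Forward-difference step produced a negative concentration."""


@dataclass(frozen=True)
class SimulationGrid:
    """Uniform integration grid: step ``dt`` and end time ``horizon`` (hours)."""

    dt: float = 0.1
    horizon: float = 600.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt > 1.0:
            raise ValueError("dt must not exceed 1 h")
        n = self.horizon / self.dt
        if self.horizon < 0 or not math.isclose(n, round(n), abs_tol=1e-9):
            raise ValueError("horizon must be a non-negative multiple of dt")

    @property
    def n_steps(self) -> int:
        return round(self.horizon / self.dt)

    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.horizon, self.n_steps + 1)


@dataclass(frozen=True)
class ConcentrationSeries:
    """A serum concentration trajectory for one hormone."""

    times: np.ndarray
    values: np.ndarray
    unit: str
    name: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("concentrations must be non-negative")

    def __len__(self) -> int:
        return self.times.size

    def slice(self, start: float, end: float) -> "ConcentrationSeries":
        """Sub-series with times in [start, end]."""
        mask = (self.times >= start) & (self.times <= end)
        return ConcentrationSeries(self.times[mask], self.values[mask],
                                   self.unit, self.name)

    def at(self, t) -> np.ndarray:
        """Linear interpolation at arbitrary times within the series range."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            raise ValueError("interpolation time outside series range")
        return np.interp(t, self.times, self.values)

    def to_csv(self, path) -> None:
        """Write as 2-column CSV (`time_h,concentration`) with a unit comment."""
        with open(path, "w") as fh:
            fh.write(f"# unit: {self.unit}\n")
            if self.name:
                fh.write(f"# hormone: {self.name}\n")
            fh.write("time_h,concentration\n")
            for t, v in zip(self.times, self.values):
                fh.write(f"{t:.6g},{v:.6g}\n")

    @classmethod
    def from_csv(cls, path) -> "ConcentrationSeries":
        unit, name = "", ""
        times, values = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if body.startswith("unit:"):
                        unit = body.split(":", 1)[1].strip()
                    elif body.startswith("hormone:"):
                        name = body.split(":", 1)[1].strip()
                    continue
                if line.startswith("time_h"):
                    continue
                t_str, v_str = line.split(",")
                times.append(float(t_str))
                values.append(float(v_str))
        return cls(np.array(times), np.array(values), unit, name)


def absorption_rate(params: DrugParams, patch_age: float,
                    area_fraction: float) -> float:
    """Absorption rate into serum, concentration-unit per hour.

    ``area_fraction * (k_o / V_d) * exp(-a * patch_age)``; zero when no
    patch is attached.
    """
    if patch_age < 0:
        raise ValueError("patch_age must be non-negative")
    if not 0.0 <= area_fraction <= 1.0:
        raise ValueError("area_fraction must lie in [0, 1]")
    if area_fraction == 0.0:
        return 0.0
    return area_fraction * params.input_rate * math.exp(-params.decay_const * patch_age)


def elimination_rate(params: DrugParams, concentration: float) -> float:
    """Magnitude of the first-order elimination term, ``k_elim * C``."""
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    return params.k_elim * concentration


def _segment_index(segments: list[Segment], times: np.ndarray) -> np.ndarray:
    """Index of the segment containing each time (right-open intervals)."""
    starts = np.array([s.t_start for s in segments])
    idx = np.searchsorted(starts, times, side="right") - 1
    return np.clip(idx, 0, len(segments) - 1)


def simulate_difference(params: DrugParams, regimen: Regimen,
                        grid: SimulationGrid | None = None,
                        c0: float = 0.0) -> ConcentrationSeries:
    """Forward-difference trajectory C(t+dt) = C(t) + (R_abs - k_elim C) dt.

    The absorption term uses the wear state (area fraction, patch age) at
    the left endpoint of each step.  A step driving the concentration
    negative raises :class:`InstabilityError` rather than clipping
    silently; tiny negative round-off (within machine epsilon of zero)
    is clipped with a warning.
    """
    if c0 < 0:
        raise ValueError("c0 must be non-negative")
    if grid is None:
        grid = SimulationGrid(horizon=regimen.horizon)
    if grid.horizon > regimen.horizon:
        raise ValueError("grid horizon exceeds regimen horizon")

    times = grid.times()
    segments = regimen.segments()
    seg_idx = _segment_index(segments, times)
    areas = np.array([s.area_fraction for s in segments])[seg_idx]
    origins = np.array(
        [s.t_start if s.age_origin is None else s.age_origin for s in segments]
    )[seg_idx]
    no_patch = np.array([s.age_origin is None for s in segments])[seg_idx]
    ages = np.where(no_patch, 0.0, times - origins)
    rates = np.where(
        no_patch, 0.0,
        areas * params.input_rate * np.exp(-params.decay_const * ages),
    )

    k, dt = params.k_elim, grid.dt
    values = np.empty_like(times)
    values[0] = c0
    clipped = False
    c = c0
    for i in range(len(times) - 1):
        c = c + (rates[i] - k * c) * dt
        if c < 0.0:
            if c < -1e-12 * max(1.0, abs(values[i])):
                raise InstabilityError(
                    f"concentration went negative ({c:.3e}) at "
                    f"t = {times[i + 1]:.3f} h; reduce dt"
                )
            c = 0.0
            clipped = True
        values[i + 1] = c
    if clipped:
        logger.warning("negative round-off clipped to zero during simulation")
    return ConcentrationSeries(times, values, params.conc_unit, params.name)


def _segment_step(params: DrugParams, c0: float, seg: Segment,
                  tau) -> np.ndarray | float:
    """Exact solution within one constant-state segment, at offsets ``tau``."""
    k = params.k_elim
    decay = np.exp(-k * np.asarray(tau, dtype=float))
    if seg.age_origin is None or seg.area_fraction == 0.0:
        return c0 * decay
    a = params.decay_const
    s0 = seg.t_start - seg.age_origin
    amp = seg.area_fraction * params.input_rate * math.exp(-a * s0)
    tau = np.asarray(tau, dtype=float)
    if abs(k - a) <= _CONFLUENT_RTOL * max(k, a):
        forced = amp * tau * np.exp(-k * tau)
    else:
        forced = amp * (np.exp(-a * tau) - np.exp(-k * tau)) / (k - a)
    return c0 * decay + forced


def analytic_concentrations(params: DrugParams, regimen: Regimen,
                            times, c0: float = 0.0) -> np.ndarray:
    """Exact piecewise solution evaluated at arbitrary (sorted) times."""
    if c0 < 0:
        raise ValueError("c0 must be non-negative")
    times = np.asarray(times, dtype=float)
    if np.any(times < 0) or np.any(times > regimen.horizon):
        raise ValueError("evaluation times outside [0, horizon]")
    segments = regimen.segments()
    out = np.empty_like(times)
    c_start = c0
    for i, seg in enumerate(segments):
        if i == len(segments) - 1:
            mask = (times >= seg.t_start) & (times <= seg.t_end)
        else:
            mask = (times >= seg.t_start) & (times < seg.t_end)
        if mask.any():
            out[mask] = _segment_step(params, c_start, seg, times[mask] - seg.t_start)
        c_start = float(_segment_step(params, c_start, seg, seg.t_end - seg.t_start))
    # exact solution is non-negative; guard round-off only
    return np.maximum(out, 0.0)


def simulate_analytic(params: DrugParams, regimen: Regimen,
                      grid: SimulationGrid | None = None,
                      c0: float = 0.0) -> ConcentrationSeries:
    """Closed-form trajectory on the same grid as :func:`simulate_difference`."""
    if grid is None:
        grid = SimulationGrid(horizon=regimen.horizon)
    if grid.horizon > regimen.horizon:
        raise ValueError("grid horizon exceeds regimen horizon")
    times = grid.times()
    values = analytic_concentrations(params, regimen, times, c0)
    return ConcentrationSeries(times, values, params.conc_unit, params.name)
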