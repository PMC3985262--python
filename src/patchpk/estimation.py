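"""Parameter recovery from serum concentration data.

Two quantities are estimable from clinical sampling:

* the elimination rate constant ``k_elim`` — ordinary least squares of
  ln C on t over the post-removal decay phase (the terminal log-linear
  slope method);
* the absorption attenuation constant (``alpha``/``beta``) — bounded
  one-dimensional least squares of the observed trajectory against the
  closed-form model solution, all other constants held fixed (it is the
  model's only adjustable parameter).

Both are exposed as scikit-learn-style estimators (``fit(X, y)`` with
fitted attributes and ``predict``) plus thin functional wrappers that
return a :class:`FitResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .model import ConcentrationSeries, analytic_concentrations
from .params import DrugParams
from .regimen import Regimen

__all__ = [
    "FitResult",
    "EliminationRateEstimator",
    "AbsorptionDecayEstimator",
    "fit_kelim",
    "fit_decay_const",
    "derive_vd",
    "half_life",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class FitResult:
    """A single estimated parameter with residual diagnostics."""

    parameter_name: str
    estimate: float
    unit: str
    stderr: float
    residual_ss: float
    n_points: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.stderr < 0 or not np.isfinite(self.estimate):
            raise ValueError("invalid fit result")
        if self.n_points < 2:
            raise ValueError("a regression needs at least 2 observations")


def _as_times(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X.ravel()
    if X.ndim != 1:
        raise ValueError("X must be a 1-D array of times or an (n, 1) column")
    return X


class EliminationRateEstimator(BaseEstimator, RegressorMixin):
    """Terminal log-linear slope estimator of the elimination constant.

    Fits ``ln C = intercept - k_elim * t`` by unweighted ordinary least
    squares.  Input concentrations must be strictly positive and should
    come from the decay phase after final patch removal, where the model
    predicts pure first-order elimination.

    Attributes (after ``fit``)
    --------------------------
    k_elim_ : float
        Estimated elimination constant, 1/h.
    stderr_ : float
        Standard error of the slope (same unit).
    log_intercept_ : float
        Fitted ln-concentration at t = 0.
    residual_ss_ : float
        Sum of squared residuals on the log scale.
    half_life_ : float
        ln2 / k_elim_, hours.
    n_points_ : int
    """

    def fit(self, X, y):
        t = _as_times(X)
        c = np.asarray(y, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and concentrations must have equal length")
        if t.size < 2:
            raise ValueError("need at least 2 observations to fit a slope")
        if np.any(c <= 0):
            raise ValueError("log-linear fit requires strictly positive concentrations")
        res = stats.linregress(t, np.log(c))
        self.k_elim_ = -float(res.slope)
        self.stderr_ = float(res.stderr) if np.isfinite(res.stderr) else 0.0
        self.log_intercept_ = float(res.intercept)
        resid = np.log(c) - (res.intercept + res.slope * t)
        self.residual_ss_ = float(resid @ resid)
        self.half_life_ = LN2 / self.k_elim_ if self.k_elim_ > 0 else math.inf
        self.n_points_ = int(t.size)
        return self

    def predict(self, X):
        t = _as_times(X)
        return np.exp(self.log_intercept_ - self.k_elim_ * t)

    def to_result(self) -> FitResult:
        return FitResult("k_elim", self.k_elim_, "1/h", self.stderr_,
                         self.residual_ss_, self.n_points_)


class AbsorptionDecayEstimator(BaseEstimator, RegressorMixin):
    """Least-squares fit of the absorption attenuation constant.

    Minimises the sum of squared deviations between observed
    concentrations and the closed-form model trajectory over
    ``decay_const`` in ``[0, bound_factor * params.decay_const]``, by
    deterministic bounded scalar minimisation.  All other kinetic
    constants are fixed at their values in ``params``.

    Parameters
    ----------
    params : DrugParams
        Fixed kinetic constants; ``params.decay_const`` seeds the search
        interval but is otherwise unused.
    regimen : Regimen
        Patch-wear timeline that generated the observations.
    c0 : float
        Initial serum concentration (default 0, drug-naive start).
    bound_factor : float
        Upper search bound as a multiple of ``params.decay_const``.

    Attributes (after ``fit``)
    --------------------------
    decay_const_ : float
        Estimated attenuation constant, 1/h.
    residual_ss_ : float
    converged_ : bool
        False when the optimum sits at the search boundary.
    n_points_ : int
    """

    def __init__(self, params: DrugParams = None, regimen: Regimen = None,
                 c0: float = 0.0, bound_factor: float = 10.0):
        self.params = params
        self.regimen = regimen
        self.c0 = c0
        self.bound_factor = bound_factor

    def fit(self, X, y):
        if self.params is None or self.regimen is None:
            raise ValueError("params and regimen must be set before fitting")
        t = _as_times(X)
        c = np.asarray(y, dtype=float)
        if t.shape != c.shape:
            raise ValueError("times and concentrations must have equal length")
        if t.size < 2:
            raise ValueError("need at least 2 observations")
        order = np.argsort(t, kind="stable")
        t_sorted, c_sorted = t[order], c[order]

        upper = self.bound_factor * self.params.decay_const
        if upper <= 0:
            raise ValueError("search interval is empty: params.decay_const must be > 0")

        def sse(a: float) -> float:
            model = analytic_concentrations(
                self.params.with_decay_const(a), self.regimen, t_sorted, self.c0)
            r = c_sorted - model
            return float(r @ r)

        res = optimize.minimize_scalar(sse, bounds=(0.0, upper), method="bounded",
                                       options={"xatol": 1e-12})
        self.decay_const_ = float(res.x)
        self.residual_ss_ = float(res.fun)
        # boundary optimum means the interval did not bracket a minimum
        margin = 1e-3 * upper
        self.converged_ = bool(res.success) and margin < self.decay_const_ < upper - margin
        self.n_points_ = int(t.size)
        return self

    def predict(self, X):
        t = _as_times(X)
        order = np.argsort(t, kind="stable")
        out = np.empty_like(t)
        out[order] = analytic_concentrations(
            self.params.with_decay_const(self.decay_const_), self.regimen,
            t[order], self.c0)
        return out

    def to_result(self) -> FitResult:
        return FitResult("decay_const", self.decay_const_, "1/h", 0.0,
                         self.residual_ss_, self.n_points_,
                         converged=self.converged_)


def fit_kelim(decay_series: ConcentrationSeries) -> FitResult:
    """Estimate ``k_elim`` (1/h) from a post-removal decay series."""
    est = EliminationRateEstimator().fit(decay_series.times, decay_series.values)
    return est.to_result()


def fit_decay_const(observed: ConcentrationSeries, params: DrugParams,
                    regimen: Regimen, c0: float = 0.0,
                    bound_factor: float = 10.0) -> FitResult:
    """Estimate the absorption attenuation constant (1/h) from observations."""
    if len(observed) == 0:
        raise ValueError("no observations supplied")
    est = AbsorptionDecayEstimator(params, regimen, c0, bound_factor)
    est.fit(observed.times, observed.values)
    return est.to_result()


def derive_vd(clearance: float, k_elim: float) -> float:
    """Volume of distribution V_d = Cl / k_elim, in mL (Cl in L/h, k in 1/h)."""
    if clearance <= 0 or k_elim <= 0:
        raise ValueError("clearance and k_elim must be positive")
    return clearance * 1.0e3 / k_elim


def half_life(k_elim: float) -> float:
    """Elimination half-life ln2 / k_elim, hours."""
    if k_elim <= 0:
        raise ValueError("k_elim must be positive")
    return LN2 / k_elim
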