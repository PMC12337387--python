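"""Laying-rate curve models, BIC model selection, and stage segmentation.

Three classical lactation-style models are fitted to weekly mean laying
rates: Wood ``y = a t^b e^{-ct}``, compartmental
``y = a (1 - e^{-c(t-d)}) e^{-bt}``, and Yang-Ning
``y = a e^{-bt} / (1 + e^{-c(t-d)})``, where model time is
``t = week_of_age - 20`` so that the laying window (weeks 21-43 of age)
maps to t = 1..23. In the Yang-Ning model `a` is the maximum potential
laying rate, `b` the weekly decline rate, `c` the weekly increase rate,
and `d` the model-time of first egg.

The Yang-Ning curve has an interior maximum at
``t* = d + ln((c - b)/b) / c`` whenever 0 < b < c; that stationary point
(converted back to week of age) splits the cycle into an up-stage and a
sustained-stage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

WEEK_OFFSET = 20  # model time t = week of age - WEEK_OFFSET
WEEKS = np.arange(21, 44)  # laying weeks of age, inclusive
N_WEEKS = len(WEEKS)  # 23


class FitFailure(RuntimeError):
    """Nonlinear least squares failed from every grid start."""


class UnsupportedModelError(ValueError):
    pass


class OutOfRangeError(ValueError):
    pass


def wood(t, a, b, c):
    t = np.asarray(t, dtype=float)
    return a * np.power(t, b) * np.exp(-c * t)


def compartmental(t, a, b, c, d):
    t = np.asarray(t, dtype=float)
    return a * (1.0 - np.exp(-c * (t - d))) * np.exp(-b * t)


def yangning(t, a, b, c, d):
    t = np.asarray(t, dtype=float)
    return a * np.exp(-b * t) / (1.0 + np.exp(-c * (t - d)))


_MODELS = {
    "wood": (wood, ("a", "b", "c")),
    "compartmental": (compartmental, ("a", "b", "c", "d")),
    "yangning": (yangning, ("a", "b", "c", "d")),
}

# Multi-start grid; the optimizer is bounded least squares from each start.
_START_GRID = {
    "a": (0.5, 0.8, 1.0),
    "b": (0.005, 0.02, 0.05),
    "c": (0.5, 1.0, 2.0),
    "d": (1.0, 3.0, 5.0),
}
_LOWER = {"a": 0.0, "b": 0.0, "c": 0.0, "d": -5.0}
_UPPER = {"a": 2.0, "b": 1.0, "c": 10.0, "d": 20.0}


@dataclass
class CurveFit:
    model: str
    params: dict[str, float]
    rss: float
    bic: float
    fitted: np.ndarray
    at_bound: bool = False
    n_points: int = 0
    meta: dict = field(default_factory=dict)

    def predict(self, t):
        fn, names = _MODELS[self.model]
        return fn(t, *[self.params[k] for k in names])


@dataclass
class StageDefinition:
    """Contiguous week-of-age ranges; up and sustained partition all."""

    up: tuple[int, int]
    sustained: tuple[int, int]
    all: tuple[int, int] = (21, 43)

    def weeks(self, stage: str) -> np.ndarray:
        lo, hi = getattr(self, stage)
        return np.arange(lo, hi + 1)


def fit_curve(weekly_rates, model: str, weeks=None) -> CurveFit:
    """Fit one laying-rate model to (week-of-age, mean rate) points.

    Parameters
    ----------
    weekly_rates : array of mean laying rates in [0, 1], one per week.
    model : 'wood' | 'compartmental' | 'yangning'.
    weeks : matching weeks of age; defaults to 21..43.
    """
    if model not in _MODELS:
        raise UnsupportedModelError(model)
    y = np.asarray(weekly_rates, dtype=float)
    w = np.asarray(weeks if weeks is not None else WEEKS[: len(y)], dtype=float)
    if y.ndim != 1 or len(y) < 6:
        raise ValueError("need at least 6 weekly points")
    if np.nanmin(y) < 0 or np.nanmax(y) > 1:
        raise ValueError("rates must lie in [0, 1]")
    t = w - WEEK_OFFSET
    fn, names = _MODELS[model]
    lo = np.array([_LOWER[k] for k in names])
    hi = np.array([_UPPER[k] for k in names])

    def resid(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            pred = fn(t, *theta)
        return np.nan_to_num(pred, nan=1e3, posinf=1e3) - y

    best = None
    for start in itertools.product(*[_START_GRID[k] for k in names]):
        theta0 = np.clip(np.asarray(start, float), lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(resid, theta0, bounds=(lo, hi), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise FitFailure(f"{model}: no start converged on {len(y)} points")
    rss, theta = best
    n, k = len(y), len(names)
    bic = n * np.log(max(rss, 1e-300) / n) + k * np.log(n)
    at_bound = bool(np.any(np.abs(theta - lo) < 1e-6) or np.any(np.abs(theta - hi) < 1e-6))
    fitted = np.clip(fn(t, *theta), 0.0, 1.0)
    return CurveFit(model=model, params=dict(zip(names, theta)), rss=rss,
                    bic=float(bic), fitted=fitted, at_bound=at_bound, n_points=n)


def stationary_point(fit: CurveFit) -> float | None:
    """Week of age where the fitted Yang-Ning curve peaks (y'(t*) = 0).

    Closed form ``t* = d + ln((c - b)/b)/c`` for 0 < b < c; returns None
    when the curve is monotone (b <= 0 or b >= c).
    """
    if fit.model != "yangning":
        raise UnsupportedModelError("stationary point is defined for the yangning model")
    b, c, d = fit.params["b"], fit.params["c"], fit.params["d"]
    if b <= 0 or b >= c:
        return None
    t_star = d + np.log((c - b) / b) / c
    return float(t_star + WEEK_OFFSET)


def segment_stages(stationary_week: float) -> StageDefinition:
    """Split weeks 21-43 into up (21..floor(t*)) and sustained stages."""
    if not (21.0 < stationary_week < 43.0):
        raise OutOfRangeError(f"stationary week {stationary_week} outside (21, 43)")
    cut = int(np.floor(stationary_week))
    return StageDefinition(up=(21, cut), sustained=(cut + 1, 43), all=(21, 43))


def select_model(weekly_rates, weeks=None, models=("wood", "compartmental", "yangning")):
    """Fit every model and return {model: CurveFit}, best model first by BIC."""
    fits = {}
    for m in models:
        try:
            fits[m] = fit_curve(weekly_rates, m, weeks=weeks)
        except FitFailure:
            continue
    return dict(sorted(fits.items(), key=lambda kv: kv[1].bic))
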