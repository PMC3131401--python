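"""Carnosine <-> fiber-type calibration.

The biopsy calibration regresses carnosine (mM, response) on % type-II
fiber area (predictor), the direction in which the data were collected.
Estimating fiber-type composition from a measured carnosine value is
therefore an *inverse regression* (classical calibration) problem:
x_hat = (y - intercept)/slope, with a prediction interval propagated
from the residual SD and the slope's sampling uncertainty.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .types import CalibrationModel

__all__ = [
    "pearson_correlation",
    "fit_calibration",
    "predict_ft_area",
    "carnosine_axis_to_ft_axis",
    "save_calibration",
    "load_calibration",
]


def _validate_xy(x, y, min_n: int = 3) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    return x, y


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Product-moment correlation with two-sided p from the t transform.

    p is computed from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom, the same convention standard statistics packages print.
    """
    x, y = _validate_xy(x, y)
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def fit_calibration(ft_area_pct: Sequence[float], carnosine_mm: Sequence[float]) -> CalibrationModel:
    """Ordinary least squares of carnosine (y) on % type-II area (x)."""
    x, y = _validate_xy(ft_area_pct, carnosine_mm)
    n = x.size
    lr = stats.linregress(x, y)
    resid = y - (lr.intercept + lr.slope * x)
    residual_sd = math.sqrt(float(np.sum(resid**2)) / (n - 2)) if n > 2 else 0.0
    return CalibrationModel(
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        r=float(lr.rvalue),
        p_value=float(lr.pvalue),
        n=n,
        residual_sd=residual_sd,
        x_mean=float(x.mean()),
        y_mean=float(y.mean()),
        sxx=float(np.sum((x - x.mean()) ** 2)),
    )


def predict_ft_area(
    model: CalibrationModel,
    carnosine_mm: float,
    interval: float = 0.95,
) -> Tuple[float, Tuple[float, float], bool]:
    """Estimate % type-II area from a carnosine measurement.

    Returns ``(estimate, (low, high), clamped)``.  The interval inverts
    the exact prediction pivot of the calibration line (Fieller-type):
    it is the set of x for which

        (y0 - a - b x)^2 <= t^2 s^2 (1 + 1/n + (x - x_bar)^2/Sxx)

    with t the n-2 df quantile — a quadratic in x whose roots bound the
    interval.  When the calibration slope is not distinguishable from
    zero at the chosen level the set is unbounded and (-inf, inf) is
    returned, as classical calibration theory requires.  Estimates
    outside [0, 100] % are clamped and flagged.
    """
    if carnosine_mm <= 0:
        raise ValueError("carnosine must be > 0")
    if model.slope == 0:
        raise ValueError("calibration uninformative: slope is zero")
    if not 0 < interval < 1:
        raise ValueError("interval must be in (0, 1)")
    x_hat = (carnosine_mm - model.intercept) / model.slope
    t_crit = stats.t.ppf(0.5 + interval / 2.0, model.n - 2)
    t2s2 = (t_crit * model.residual_sd) ** 2
    g = t2s2 / model.sxx
    delta = carnosine_mm - model.y_mean  # y0 - yhat(x_bar)
    a = model.slope**2 - g
    b = -2.0 * delta * model.slope
    c = delta**2 - t2s2 * (1.0 + 1.0 / model.n)
    disc = b * b - 4.0 * a * c
    if a > 0 and disc >= 0:
        root = math.sqrt(disc)
        u1, u2 = (-b - root) / (2 * a), (-b + root) / (2 * a)
        lo, hi = model.x_mean + min(u1, u2), model.x_mean + max(u1, u2)
    else:
        # slope not significant at this level: the inversion is unbounded
        lo, hi = float("-inf"), float("inf")
    clamped = False
    est = x_hat
    if est < 0.0 or est > 100.0:
        est = float(np.clip(est, 0.0, 100.0))
        clamped = True
    return est, (lo, hi), clamped


def carnosine_axis_to_ft_axis(model: CalibrationModel, tick_values_mm: Sequence[float]) -> np.ndarray:
    """Map carnosine-axis ticks to the secondary % type-II area axis.

    Element-wise inverse regression; strictly monotone when the slope is
    positive.  Used to draw the estimated fiber-type axis alongside a
    measured-carnosine axis.
    """
    if model.slope == 0:
        raise ValueError("calibration uninformative: slope is zero")
    ticks = np.asarray(tick_values_mm, dtype=float)
    return (ticks - model.intercept) / model.slope


def save_calibration(model: CalibrationModel, path) -> str:
    with open(path, "w") as fh:
        json.dump(asdict(model), fh, indent=2)
    return str(path)


def load_calibration(path) -> CalibrationModel:
    with open(path) as fh:
        return CalibrationModel(**json.load(fh))
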