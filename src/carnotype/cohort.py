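"""Cohort analytics: Z-scores, group summaries, contrasts, sigmoid model.

Men carry systematically more muscle carnosine than women, so mixed-sex
figures use Z-scores against the sex-matched reference (control)
population.  Group contrasts are two-sample t-tests computed from
summary statistics (pooled variance by default, matching the p-values
the original analysis printed; Welch available).  The discipline model
is a four-parameter logistic of Z-score against log10 of an athlete's
best running distance, whose midpoint parameter d50 is directly
interpretable as the distance separating sprint-type from
endurance-type muscle.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Optional, Sequence, Tuple

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .types import ReferenceStats, SigmoidModel, SubjectRecord

__all__ = [
    "zscore",
    "reference_from_records",
    "summary_ttest",
    "group_summaries",
    "percent_difference",
    "fold_change",
    "fit_sigmoid",
    "predict_z",
]


def zscore(value_mm: float, ref: ReferenceStats) -> float:
    """(value - reference mean) / reference SD, within sex."""
    if ref.sd_mm <= 0:
        raise ValueError("reference sd must be > 0")
    return (value_mm - ref.mean_mm) / ref.sd_mm


def reference_from_records(records: Iterable[SubjectRecord], sex: str, group: str = "control") -> ReferenceStats:
    """Build sex-specific reference stats from the control subjects."""
    vals = [r.carnosine_mean_mm for r in records if r.sex == sex and r.group == group]
    if len(vals) < 2:
        raise ValueError(f"fewer than 2 {sex} {group} subjects")
    return ReferenceStats(sex, float(np.mean(vals)), float(np.std(vals, ddof=1)), len(vals))


def summary_ttest(
    n1: int,
    mean1: float,
    sd1: float,
    n2: int,
    mean2: float,
    sd2: float,
    variant: str = "pooled",
) -> Tuple[float, float, float]:
    """Independent two-sample t-test from summary statistics.

    Returns (t, df, two-sided p).  ``pooled`` uses the common-variance
    estimate with df = n1 + n2 - 2; ``welch`` uses the Welch-Satterthwaite
    approximation.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("sds must be > 0")
    v1, v2 = sd1**2, sd2**2
    if variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif variant == "welch":
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    else:
        raise ValueError(f"unknown variant {variant!r}; use 'pooled' or 'welch'")
    if mean1 == mean2:
        return 0.0, float(df), 1.0
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def group_summaries(
    records: Sequence[SubjectRecord],
    stratify: Sequence[str] = ("sex", "group", "category"),
) -> pd.DataFrame:
    """n / mean / sd / median / quartiles per stratum.

    Quartiles use linear interpolation; the SD of a single-subject
    stratum is reported as missing.  Rows are sorted by the stratify
    keys for deterministic output.
    """
    if not records:
        raise ValueError("empty cohort")
    valid = {"sex", "group", "category", "discipline"}
    for key in stratify:
        if key not in valid:
            raise ValueError(f"unknown stratify key {key!r}; valid: {sorted(valid)}")
    df = pd.DataFrame(
        {
            **{k: [getattr(r, k) for r in records] for k in stratify},
            "carnosine_mm": [r.carnosine_mean_mm for r in records],
        }
    )
    out = (
        df.groupby(list(stratify), sort=True)["carnosine_mm"]
        .agg(
            n="count",
            mean_mm="mean",
            sd_mm=lambda v: v.std(ddof=1) if len(v) > 1 else float("nan"),
            median_mm="median",
            q1_mm=lambda v: v.quantile(0.25),
            q3_mm=lambda v: v.quantile(0.75),
        )
        .reset_index()
    )
    return out


def percent_difference(group_mean_mm: float, reference_mean_mm: float) -> float:
    """Signed % difference of a group mean from the reference mean."""
    if reference_mean_mm <= 0:
        raise ValueError("reference mean must be > 0")
    return 100.0 * (group_mean_mm - reference_mean_mm) / reference_mean_mm


def fold_change(mean_a_mm: float, mean_b_mm: float) -> float:
    """Ratio of two group means (e.g. sprinters vs marathoners)."""
    if mean_b_mm <= 0:
        raise ValueError("denominator mean must be > 0")
    return mean_a_mm / mean_b_mm


def _logistic(d: np.ndarray, top: float, bottom: float, log10_d50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (np.log10(d) - log10_d50)))


def fit_sigmoid(distances_m: Sequence[float], z: Sequence[float]) -> SigmoidModel:
    """Least-squares 4-parameter logistic of Z on log10(distance).

    Requires >= 5 points spanning at least one decade of distance.
    Multi-start over d50 at {0.3, 1, 3} times the geometric mean of the
    distances guards against local minima (for the study's 100 m to
    marathon panel this is the {~300, ~1000, ~3000} m grid);
    non-convergence is flagged on the returned model rather than
    silently masked.
    """
    d = np.asarray(distances_m, dtype=float)
    zv = np.asarray(z, dtype=float)
    if d.shape != zv.shape or d.ndim != 1:
        raise ValueError("distances and z must be 1-D arrays of equal length")
    if d.size < 5:
        raise ValueError("need >= 5 points for a 4-parameter fit")
    if np.any(d <= 0):
        raise ValueError("distance <= 0")
    if np.log10(d.max() / d.min()) < 1.0:
        raise ValueError("distances must span at least one decade")
    order = np.argsort(d)
    d, zv = d[order], zv[order]
    z_lo, z_hi = float(zv.min()), float(zv.max())
    span = max(z_hi - z_lo, 1e-6)

    def residual(params):
        return (
            _logistic(d, params["top"], params["bottom"], params["log10_d50"], params["hill"])
            - zv
        )

    best = None
    log_gm = float(np.mean(np.log10(d)))
    for d50_0 in (10.0 ** (log_gm - 0.5), 10.0**log_gm, 10.0 ** (log_gm + 0.5)):
        params = lmfit.Parameters()
        params.add("top", value=z_hi, min=z_lo - 2 * span, max=z_hi + 2 * span)
        params.add("bottom", value=z_lo, min=z_lo - 2 * span, max=z_hi + 2 * span)
        params.add("log10_d50", value=math.log10(d50_0), min=math.log10(d.min()) - 1, max=math.log10(d.max()) + 1)
        params.add("hill", value=2.0, min=0.01, max=50.0)
        try:
            res = lmfit.minimize(residual, params, method="leastsq", xtol=1e-10, ftol=1e-12, max_nfev=5000)
        except Exception:
            continue
        sse = float(np.sum(res.residual**2))
        if best is None or sse < best[0]:
            best = (sse, res)
    if best is None:
        raise RuntimeError("sigmoid fit failed from every start")
    sse, res = best
    p = res.params
    sst = float(np.sum((zv - zv.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return SigmoidModel(
        top=float(p["top"].value),
        bottom=float(p["bottom"].value),
        d50_m=float(10.0 ** p["log10_d50"].value),
        hill=float(p["hill"].value),
        r_squared=r2,
        converged=bool(res.success),
    )


def predict_z(model: SigmoidModel, distance_m) -> np.ndarray:
    """Evaluate the fitted logistic at the given distance(s)."""
    return model(distance_m)
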