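"""Per-participant distortion measures: LLO fits, kernel smoothing, areas.

The distortion of relative-frequency judgment is summarized two ways:

* parametrically, by fitting the linear-in-log-odds model
  ``lambda(pi(p)) = gamma * lambda(p) + (1 - gamma) * lambda(p0)`` by
  ordinary least squares in log-odds (gamma = slope, p0 = crossover point);
* non-parametrically, by Nadaraya-Watson kernel smoothing of pi(p) - p on
  the stimulus grid and integrating the smoothed curve into a curvature
  (unsigned area) and an elevation (signed area) metric.

Group variability is visualized by bootstrap resampling participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SUPPORT, clamp_probability, logistic, logodds

__all__ = [
    "LLOFit",
    "SmoothedCurve",
    "DistortionMetrics",
    "fit_llo",
    "smooth_curve",
    "curvature_elevation",
    "bootstrap_cloud",
]


@dataclass(frozen=True)
class LLOFit:
    """Result of a linear-in-log-odds fit for one participant."""

    gamma: float
    p0: float  # NaN when gamma is numerically 1 (crossover undefined)
    intercept: float
    residual_sd: float
    n_trials: int


@dataclass(frozen=True)
class SmoothedCurve:
    """Kernel-smoothed pi(p) - p evaluated on a probability grid."""

    p_grid: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)
    bandwidth: float = 0.03


@dataclass(frozen=True)
class DistortionMetrics:
    """Area summaries of a smoothed distortion curve.

    ``curvature`` is the unsigned area between the curve and zero
    (inversely related to gamma); ``elevation`` is the signed area, area
    above zero minus area below (related to p0).
    """

    curvature: float
    elevation: float


def _extract(trials) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trials, pd.DataFrame):
        p = trials["p"].to_numpy(float)
        resp = trials["response"].to_numpy(float)
    else:
        p, resp = (np.asarray(a, dtype=float) for a in trials)
    return p, clamp_probability(resp)


def fit_llo(trials) -> LLOFit:
    """Fit the LLO model to one participant's trials by OLS in log-odds.

    ``trials`` is a trial-table DataFrame (columns ``p`` and ``response``)
    or a ``(p, response)`` pair of arrays.  The slope is gamma and the
    intercept c maps to the crossover point ``p0 = logistic(c / (1 -
    gamma))``; when ``|1 - gamma| < 1e-6`` the crossover is undefined and
    p0 is reported as NaN.
    """
    p, resp = _extract(trials)
    if p.size < 10 or np.unique(p).size < 3:
        raise ValueError("fit_llo needs at least 10 trials spanning 3 distinct p values")
    s = logodds(p)
    r = logodds(resp)
    if np.ptp(s) == 0:
        raise ValueError("degenerate design: all stimuli identical")
    X = np.column_stack([s, np.ones_like(s)])
    coef, _, _, _ = np.linalg.lstsq(X, r, rcond=None)
    gamma, intercept = float(coef[0]), float(coef[1])
    resid = r - X @ coef
    p0 = float(logistic(intercept / (1.0 - gamma))) if abs(1.0 - gamma) >= 1e-6 else float("nan")
    return LLOFit(
        gamma=gamma,
        p0=p0,
        intercept=intercept,
        residual_sd=float(np.std(resid)),
        n_trials=int(p.size),
    )


def smooth_curve(trials, h: float = 0.03, p_grid=None) -> SmoothedCurve:
    """Nadaraya-Watson smoothing of pi(p) - p on the probability grid.

    At each grid point x the estimate is the Gaussian-kernel weighted mean
    ``sum_i K((x - p_i)/h) y_i / sum_i K((x - p_i)/h)`` with
    ``y_i = response_i - p_i`` over all trials.  The Gaussian kernel gives
    strictly positive weights, so the curve is defined everywhere.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    p, resp = _extract(trials)
    if p.size < 1:
        raise ValueError("smooth_curve needs at least one trial")
    p_grid = SUPPORT.copy() if p_grid is None else np.asarray(p_grid, dtype=float)
    y = resp - p
    w = np.exp(-((p_grid[:, None] - p[None, :]) ** 2) / (2.0 * h * h))
    values = (w @ y) / w.sum(axis=1)
    return SmoothedCurve(p_grid=p_grid, values=values, bandwidth=h)


def curvature_elevation(curve: SmoothedCurve) -> DistortionMetrics:
    """Trapezoidal curvature (integral of |f|) and elevation (integral of f)."""
    f = np.asarray(curve.values, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("smoothed curve contains non-finite values")
    return DistortionMetrics(
        curvature=float(np.trapezoid(np.abs(f), curve.p_grid)),
        elevation=float(np.trapezoid(f, curve.p_grid)),
    )


def bootstrap_cloud(per_participant, n_boot: int = 500, seed=None) -> pd.DataFrame:
    """Bootstrap the group mean of per-participant metric pairs.

    ``per_participant`` is a DataFrame with one row per participant and
    numeric metric columns (e.g. gamma/p0 or curvature/elevation).  Each of
    the ``n_boot`` resamples draws participants with replacement (same size
    as the group) and records the column means.  Deterministic given
    ``seed``.
    """
    df = pd.DataFrame(per_participant)
    n = len(df)
    if n < 2:
        raise ValueError("bootstrap_cloud needs at least 2 participants")
    rng = np.random.default_rng(seed)
    values = df.to_numpy(float)
    idx = rng.integers(0, n, size=(n_boot, n))
    means = values[idx].mean(axis=1)
    return pd.DataFrame(means, columns=df.columns)
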