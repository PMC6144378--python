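"""Linear and stimulus-dependent (non-linear) sequential-effect estimation.

The linear analysis regresses the current response on the current stimulus
and the previous responses, all in log-odds:

    R_n = beta0 * S_n + sum_i beta_{-i} * R_{n-i} + betaC + noise.

The non-linear analysis asks whether the previous-response coefficient
beta_{-1} depends on where the current and previous stimuli lie: a local
weighted-least-squares regression is run at every grid cell (p_n, p_{n-1}),
with trial weights from a two-dimensional Gaussian kernel centred on the
cell.  Serial dependence of the derivative-of-Gaussian kind shows up as a
ridge of large local beta_{-1} along the diagonal p_{n-1} = p_n.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import logodds
from .synthetic import ObserverParams, simulate_observer

__all__ = [
    "SeqRegressionResult",
    "SeqEffectMap",
    "fit_sequential_ols",
    "wls_beta_map",
    "predicted_beta_map",
    "map_correlation",
]


@dataclass(frozen=True)
class SeqRegressionResult:
    """Global OLS estimates of the sequential regression with m lags."""

    beta0: float
    beta_lags: tuple
    betaC: float
    m: int
    n_obs: int

    @property
    def beta_prev(self) -> float:
        """Coefficient on the immediately preceding response."""
        return self.beta_lags[0]


@dataclass(frozen=True)
class SeqEffectMap:
    """Locally estimated previous-response coefficient over (p_n, p_{n-1}).

    ``beta[i, j]`` is the local beta_{-1} at ``(grid_pn[i], grid_pprev[j])``;
    cells whose Kish effective sample size falls below the guard are NaN.
    """

    grid_pn: np.ndarray = field(repr=False)
    grid_pprev: np.ndarray = field(repr=False)
    beta: np.ndarray = field(repr=False)
    ess: np.ndarray = field(repr=False)
    sigma_k: float = 0.1


def _lagged_design(trials: pd.DataFrame, m: int = 1):
    """Stack per-participant lagged rows: (Y, X, p_n, p_prev).

    Row j (per participant, j > m) has response R_j regressed on
    [S_j, R_{j-1}, ..., R_{j-m}, 1]; lag structure never crosses a
    participant boundary.
    """
    ys, xs, pn, pprev = [], [], [], []
    for _, grp in trials.groupby("participant_id", sort=True):
        grp = grp.sort_values("trial_index")
        p = grp["p"].to_numpy(float)
        s = logodds(p)
        r = logodds(grp["response"].to_numpy(float))
        n = s.size
        if n <= m:
            continue
        rows = np.arange(m, n)
        cols = [s[rows]] + [r[rows - i] for i in range(1, m + 1)] + [np.ones(rows.size)]
        xs.append(np.column_stack(cols))
        ys.append(r[rows])
        pn.append(p[rows])
        pprev.append(p[rows - 1])
    if not ys:
        raise ValueError("no participant has more than m trials")
    return (
        np.concatenate(ys),
        np.vstack(xs),
        np.concatenate(pn),
        np.concatenate(pprev),
    )


def fit_sequential_ols(trials: pd.DataFrame, m: int = 1) -> SeqRegressionResult:
    """OLS of R_n on (S_n, R_{n-1..n-m}, 1) pooled over participants."""
    y, X, _, _ = _lagged_design(trials, m)
    if y.size < m + 10:
        raise ValueError("too few trials for the sequential regression")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"collinear sequential design: rank {rank} < {X.shape[1]} columns"
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return SeqRegressionResult(
        beta0=float(coef[0]),
        beta_lags=tuple(float(c) for c in coef[1 : m + 1]),
        betaC=float(coef[-1]),
        m=m,
        n_obs=int(y.size),
    )


def default_map_grid(n: int = 25) -> np.ndarray:
    """Evenly spaced probability grid over [0.01, 0.99] for beta maps."""
    return np.linspace(0.01, 0.99, n)


def wls_beta_map(
    trials: pd.DataFrame,
    sigma_k: float = 0.1,
    grid=None,
    min_ess: float = 5.0,
) -> SeqEffectMap:
    """Local beta_{-1} over the (p_n, p_{n-1}) plane by kernel-weighted WLS.

    Each cell runs a weighted least-squares regression of R_j on
    (S_j, R_{j-1}, 1) over all lagged trials, with weight matrix
    ``W = diag(w_j^2)`` where ``w_j`` is a two-dimensional Gaussian kernel
    of span ``sigma_k`` centred on the cell, evaluated at
    ``(p_j, p_{j-1})``.  Cells with Kish effective sample size below
    ``min_ess`` are flagged NaN rather than extrapolated.
    """
    y, X, pn, pprev = _lagged_design(trials, m=1)
    if y.size < 30:
        raise ValueError("wls_beta_map needs at least 30 lagged trials")
    grid = default_map_grid() if grid is None else np.asarray(grid, dtype=float)
    norm = 1.0 / (2.0 * np.pi * sigma_k**2)
    beta = np.full((grid.size, grid.size), np.nan)
    ess = np.zeros((grid.size, grid.size))
    for i, gn in enumerate(grid):
        # 1-D kernel factors reused across the row of cells
        kn = np.exp(-((pn - gn) ** 2) / (2.0 * sigma_k**2))
        for j, gp in enumerate(grid):
            w = norm * kn * np.exp(-((pprev - gp) ** 2) / (2.0 * sigma_k**2))
            v = w * w  # the diagonal of W carries the squared kernel
            sv = v.sum()
            if sv <= 0:
                continue
            ess[i, j] = sv**2 / np.sum(v * v)
            if ess[i, j] < min_ess:
                continue
            XtW = X.T * v
            coef = np.linalg.solve(XtW @ X, XtW @ y)
            beta[i, j] = coef[1]
    return SeqEffectMap(grid_pn=grid, grid_pprev=grid, beta=beta, ess=ess, sigma_k=sigma_k)


def predicted_beta_map(
    params: ObserverParams,
    trials: pd.DataFrame,
    n_sim: int = 20,
    seed=None,
    sigma_k: float = 0.1,
    grid=None,
    min_ess: float = 5.0,
) -> SeqEffectMap:
    """Model-predicted beta map: simulate on the observed stimulus sequences.

    The fitted model generates fresh responses to each participant's actual
    stimulus sequence ``n_sim`` times; :func:`wls_beta_map` is computed per
    simulation and the maps averaged cell-wise (NaN cells ignored).
    """
    rng = np.random.default_rng(seed)
    sequences = [
        (pid, grp.sort_values("trial_index")["p"].to_numpy(float))
        for pid, grp in trials.groupby("participant_id", sort=True)
    ]
    maps = []
    template = None
    for _ in range(n_sim):
        tables = [
            simulate_observer(params, stim, seed=rng.integers(0, 2**31), participant_id=pid)
            for pid, stim in sequences
        ]
        m = wls_beta_map(pd.concat(tables, ignore_index=True), sigma_k=sigma_k, grid=grid, min_ess=min_ess)
        maps.append(m.beta)
        template = m
    with np.errstate(invalid="ignore"):
        mean_beta = np.nanmean(np.stack(maps), axis=0)
    return replace(template, beta=mean_beta)


def map_correlation(observed: SeqEffectMap, predicted: SeqEffectMap) -> float:
    """Pearson r between two beta maps over their common finite cells."""
    if observed.beta.shape != predicted.beta.shape:
        raise ValueError("beta maps must share the same grid")
    a = observed.beta.ravel()
    b = predicted.beta.ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 jointly finite cells")
    return float(stats.pearsonr(a[ok], b[ok]).statistic)
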