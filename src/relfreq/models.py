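"""Maximum-likelihood fitting of the six observer models and comparison.

Each model predicts the log-odds response R_n of trial n from the log-odds
stimulus S_n, optionally an adaptation level L_n updated by the delta rule
from the observed stimuli, and optionally previous-response terms (linear or
derivative-of-Gaussian), with additive Gaussian noise.  Fitting maximizes
the Gaussian likelihood of the observed R_n around the model mean; only
trials with index n >= 6 enter the likelihood so that lags up to 5 trials
back are always available.

The likelihood is maximized by profiling: for fixed values of the
non-linear parameters (learning rate kappa, scope-of-influence omega) the
model mean is linear in (beta0, beta_lags, betaC), which are solved in
closed form by least squares together with the noise SD; a bounded
quasi-Newton search with random multistart then covers the (at most
two-dimensional) non-linear subspace.

Model comparison uses the small-sample-corrected Akaike criterion and a
random-effects group analysis (variational Dirichlet scheme) yielding
protected exceedance probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal, special

from .core import logodds
from .synthetic import MODELS, ObserverParams

__all__ = [
    "ModelFamily",
    "FitResult",
    "DEFAULT_BOUNDS",
    "FIRST_FITTED_TRIAL",
    "model_family",
    "adaptation_level",
    "predict_mean",
    "negloglik",
    "fit_model",
    "aicc",
    "compare_models",
    "protected_exceedance_probability",
]

#: Trials with 1-based index below this are excluded from the likelihood,
#: so lag terms up to 5 trials back always have observed predecessors.
FIRST_FITTED_TRIAL = 6

#: Bounds used both for multistart sampling and for the bounded search.
DEFAULT_BOUNDS = {
    "beta0": (1e-6, 2.0),
    "beta_lag": (-0.5, 0.5),
    "betaC": (-2.0, 2.0),
    "kappa": (0.0, 1.0),
    "omega": (0.1, 10.0),
    "sigma": (0.01, 3.0),
}


@dataclass(frozen=True)
class ModelFamily:
    """Structural description of one of the six model families."""

    name: str
    has_adaptation: bool
    seq_kind: str  # none | linear | nonlinear

    def k(self, m: int = 1) -> int:
        """Free-parameter count (sigma_noise included)."""
        k = 3  # beta0, betaC, sigma
        if self.has_adaptation:
            k += 1  # kappa
        if self.seq_kind != "none":
            k += m  # lag coefficients
        if self.seq_kind == "nonlinear":
            k += 1  # omega
        return k


def model_family(name: str) -> ModelFamily:
    if name not in MODELS:
        raise ValueError(f"unknown model family {name!r}; expected one of {MODELS}")
    return ModelFamily(
        name=name,
        has_adaptation=name.startswith("AL"),
        seq_kind="nonlinear" if name.endswith("-NL") else ("linear" if name.endswith("-L") else "none"),
    )


def adaptation_level(s: np.ndarray, kappa: float, L_init: float = 0.0) -> np.ndarray:
    """Delta-rule adaptation level L_n = L_{n-1} + kappa (S_{n-1} - L_{n-1}).

    L_1 = ``L_init``; the whole recursion is an exponential filter of the
    stimulus history and is evaluated with a linear filter.
    """
    s = np.asarray(s, dtype=float)
    if kappa == 0.0:
        return np.full(s.size, L_init)
    zi = np.array([(1.0 - kappa) * L_init])
    tail, _ = signal.lfilter([kappa], [1.0, -(1.0 - kappa)], s[:-1], zi=zi)
    return np.concatenate([[L_init], tail])


def _extract_sr(trials) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trials, pd.DataFrame):
        df = trials.sort_values("trial_index")
        return logodds(df["p"].to_numpy(float)), logodds(df["response"].to_numpy(float))
    s, r = (np.asarray(a, dtype=float) for a in trials)
    return s, r


def _lag_columns(family: ModelFamily, s, r, omega: float, m: int) -> list[np.ndarray]:
    """Per-lag regressor columns built from observed previous responses.

    Rows whose lag would reach before the first trial are zero; they never
    enter the likelihood (the first fitted trial exceeds m).
    """
    cols = []
    for i in range(1, m + 1):
        col = np.zeros(s.size)
        if family.seq_kind == "linear":
            col[i:] = r[:-i]
        else:
            d = r[:-i] - s[i:]
            col[i:] = d * np.exp(-(d * d) / (2.0 * omega**2))
        cols.append(col)
    return cols


def predict_mean(family: ModelFamily, params: ObserverParams, s, r) -> np.ndarray:
    """Model-mean log-odds response per trial, using observed lags and stimuli."""
    s = np.asarray(s, dtype=float)
    r = np.asarray(r, dtype=float)
    base = s - adaptation_level(s, params.kappa, params.L_init) if family.has_adaptation else s
    mean = params.beta0 * base + params.betaC
    if family.seq_kind != "none":
        for beta, col in zip(
            params.beta_lags, _lag_columns(family, s, r, params.omega, params.m)
        ):
            mean = mean + beta * col
    return mean


def negloglik(family, params: ObserverParams, trials, first_fitted: int = FIRST_FITTED_TRIAL) -> float:
    """Negative Gaussian log-likelihood (nats) of the fitted trials.

    Only trials with 1-based index >= ``first_fitted`` contribute; the
    adaptation-level recursion and lag terms still use the full series.
    """
    if isinstance(family, str):
        family = model_family(family)
    if params.sigma_noise <= 0:
        raise ValueError("sigma_noise must be positive")
    s, r = _extract_sr(trials)
    mean = predict_mean(family, params, s, r)
    resid = (r - mean)[first_fitted - 1 :]
    n = resid.size
    sig2 = params.sigma_noise**2
    return float(0.5 * n * np.log(2.0 * np.pi * sig2) + np.sum(resid**2) / (2.0 * sig2))


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one family to one participant."""

    family: str
    params: ObserverParams
    loglik: float
    aicc: float
    k: int
    n_fitted: int
    n_restarts: int
    converged: bool


def aicc(loglik: float, k: int, n: int, correction: str = "kminus1") -> float:
    """Small-sample-corrected Akaike information criterion.

    The default ``correction='kminus1'`` uses the penalty ``2k(k-1)/(n-k-1)``
    — the convention of the analyses this pipeline mirrors;
    ``correction='standard'`` switches to the textbook
    ``2k(k+1)/(n-k-1)``.  The two differ by a constant for fixed k and
    never change a comparison at equal k.
    """
    if n <= k + 1:
        raise ValueError("aicc requires n > k + 1")
    if correction == "kminus1":
        extra = 2.0 * k * (k - 1) / (n - k - 1)
    elif correction == "standard":
        extra = 2.0 * k * (k + 1) / (n - k - 1)
    else:
        raise ValueError("correction must be 'kminus1' or 'standard'")
    return float(-2.0 * loglik + 2.0 * k + extra)


def _profiled_fit(family: ModelFamily, s, r, mask, kappa: float, omega: float, m: int):
    """Closed-form ML over the linear coefficients and sigma at fixed (kappa, omega).

    Returns (loglik, coefs) where coefs = (beta0, beta_lags, betaC, sigma).
    """
    base = s - adaptation_level(s, kappa) if family.has_adaptation else s
    cols = [base]
    if family.seq_kind != "none":
        cols += _lag_columns(family, s, r, omega, m)
    cols.append(np.ones(s.size))
    X = np.column_stack(cols)[mask]
    y = r[mask]
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    n = y.size
    sig = max(float(np.sqrt(np.mean(resid**2))), 1e-6)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sig**2) + np.mean(resid**2) / sig**2)
    n_lags = m if family.seq_kind != "none" else 0
    beta_lags = tuple(float(c) for c in coef[1 : 1 + n_lags]) if n_lags else (0.0,)
    return loglik, (float(coef[0]), beta_lags, float(coef[-1]), sig)


def fit_model(
    family,
    trials,
    n_restarts: int = 20,
    seed=None,
    bounds: dict | None = None,
    m: int = 1,
    first_fitted: int = FIRST_FITTED_TRIAL,
) -> FitResult:
    """Best-of-restarts maximum-likelihood fit of one family to one participant.

    The linear coefficients and the noise SD are profiled out in closed
    form, so the numerical search runs only over kappa and/or omega (when
    the family has them) with L-BFGS-B inside the declared bounds,
    restarted from ``n_restarts`` starting points (a deterministic start at
    the bound-box centre plus kappa = 0 / a small-omega corner, the rest
    drawn uniformly from the bounds).  Deterministic given ``seed``.
    """
    if isinstance(family, str):
        family = model_family(family)
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    s, r = _extract_sr(trials)
    mask = np.arange(1, s.size + 1) >= first_fitted
    n_fitted = int(mask.sum())
    k = family.k(m)
    if n_fitted < k + 20:
        raise ValueError("too few fitted trials for a stable fit")

    free = []  # names of non-linear parameters searched numerically
    if family.has_adaptation:
        free.append("kappa")
    if family.seq_kind == "nonlinear":
        free.append("omega")

    def unpack(theta):
        d = {"kappa": 0.0, "omega": 1.0}
        for name, val in zip(free, theta):
            d[name] = float(val)
        return d

    def objective(theta):
        d = unpack(theta)
        loglik, _ = _profiled_fit(family, s, r, mask, d["kappa"], d["omega"], m)
        return -loglik

    converged = True
    if not free:
        best_theta, n_used = np.empty(0), 1
    else:
        lo = np.array([bounds[n][0] for n in free])
        hi = np.array([bounds[n][1] for n in free])
        rng = np.random.default_rng(seed)
        # The likelihood can be sharply peaked in kappa (the delta-rule
        # filter changes fast at small learning rates), so local searches
        # start from the best points of a coarse deterministic grid in
        # addition to random draws within the bounds.
        grids = {
            "kappa": np.array([0.0, 0.005, 0.01, 0.02, 0.035, 0.05, 0.08, 0.12, 0.2, 0.35, 0.6, 1.0]),
            "omega": np.array([0.1, 0.3, 0.7, 1.5, 3.0, 6.0, 10.0]),
        }
        axes = [np.clip(grids[name], bounds[name][0], bounds[name][1]) for name in free]
        mesh = np.stack([a.ravel() for a in np.meshgrid(*axes, indexing="ij")], axis=1)
        grid_vals = np.array([objective(theta) for theta in mesh])
        top = mesh[np.argsort(grid_vals)[:3]]
        starts = list(top) + [0.5 * (lo + hi)]
        while len(starts) < max(n_restarts, len(starts)):
            starts.append(rng.uniform(lo, hi))
        best_theta, best_val, converged = None, np.inf, False
        for x0 in starts:
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B", bounds=list(zip(lo, hi))
            )
            if np.isfinite(res.fun) and res.fun < best_val:
                best_theta, best_val = res.x, float(res.fun)
                converged = converged or bool(res.success)
        if best_theta is None:  # every local search failed: fall back to the grid
            best_theta = mesh[int(np.argmin(grid_vals))]
        n_used = len(starts)

    d = unpack(best_theta)
    loglik, (beta0, beta_lags, betaC, sig) = _profiled_fit(
        family, s, r, mask, d["kappa"], d["omega"], m
    )
    params = ObserverParams(
        model=family.name,
        beta0=beta0,
        beta_lags=beta_lags,
        betaC=betaC,
        kappa=d["kappa"],
        omega=d["omega"],
        sigma_noise=sig,
    )
    return FitResult(
        family=family.name,
        params=params,
        loglik=float(loglik),
        aicc=aicc(loglik, k, n_fitted),
        k=k,
        n_fitted=n_fitted,
        n_restarts=n_used,
        converged=bool(converged),
    )


def compare_models(fits: pd.DataFrame) -> pd.DataFrame:
    """Summarize a participants x families grid of fits.

    ``fits`` has columns ``participant_id``, ``family``, ``aicc`` (one row
    per fit; the grid must be complete).  Returns one row per family with
    the summed AICc, the difference to the best family, and the number of
    participants for which the family is individually best.
    """
    pivot = fits.pivot(index="participant_id", columns="family", values="aicc")
    if pivot.isna().any().any():
        raise ValueError("incomplete participants x families grid")
    summed = pivot.sum(axis=0)
    best_counts = pivot.idxmin(axis=1).value_counts()
    out = pd.DataFrame(
        {
            "summed_aicc": summed,
            "delta_aicc": summed - summed.min(),
            "n_participants_best": [int(best_counts.get(f, 0)) for f in summed.index],
        }
    )
    return out.sort_values("summed_aicc")


def protected_exceedance_probability(
    log_evidence,
    n_samples: int = 200_000,
    seed=None,
    alpha0: float = 1.0,
):
    """Random-effects group model selection from per-participant log evidence.

    ``log_evidence`` is an (participants x families) array — here the
    AICc-based proxy ``-AICc / 2``.  A variational Dirichlet scheme
    estimates the population frequencies of the families; exceedance
    probabilities (the chance each family is the most frequent) are
    computed by Dirichlet Monte-Carlo sampling, and protected against the
    null of equal frequencies via the Bayesian omnibus risk:
    ``PXP = (1 - BOR) * EP + BOR / K``.

    Returns a dict with ``pxp``, ``ep``, ``bor``, ``alpha`` and the
    expected frequencies ``freq``.
    """
    lme = np.asarray(log_evidence, dtype=float)
    if lme.ndim != 2 or lme.shape[0] < 2 or lme.shape[1] < 2:
        raise ValueError("log_evidence must be (>=2 participants) x (>=2 families)")
    if not np.all(np.isfinite(lme)):
        raise ValueError("log evidence must be finite")
    n, K = lme.shape
    a0 = np.full(K, float(alpha0))

    # Variational updates (Dirichlet posterior over family frequencies).
    alpha = a0.copy()
    g = np.full((n, K), 1.0 / K)
    for _ in range(500):
        logu = lme + (special.digamma(alpha) - special.digamma(alpha.sum()))[None, :]
        logu -= logu.max(axis=1, keepdims=True)
        g_new = np.exp(logu)
        g_new /= g_new.sum(axis=1, keepdims=True)
        alpha_new = a0 + g_new.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < 1e-10:
            alpha, g = alpha_new, g_new
            break
        alpha, g = alpha_new, g_new

    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=n_samples)
    ep = np.bincount(np.argmax(samples, axis=1), minlength=K) / n_samples

    # Free energy of the random-effects model vs the equal-frequency null.
    Elogr = special.digamma(alpha) - special.digamma(alpha.sum())
    Sqf = (
        np.sum(special.gammaln(alpha))
        - special.gammaln(alpha.sum())
        - np.sum((alpha - 1.0) * Elogr)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        Sqm = -np.sum(np.where(g > 0, g * np.log(g), 0.0))
    ELJ = (
        special.gammaln(a0.sum())
        - np.sum(special.gammaln(a0))
        + np.sum((a0 - 1.0) * Elogr)
        + np.sum(g * (Elogr[None, :] + lme))
    )
    F1 = ELJ + Sqf + Sqm
    F0 = float(np.sum(special.logsumexp(lme - np.log(K), axis=1)))
    bor = float(1.0 / (1.0 + np.exp(F1 - F0)))

    pxp = (1.0 - bor) * ep + bor / K
    pxp /= pxp.sum()
    return {
        "pxp": pxp,
        "ep": ep,
        "bor": bor,
        "alpha": alpha,
        "freq": alpha / alpha.sum(),
    }
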