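"""Closed-form predictors for the two competing context-effect theories.

Both theories predict how the subjective-frequency curve pi(p) should shift
when the stimulus distribution changes, but in opposite directions:

* **Adaptation-level theory** subtracts a reference point (the adaptation
  level L, set by the mean stimulus of the context) inside an LLO transform,
  so pi(p) is *repelled* from the concentrated regions of p — overall
  overestimation in the Small condition, underestimation in the Large one,
  and no U/E difference (same mean).

* **Bayesian inference** (Bayes-least-squares observer) combines a noisy
  log-odds percept with the stimulus distribution as prior and reports the
  posterior mean, so pi(p) is *attracted* toward the concentrated regions —
  underestimation in Small, overestimation in Large, and a steeper curve in
  Extreme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SUPPORT, ConditionPMF, logistic, logodds

__all__ = [
    "ALTheoryParams",
    "BayesObserverSpec",
    "al_theory_curve",
    "bayes_bls_curve",
]


@dataclass(frozen=True)
class ALTheoryParams:
    """Adaptation-level predictor parameters.

    ``gamma`` is the LLO slope, ``p0`` the crossover point, and ``eta``
    scales how strongly the adaptation level tracks the mean log-odds of
    the stimulus distribution.
    """

    gamma: float = 0.8
    p0: float = 0.5
    eta: float = 0.2

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not (0.0 < self.p0 < 1.0):
            raise ValueError("p0 must lie in (0, 1)")


@dataclass(frozen=True)
class BayesObserverSpec:
    """Bayes-least-squares observer: percept noise and marginalization grid.

    The percept y of a stimulus p is Gaussian around lambda(p) with SD
    ``sigma_noise`` on the log-odds scale; the prior over the true value is
    the condition pmf.  ``y_lo``/``y_hi``/``n_y`` define the log-odds grid
    on which y is marginalized by trapezoidal quadrature.
    """

    pmf: ConditionPMF
    sigma_noise: float = 1.0
    y_lo: float = -10.0
    y_hi: float = 10.0
    n_y: int = 1335

    def __post_init__(self):
        if self.sigma_noise <= 0:
            raise ValueError("sigma_noise must be positive")
        if not (self.y_lo <= -8.0 and self.y_hi >= 8.0):
            raise ValueError("y grid must cover at least [-8, 8] in log-odds")
        if self.n_y < 3:
            raise ValueError("n_y must be at least 3")


def al_theory_curve(params: ALTheoryParams, pmf: ConditionPMF, p_grid=None):
    """Adaptation-level prediction pi(p) over ``p_grid``.

    The adaptation level satisfies ``lambda(L) = eta * sum_p theta(p)
    lambda(p)`` (exact enumeration over the pmf support) and enters the LLO
    transform as ``lambda(pi) = gamma * (lambda(p) - lambda(L)) +
    (1 - gamma) * lambda(p0)``.

    Returns ``(p_grid, pi)`` as float arrays.
    """
    p_grid = SUPPORT.copy() if p_grid is None else np.asarray(p_grid, dtype=float)
    lam_L = params.eta * pmf.mean_logodds()
    lam_pi = params.gamma * (logodds(p_grid) - lam_L) + (1.0 - params.gamma) * logodds(params.p0)
    return p_grid, logistic(lam_pi)


def bayes_bls_curve(spec: BayesObserverSpec, p_grid=None):
    """Bayes-least-squares prediction pi(p) over ``p_grid``.

    For every percept value y on the grid the posterior over the 99
    candidate stimuli q is ``Pr(y | q) * theta(q)`` normalized to sum 1,
    and the reported estimate is the posterior mean of q.  The observable
    mapping marginalizes the percept: ``pi(p) = integral pi_y Pr(y | p)
    dy``, computed by trapezoidal quadrature on the log-odds y grid with
    ``Pr(y | p)`` Gaussian and renormalized on the grid.

    Raises if the grid is too narrow to hold at least ``1 - 1e-6`` of the
    percept distribution's mass for any requested p.
    """
    p_grid = SUPPORT.copy() if p_grid is None else np.asarray(p_grid, dtype=float)
    y = np.linspace(spec.y_lo, spec.y_hi, spec.n_y)
    sig = spec.sigma_noise
    lam_q = logodds(spec.pmf.support)

    # Posterior mean estimate for each percept value y; normalized in log
    # space so tiny sigma_noise does not underflow.
    with np.errstate(divide="ignore"):
        logpost = -((y[:, None] - lam_q[None, :]) ** 2) / (2.0 * sig**2) + np.log(
            spec.pmf.mass[None, :]
        )
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    pi_y = post @ spec.pmf.support

    # Marginalize the percept for each stimulus p.
    lam_p = logodds(p_grid)
    dens = np.exp(-((y[None, :] - lam_p[:, None]) ** 2) / (2.0 * sig**2)) / (
        sig * np.sqrt(2.0 * np.pi)
    )
    coverage = np.trapezoid(dens, y, axis=1)
    if np.any(coverage < 1.0 - 1e-6):
        raise ValueError(
            "y grid too narrow: percept distribution not covered to 1 - 1e-6 "
            f"(min coverage {coverage.min():.8f})"
        )
    dens /= coverage[:, None]
    pi_p = np.trapezoid(dens * pi_y[None, :], y, axis=1)
    return p_grid, pi_p
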