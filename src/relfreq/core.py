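"""Log-odds scale and the four stimulus-distribution conditions.

Relative-frequency judgments are modelled on the log-odds scale
``lambda(p) = log(p / (1 - p))`` (natural log), on which the
linear-in-log-odds (LLO) family of distortion models is linear.  The
experiment draws objective relative-frequencies from one of four discrete
distributions over the 99-value support ``{0.01, 0.02, ..., 0.99}``:

* ``U`` (Uniform)  — every value equally likely;
* ``E`` (Extreme)  — small and large values over-represented (U-shaped);
* ``S`` (Small)    — half the mass on ``[0.01, 0.10]``;
* ``L`` (Large)    — mirror of ``S``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "CONDITIONS",
    "SUPPORT",
    "CLAMP_LO",
    "CLAMP_HI",
    "ConditionPMF",
    "logodds",
    "logistic",
    "clamp_probability",
    "condition_pmf",
    "expected_adjacent_distance",
]

CONDITIONS = ("U", "E", "S", "L")

#: The 99 admissible relative-frequency values 0.01 .. 0.99, built from
#: integers to avoid float accumulation error.
SUPPORT = np.arange(1, 100) / 100.0

# Reported responses of 0 or 100% have no log-odds; they are clamped half a
# stimulus step inside the admissible range before transforming.
CLAMP_LO = 0.005
CLAMP_HI = 0.995


def logodds(p):
    """Natural-log odds ``lambda(p) = log(p / (1 - p))``.

    Accepts scalars or arrays; every element must lie strictly inside
    (0, 1) — callers clamp boundary responses first.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError("logodds requires probabilities strictly inside (0, 1)")
    out = logit(arr)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def logistic(x):
    """Inverse of :func:`logodds`: ``p = 1 / (1 + exp(-x))``."""
    arr = np.asarray(x, dtype=float)
    out = expit(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def clamp_probability(p):
    """Clamp reported probabilities into ``[0.005, 0.995]``.

    The response bar allows 0 and 100%, where log-odds are undefined; the
    clamp is half of the 0.01 stimulus step inside each boundary.
    """
    arr = np.asarray(p, dtype=float)
    out = np.clip(arr, CLAMP_LO, CLAMP_HI)
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


@dataclass(frozen=True)
class ConditionPMF:
    """Discrete stimulus distribution theta(p) of one condition.

    Attributes
    ----------
    condition : str
        One of ``U``, ``E``, ``S``, ``L`` (or a custom label for ad-hoc
        pmfs used in tests and theory predictions).
    support : numpy.ndarray
        Ordered stimulus values, by default the 99-value grid.
    mass : numpy.ndarray
        Probability of each support value; non-negative, sums to one.
    """

    condition: str
    support: np.ndarray = field(repr=False)
    mass: np.ndarray = field(repr=False)

    def __post_init__(self):
        support = np.asarray(self.support, dtype=float)
        mass = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "mass", mass)
        if support.shape != mass.shape or support.ndim != 1:
            raise ValueError("support and mass must be 1-D arrays of equal length")
        if np.any(mass < 0):
            raise ValueError("pmf masses must be non-negative")
        if abs(mass.sum() - 1.0) > 1e-12:
            raise ValueError("pmf masses must sum to 1 within 1e-12")

    def mean_logodds(self) -> float:
        """Expected log-odds ``sum_p theta(p) * lambda(p)`` of the condition."""
        return float(np.sum(self.mass * logodds(self.support)))

    def mirrored(self) -> "ConditionPMF":
        """The pmf of the mirror-reflected stimuli ``p -> 1 - p``."""
        return ConditionPMF(
            condition=self.condition + "-mirror",
            support=self.support,
            mass=self.mass[::-1].copy(),
        )


def condition_pmf(condition: str) -> ConditionPMF:
    """Stimulus distribution theta(p) for condition ``U``, ``E``, ``S`` or ``L``.

    The masses follow the experiment's design exactly:

    * ``U``: 1/99 on every support value.
    * ``E``: 3/99 on each value in {0.01..0.10} and {0.90..0.99} (30/99 of
      trials on each end), (39/79)/99 on each middle value.
    * ``S``: 5/99 on each value in {0.01..0.10} (50/99 of trials on small
      values), (49/89)/99 on each value in {0.11..0.99}.
    * ``L``: mirror image of ``S``.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    idx = np.arange(1, 100)  # support value * 100
    mass = np.empty(99)
    if condition == "U":
        mass[:] = 1.0 / 99.0
    elif condition == "E":
        ends = (idx <= 10) | (idx >= 90)
        mass[ends] = 3.0 / 99.0
        mass[~ends] = (39.0 / 79.0) / 99.0
    elif condition == "S":
        small = idx <= 10
        mass[small] = 5.0 / 99.0
        mass[~small] = (49.0 / 89.0) / 99.0
    else:  # L, mirror of S
        large = idx >= 90
        mass[large] = 5.0 / 99.0
        mass[~large] = (49.0 / 89.0) / 99.0
    return ConditionPMF(condition=condition, support=SUPPORT.copy(), mass=mass)


def expected_adjacent_distance(pmf: ConditionPMF) -> float:
    """Expected |lambda(p_i) - lambda(p_j)| between two independent draws.

    Computed by exact double enumeration over the support grid:
    ``sum_i sum_j theta(p_i) theta(p_j) |lambda(p_i) - lambda(p_j)|``.
    This is the distribution-level analogue of the mean absolute log-odds
    distance between consecutive trials of an i.i.d. stimulus sequence.
    """
    lo = logodds(pmf.support)
    dist = np.abs(lo[:, None] - lo[None, :])
    return float(np.einsum("i,j,ij->", pmf.mass, pmf.mass, dist))
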