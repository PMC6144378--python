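"""Synthetic experiment generator: stimulus sequences and model observers.

Emulates the relative-frequency judgment experiment — per condition, 16
participants each complete 693 trials (7 blocks of 99) whose objective
relative-frequencies follow the condition's distribution — and generates
responses from any of six generative observer models built on the
linear-in-log-odds (LLO) transform:

========  ==========================================================
LLO       R_n = b0 * S_n + bC + noise
AL        R_n = b0 * (S_n - L_n) + bC + noise, with delta-rule L_n
LLO-L     LLO + linear previous-response terms  b_{-i} * R_{n-i}
LLO-NL    LLO + derivative-of-Gaussian terms
          b_{-i} * (R_{n-i} - S_n) * exp(-(R_{n-i} - S_n)^2 / (2 w^2))
AL-L      AL + linear terms
AL-NL     AL + derivative-of-Gaussian terms
========  ==========================================================

All quantities are in natural-log odds: S_n = logodds(p_n) is the stimulus,
R_n = logodds(response_n) the realized (noisy, clamped) response; lag terms
feed on realized previous responses, and the adaptation level follows the
delta rule L_n = L_{n-1} + kappa * (S_{n-1} - L_{n-1}).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import (
    ConditionPMF,
    clamp_probability,
    logistic,
    logodds,
)

__all__ = [
    "MODELS",
    "TRIAL_COLUMNS",
    "ExperimentDesign",
    "ObserverParams",
    "generate_stimulus_sequence",
    "simulate_observer",
    "simulate_cohort",
    "read_trials",
    "write_trials",
]

MODELS = ("LLO", "AL", "LLO-L", "LLO-NL", "AL-L", "AL-NL")

TRIAL_COLUMNS = [
    "participant_id",
    "condition",
    "block",
    "trial_index",
    "n_dots",
    "p",
    "response",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Trial bookkeeping of the experiment.

    693 trials in 7 blocks of 99 per participant, 16 participants per
    condition; the total dot count of a display is one of 200, 300, ..., 800
    (carried as a covariate, never used in analysis).
    """

    n_blocks: int = 7
    block_size: int = 99
    n_participants: int = 16
    dot_totals: tuple = (200, 300, 400, 500, 600, 700, 800)

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.block_size


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one of the six observer models.

    Parameters irrelevant to the chosen model are carried but ignored
    (e.g. ``omega`` for LLO).  ``beta_lags[i-1]`` is the coefficient of the
    i-trial-back term; its length sets the number of lags m.
    """

    model: str = "LLO"
    beta0: float = 1.0
    beta_lags: tuple = (0.0,)
    betaC: float = 0.0
    kappa: float = 0.0
    omega: float = 1.0
    sigma_noise: float = 0.3
    L_init: float = 0.0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError("kappa must lie in [0, 1]")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be non-negative")
        object.__setattr__(self, "beta_lags", tuple(float(b) for b in self.beta_lags))
        if len(self.beta_lags) < 1:
            raise ValueError("at least one lag coefficient is required")

    @property
    def m(self) -> int:
        return len(self.beta_lags)

    @property
    def has_adaptation(self) -> bool:
        return self.model.startswith("AL")

    @property
    def seq_kind(self) -> str:
        if self.model.endswith("-NL"):
            return "nonlinear"
        if self.model.endswith("-L"):
            return "linear"
        return "none"


def generate_stimulus_sequence(
    pmf: ConditionPMF,
    design: ExperimentDesign = ExperimentDesign(),
    seed=None,
    mode: str = "block-balanced",
) -> np.ndarray:
    """Draw a participant's stimulus sequence from the condition pmf.

    ``mode='iid'`` draws every trial independently from theta; the default
    ``'block-balanced'`` draws each 99-trial block's composition as one
    multinomial draw from theta and shuffles it within the block, so block
    histograms track theta tightly.
    """
    if mode not in ("iid", "block-balanced"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    if mode == "iid":
        return rng.choice(pmf.support, size=design.n_trials, p=pmf.mass)
    blocks = []
    for _ in range(design.n_blocks):
        counts = rng.multinomial(design.block_size, pmf.mass)
        block = np.repeat(pmf.support, counts)
        rng.shuffle(block)
        blocks.append(block)
    return np.concatenate(blocks)


def _sequential_term(params: ObserverParams, lag_responses, s_n: float) -> float:
    """Sum of lag contributions for one trial given realized lag responses."""
    if params.seq_kind == "none":
        return 0.0
    total = 0.0
    for beta, r_prev in zip(params.beta_lags, lag_responses):
        if r_prev is None:  # lag reaches before the first trial: dropped
            continue
        if params.seq_kind == "linear":
            total += beta * r_prev
        else:
            d = r_prev - s_n
            total += beta * d * np.exp(-(d * d) / (2.0 * params.omega**2))
    return total


def simulate_observer(
    params: ObserverParams,
    stimuli,
    seed=None,
    participant_id: int = 1,
    condition: str = "U",
    design: ExperimentDesign = ExperimentDesign(),
) -> pd.DataFrame:
    """Generate one observer's trial table from a stimulus sequence.

    Responses are produced sequentially: the model's predicted mean in
    log-odds gets Gaussian noise of SD ``sigma_noise`` added, is mapped to
    the probability scale and clamped; lag terms on later trials use the
    realized (clamped) responses.  Trials n <= m use only the lags that
    exist.  Deterministic given ``seed``.
    """
    stimuli = np.asarray(stimuli, dtype=float)
    n = stimuli.size
    if n == 0:
        raise ValueError("stimuli must be non-empty")
    if params.m >= n:
        raise ValueError("number of lags must be smaller than the number of trials")
    rng = np.random.default_rng(seed)
    s = logodds(stimuli)
    noise = rng.normal(0.0, params.sigma_noise, size=n) if params.sigma_noise > 0 else np.zeros(n)
    n_dots = rng.choice(design.dot_totals, size=n)

    r = np.empty(n)
    level = params.L_init
    for i in range(n):
        base = s[i] - level if params.has_adaptation else s[i]
        lags = [r[i - j] if i - j >= 0 else None for j in range(1, params.m + 1)]
        mean = params.beta0 * base + _sequential_term(params, lags, s[i]) + params.betaC
        raw = mean + noise[i]
        r[i] = logodds(clamp_probability(logistic(raw)))
        if params.has_adaptation:
            level = level + params.kappa * (s[i] - level)

    trial_index = np.arange(1, n + 1)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "condition": condition,
            "block": (trial_index - 1) // design.block_size + 1,
            "trial_index": trial_index,
            "n_dots": n_dots,
            "p": stimuli,
            "response": logistic(r),
        }
    )


def simulate_cohort(
    design: ExperimentDesign,
    condition: str,
    params: ObserverParams,
    pmf: ConditionPMF,
    seed=None,
    mode: str = "block-balanced",
    param_jitter: float = 0.0,
) -> pd.DataFrame:
    """Simulate ``design.n_participants`` independent observers of one condition.

    Every participant gets an independent stimulus sequence and noise
    stream, all derived reproducibly from the master ``seed``.  With
    ``param_jitter > 0``, each participant's beta0 and sigma_noise are
    multiplied by independent log-normal factors of that log-SD (a simple
    model of between-participant spread); the default is fixed parameters.
    """
    master = np.random.default_rng(seed)
    tables = []
    for pid in range(1, design.n_participants + 1):
        seq_seed, obs_seed, jit_seed = master.integers(0, 2**31, size=3)
        stimuli = generate_stimulus_sequence(pmf, design, seed=seq_seed, mode=mode)
        p = params
        if param_jitter > 0:
            jrng = np.random.default_rng(jit_seed)
            p = replace(
                params,
                beta0=params.beta0 * float(np.exp(jrng.normal(0, param_jitter))),
                sigma_noise=params.sigma_noise * float(np.exp(jrng.normal(0, param_jitter))),
            )
        tables.append(
            simulate_observer(
                p, stimuli, seed=obs_seed, participant_id=pid, condition=condition, design=design
            )
        )
    return pd.concat(tables, ignore_index=True)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as UTF-8 CSV with p/response at 6 decimals."""
    out = trials[TRIAL_COLUMNS].copy()
    out["p"] = out["p"].map(lambda v: f"{v:.6f}")
    out["response"] = out["response"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV written by :func:`write_trials`.

    Responses are clamped into (0, 1); trial indices must be dense and
    ordered within each participant.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    df = df[TRIAL_COLUMNS].copy()
    if np.any((df["p"] <= 0) | (df["p"] >= 1)):
        bad = int(np.flatnonzero((df["p"] <= 0) | (df["p"] >= 1))[0])
        raise ValueError(f"p outside (0, 1) at row {bad}")
    df["response"] = clamp_probability(df["response"].to_numpy(float))
    for pid, grp in df.groupby("participant_id"):
        idx = grp["trial_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, idx.size + 1)):
            raise ValueError(f"trial_index not dense/ordered for participant {pid}")
    return df
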