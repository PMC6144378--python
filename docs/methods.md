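# Methods

## Scales and conventions

All modelling is done in natural-log odds, `λ(p) = log(p/(1−p))`; the
stimulus of trial *n* is `S_n = λ(p_n)` and the response `R_n = λ(π(p_n))`.
Reported probabilities at or beyond the bounds are clamped into
`[0.005, 0.995]` — half of the 0.01 stimulus step inside each boundary —
before the log-odds transform, since a response bar allows exact 0 and
100% where log-odds are undefined. The 99-value stimulus support is built
as `i/100` from integers to avoid float accumulation.

## Stimulus distributions

The four conditions are discrete distributions over {0.01, …, 0.99}:
Uniform (1/99 everywhere); Extreme (3/99 on each value of both ends
[0.01, 0.10] and [0.90, 0.99], i.e. 30/99 of trials per end, and
(39/79)/99 on each middle value); Small (5/99 on each of [0.01, 0.10],
(49/89)/99 elsewhere); Large (mirror of Small). The expected absolute
log-odds distance between two consecutive i.i.d. draws is computed by
exact double enumeration over the 99×99 grid; it is invariant under mirror
reflection (so S and L coincide) and is smallest for U (1.910) and largest
for E (2.905). Empirical sequences drawn without replacement within blocks
run slightly higher (factor ≈ 99/98), which is visible when comparing to
trial-sequence averages.

## The synthetic experiment

A participant completes 693 trials in 7 blocks of 99; 16 participants per
condition. Two sequencing modes are provided because the original design
is ambiguous on this point: `iid` draws every trial independently from the
condition distribution, `block-balanced` (default) draws each block's
composition as one multinomial and shuffles within the block. The total
dot count of a display (200–800 in steps of 100) is carried as a covariate
but never used — it documents the display design, nothing downstream
depends on it.

Observers generate responses sequentially from one of the six model
equations. The adaptation level starts at `L_1 = 0` (log-odds of 0.5, a
neutral start appropriate for symmetric environments) and follows the
delta rule `L_n = L_{n−1} + κ(S_{n−1} − L_{n−1})`. Lag terms feed on
*realized* previous responses — noise included, after clamping — because
the sequential regressions operate on observed responses; on trials
n ≤ m the unavailable lags are simply dropped (fitting later discards
those trials anyway). One lag (m = 1) is the default everywhere: in data
of this kind only the one-trial-back coefficient is reliably nonzero.
Per-participant parameter spread is off by default (fixed cohort
parameters); an optional log-normal jitter on β0 and σ is available.

Default generator parameters for the end-to-end pipeline are calibrated
near the group medians reported for human cohorts in this paradigm:
slope β0 = 0.82 (U), 0.76 (E), 0.80 (S, L); crossover encoded as
`βC = (1−β0)·λ(p0)` with p0 = 0.59 (S) and 0.39 (L), 0.5 otherwise;
scope-of-influence ω = 1.296 / 2.209 / 1.989 / 1.890 (U/E/S/L);
β₋₁ = 0.05, κ = 0.05, σ = 0.3 everywhere.

## Theoretical predictors

*Adaptation-level theory*: `λ[π(p)] = γ(λ[p] − λ[L]) + (1−γ)λ[p0]` with
`λ[L] = η·Σ θ(p)λ(p)` computed by exact enumeration. With γ = 0.8,
p0 = 0.5, η = 0.2 it predicts the contrast ordering π_S > π_U > π_L with
π_E = π_U.

*Bayes-least-squares observer*: the percept y is Gaussian around λ(p) with
SD σ_noise on the log-odds scale; the prior over the 99 candidate stimuli
is the condition distribution; the estimate is the posterior mean over q
on the probability scale, and the reported curve marginalizes the percept
by trapezoidal quadrature on a log-odds grid. Working throughout on the
log-odds scale for y absorbs the change-of-variables factor that would
otherwise appear on the probability scale. The default grid spans
[−10, 10] with 1335 points: the quadrature must hold at least 1 − 1e-6 of
the percept mass for every requested stimulus (enforced with an explicit
error), which a [−9, 9] grid misses at σ = 1 for p = 0.01. Posterior rows
are normalized in log space so the σ → 0 limit is numerically exact.
Doubling the grid density changes the curve by < 1e-12.

## Distortion measures

LLO is fitted by ordinary least squares of R on S in log-odds — equivalent
to the Gaussian MLE, since every model's noise is Gaussian in log-odds and
the LLO equation is linear there. The crossover maps back as
`p0 = logistic(c/(1−γ))`; within 1e-6 of γ = 1 it is undefined and
reported as NaN. The smoothed deviation curve uses the Nadaraya–Watson
estimator with a Gaussian kernel and fixed bandwidth h = 0.03 (a fixed
value avoids artifacts from per-participant bandwidth selection).
Curvature (`∫|f|dp`) and elevation (`∫f dp`) are trapezoidal integrals
over the 0.01-step grid, where the choice of rule is immaterial at the
reported precision. Group variability is visualized by bootstrapping
participants (default 500 resamples of 16 with replacement).

## Sequential-effect maps

The global regression `R_n ~ S_n + R_{n−1..n−m} + 1` is pooled across
participants with lag structure never crossing a participant boundary, and
uses plain OLS. The local map runs, at every cell of a 25 × 25 grid over
[0.01, 0.99]² (a full 99 × 99 grid is available via the `grid` argument),
a weighted least-squares regression whose weight matrix carries the
*squared* two-dimensional Gaussian kernel (span σ_k = 0.1) on its
diagonal — exactly as the estimator is defined in this literature. Every
trial contributes to every cell (Gaussian weights never vanish); cells
whose Kish effective sample size `(Σw²)²/Σw⁴` falls below 5 are flagged
missing rather than extrapolated, and map correlations delete missing
cells pairwise. Model-predicted maps resimulate responses on the observed
stimulus sequences (default 20 simulations, averaged), since a single
simulation leaves visible Monte-Carlo texture in the map.

One property of this estimator matters for interpretation: under
trial-by-trial adaptation the omitted time-varying level induces a smooth,
stimulus-dependent bias field in the local β₋₁ map that is shared by *any*
adaptation-based simulation. Observed-vs-predicted map correlations on
synthetic cohorts are therefore uniformly high for all adaptation models,
and only the *ordering* — non-linear predictors correlating better than
linear ones, thanks to the diagonal ridge — is a meaningful signature.

## Model fitting and comparison

The likelihood of each family is Gaussian in log-odds around the model
mean, with lag terms using observed previous responses and the adaptation
level computed recursively from observed stimuli. Only trials with index
n ≥ 6 enter the likelihood, so lags up to five back always exist; the
recursion still consumes the full series. Because the mean is linear in
(β0, β₋ᵢ, βC) once κ and ω are fixed, those coefficients and σ are
profiled out in closed form and the numerical search runs only over the
one- or two-dimensional (κ, ω) space: bounded L-BFGS-B restarted from the
best points of a coarse deterministic grid plus random draws within the
declared bounds (κ ∈ [0, 1], ω ∈ [0.1, 10]; β0 ∈ (0, 2], β₋₁ ∈
[−0.5, 0.5], βC ∈ [−2, 2], σ ∈ (0.01, 3] bound the random starting
points). The grid pre-scan matters: the likelihood is sharply peaked in κ
(a learning rate of 0.05 versus 0.10 changes the adaptation trajectory
substantially), and purely random multistart can miss the basin. Default
20 restarts; the linear coefficients come from the closed-form profile and
are not themselves box-constrained.

AICc is implemented with the penalty `2k + 2k(k−1)/(N−k−1)`, the
convention of the analyses this pipeline mirrors. Note the standard
small-sample correction is
`2k(k+1)/(N−k−1)`; the discrepancy is deliberate (fidelity to the printed
formula) and a `correction="standard"` switch is provided. At N = 688 the
difference is ≈ 0.06–0.1 AICc units and never changes a comparison at
equal k. σ_noise is counted as a free parameter, giving k = 3/4/4/5/5/6
for LLO/AL/LLO-L/LLO-NL/AL-L/AL-NL at m = 1, and k is reported alongside
every AICc.

Group-level selection treats `−AICc/2` as the per-participant log model
evidence and runs the variational Dirichlet random-effects scheme:
posterior frequency parameters α, exceedance probabilities by Dirichlet
Monte-Carlo sampling (default 200,000 draws, seeded), and protection via
the Bayesian omnibus risk `BOR = 1/(1+exp(F1−F0))` comparing the
random-effects free energy against the equal-frequency null, with
`PXP = (1−BOR)·EP + BOR/K`.

## Efficient-coding analysis

Responses are pooled across all participants of a condition and binned
into 10 equal bins on [0, 1] (last bin right-closed); the KL divergence to
the uniform distribution uses natural log with empty bins contributing
zero. The U-mapping reference draws, for every stimulus of the target
condition, one response with replacement from the Uniform-condition
responses to the identical stimulus. Because only bin counts enter the
divergence, each simulation is realized as one multinomial draw per
distinct stimulus value over that stimulus's response-bin distribution —
distribution-identical to response-level resampling and far cheaper, which
is what makes 10⁶ simulations feasible if requested (default 10,000, at
which the reported quantiles are stable to ~1e-3). Target stimuli with no
Uniform-condition match fall back to the nearest available stimulus (ties
toward 0.5); the fallback can be disabled, in which case unmatched stimuli
raise.

## What the synthetic generator does and does not show

The generator reproduces the design (conditions, trial counts, response
scale) and the six candidate response processes, so it supports parameter
recovery, model recovery, estimator cross-checks and direction-of-effect
tests. It does not emulate perceptual numerosity noise from the dot
displays, lapses, motor error on the response bar, learning across blocks,
or individual differences beyond optional parameter jitter — so passing
tests certify the analysis chain, not the empirical claims about human
observers, whose raw data are not bundled here.

## Problem sizes used in the test suite

Expensive properties run at reduced but still informative scale chosen as
part of the suite's design: parameter recovery uses 20 independent
693-trial observers; model recovery uses 10 master seeds × 6 generating
families × 8 participants with all-six refits (the simple families sit
near the 90% recovery boundary at this cohort size — see the recovery
notes above); the map-correlation ordering uses one 16-participant cohort
with 20-simulation predicted maps; efficient-coding checks use 10,000
resamples. The full-scale run remains available through
`relfreq reproduce` and the configurable pipeline.

## Known limitations

* The local WLS β map is biased under adaptation (see above); it is a
  descriptive tool, not an unbiased estimator of the DoG kernel.
* The AICc correction defaults to the non-standard k−1 penalty described
  above.
* Exceedance probabilities use Dirichlet sampling rather than the exact
  integral; with the default 200,000 draws the Monte-Carlo SD is ≈ 0.001.
* `fit_model` profiles the linear coefficients without box constraints;
  in degenerate data (e.g. constant stimuli) the OLS step, not the bounds,
  determines the estimates.
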