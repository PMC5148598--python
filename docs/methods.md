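# Methods

## Model

The package fits the generalized Waring regression model: counts
`Y_i | x_i ~ UGWD(a_i, k, ρ)` with `μ_i = exp(x_i′β + offset_i)` and
`a_i = μ_i(ρ−1)/k`.  The UGWD is the beta-negative-binomial: mixing the
negative binomial's success probability with a Beta(ρ, k) (equivalently,
mixing a Poisson's rate with Gamma(a, scale v) and the scale v with a beta
prime) produces a proper count law for any a, k, ρ > 0, with mean
`a·k/(ρ−1)` (requires ρ > 1) and, for ρ > 2, variance

    μ + μ(k+1)/(ρ−2) + μ²(k+ρ−1)/(k(ρ−2))

whose three terms the package reports as randomness, liability and
proneness.  The pmf is symmetric in a and k; the regression breaks that
symmetry by tying a to the covariates and keeping k global.  The tail is a
power law of exponent ρ+1, so small fitted ρ is a diagnosis of genuinely
heavy tails rather than a numerical nuisance.

Assumptions: counts are conditionally independent given covariates; the
log link is correct; k and ρ are common to all observations (covariates
move only the mean).  Case weights multiply each observation's
log-likelihood contribution; the BIC sample size remains the row count.

## Estimation

`fit_gw` maximizes the weighted log-likelihood in three stages:

1. BFGS on the unconstrained parameterization `(β, k0, ρ0)`,
   `k = e^{k0}`, `ρ = 1 + e^{ρ0}` (the transform guarantees ρ > 1);
2. Nelder–Mead on the same surface;
3. L-BFGS-B on the natural scale `(β, k, ρ)` with bounds `k ≥ 1e−5`,
   `ρ ≥ 1 + 1e−5`, started from the better of stages 1–2.  Standard
   errors come from the inverse numerical Hessian at this optimum.

β starts at the Poisson log-link fit (statsmodels GLM); `kstart = 1` and
`rostart = 2` by default.  Selecting a single unconstrained method reports
SEs on the `(β, k0, ρ0)` scale only, with k and ρ as point estimates — no
delta-method back-transform is attempted.  Gradients everywhere are scaled
central differences (step `1e−6·max(1, |θ_j|)`); scipy's one-sided default
stalls the L-BFGS-B line search near the optimum.  A stalled line search at
an interior point with gradient below 1e−2 in infinity norm is treated as
convergence.  Tolerances: gradient 1e−6, 500 iterations per stage
(Nelder–Mead: 200·dim), overridable via `control`.  Invalid parameter
points return a large finite penalty to the optimizer rather than raising;
hard guards (`1e−8 < k < 1e8`, `1 < ρ < 1e8`, `a ≤ 1e10`, linear predictor
≤ 500) exclude corners where no fit can plausibly lie and where any
floating-point evaluation of the pmf would be meaningless.

Non-convergence never raises from `fit_gw`: the result carries the stage-3
status code and a warning, so callers (stepwise search, envelopes) can flag
rather than crash.

## Numerical evaluation of the pmf

All pmf work is in log space.  The naive sum of log-gammas loses ~2e−12
relative accuracy by y ≈ 1000 (four terms of magnitude y·ln y each carry
~1 ulp of absolute error), so the implementation groups the expression into
paired differences `lnΓ(x+d) − lnΓ(x)` and evaluates each pair, when
min(x, x+d) ≥ 32, by a Stirling-series expansion of the *difference* —
every intermediate then lives on the scale of the result.  This keeps the
pmf accurate to ~1e−14 relative over the tested range and overflow-free for
parameters and counts up to at least 1e4.  Truncated normalization sums in
tests accumulate until the mass exceeds 0.999 over explicit grids.

Random generation uses the exact two-stage route (p ~ Beta(ρ, k), then
Y ~ NB(a, p)); the three-stage Poisson–Gamma–beta-prime hierarchy is kept
in `simulate.sample_hierarchy` as an independent cross-check, with the
beta-prime convention (v = G_k/G_ρ) pinned by a distributional test against
the pmf rather than by any naming convention.

## Prediction, partition, tests, selection

Prediction is `exp(x′β̂ + offset)` with strict refusal of unseen
categorical levels.  The partition is evaluated per covariate pattern from
(μ̂, k̂, ρ̂); it raises when ρ̂ ≤ 2 (infinite variance) and warns when
ρ̂ ≤ 2.001, where the components are numerically explosive.  The LRT
requires nested column sets and identical rows, offsets and weights.
Stepwise selection refits one term per move, keeps the smaller model on
criterion ties within 1e−8, evaluates additions and deletions every round
under `direction="both"`, and records every candidate in a trace; the
selected model is refit once with a Hessian so its summary has SEs.

## Residuals and envelopes

Deviance contributions are `d_i = 2[ln f(y_i | μ=y_i) − ln f(y_i | μ=μ̂_i)]`
holding (k̂, ρ̂) fixed, with the y=0 saturated term taken as the μ → 0⁺
limit (pmf → 1).  For this distribution μ = y is *not* the exact
single-observation maximizer of the likelihood in μ, so d_i can be slightly
negative (order 0.03–0.15) when μ̂_i lies between y_i and the true
maximizer; such values are clamped to 0 before the signed square root
`sign(y−μ̂)·√d_i` used for plotting.  Pearson residuals divide by the
square root of the three-component total variance and therefore require
ρ̂ > 2.

The envelope simulates `rep` response vectors from the fitted model at the
observed covariates, *refits* each one, and takes per-rank min/max of the
sorted residuals.  Min/max (rather than percentiles) makes the escape
probability of the largest absolute residual exactly 1/(rep+1) under a
correct model — 1/20 at the default rep = 19.  Replicate refits are
warm-started: a single bounded L-BFGS-B stage from the original estimates,
no Hessian.  The full three-stage strategy exists to survive cold starts;
started at the truth-adjacent original estimates the bounded stage reaches
the same optimum at a fraction of the cost, and the refit still injects the
estimation noise the envelope is meant to reflect.  Per-replicate seeds are
spawned from the user seed by index, so results are bit-identical across
serial/parallel execution and nested across increasing rep.  A failed
replicate is resimulated with the next derived seed, three attempts, then a
hard error.  Signed residuals are plotted against Blom-scored normal order
statistics.

## Synthetic data

`generate_dataset` draws covariates from declarative column specs, builds
`μ_i` through the same link used in fitting, and draws counts by the exact
sampler — so estimator calibration tests are against the model's own
data-generating process.  The `badhealth_like` fixture emulates a health
survey's shape (binary indicator with prevalence 0.11, age uniform on
[20, 60] with a zero true coefficient, β = (0.66, 1.16, 0), k = 1.57,
ρ = 6.85 — magnitudes typical of published doctor-visit analyses but
arbitrary defaults, not estimates of any real dataset).  `goals_like`
emulates season scoring counts: a 3-level position with defender as
reference, matches played uniform on 1–38 as log-offset exposure,
β = (−3.4, 1.8, 0.9), k = 1.1, ρ = 3.5.  What the generator does *not*
emulate: covariate measurement error, within-cluster dependence (players
within teams, repeat visits within patients), zero-inflation, or any
misspecification of the link — passing recovery tests therefore show
correctness of the estimator under the model, not robustness of the model
on real data.

## Test problem sizes

The suite favours sizes that exercise the asymptotics without waste:
recovery uses one n = 5000 draw plus 100 replicates at n = 2000; envelope
coverage uses 100 outer replicates at n = 300 with rep = 19; the LRT
type-I-error check runs 120 null simulations at n = 400 against a generous
99% binomial band.  These are the package's calibration choices; larger
runs tighten the Monte-Carlo bands but change no conclusion.

## Known limitations

- Additive terms only: no interactions or transformations in the term
  language (pre-compute columns instead).
- No quantile function or distribution-level (non-regression) fitting
  beyond an intercept-only model.
- SEs rely on the numerical Hessian; a singular Hessian flags SEs
  unavailable rather than regularizing.
- Very heavy-tailed fits (ρ̂ ≤ 2) forfeit Pearson residuals and the
  variance partition by construction — this is a property of the model,
  not of the implementation.
- Stepwise candidates must use the same rows as the start fit; rows with
  missing values in scope terms raise rather than silently changing the
  comparison set.
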