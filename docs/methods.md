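# Methods

## The task and its state machines

A CCT round is parameterized by `(g, l, m, N)`: gain per gain card, penalty
of the single revealed loss card, number of loss cards, and deck size
(default 32; the 4×8 grid of the on-screen task is cosmetic, so only the
reveal order is modelled). A round's score is `g × (gain cards revealed) −
l × 1{loss revealed}`; at most one loss card can ever be revealed because
the first loss ends the round. Sessions total round scores and pay a bonus
of $1 per 100 points, floored at zero.

The four versions are implemented as one engine with four commitment/
feedback protocols. Cold and Warm commit a count `n` up front (Cold gets no
per-round feedback, Warm sees the committed cards revealed); Toasty commits
an initial batch and then repeatedly decides continue-with-another-batch or
stop; Hot decides card by card. Warm and Hot are exact limits of Toasty
(one batch; all batches of size one), and the test suite checks these as
transcript-level identities. A round is **right-censored** exactly when a
loss ends it before the policy signalled stop — possible only in Toasty and
Hot.

Two engine conventions are deliberate choices:

- `cards_revealed` counts the terminal loss card (it was flipped); an
  exclusive count is available as `gains_revealed`. The literature does not
  pin this convention, so both are exposed.
- The intended-count lower bound recorded for a censored round defaults to
  the total **committed** through the batch containing the loss (`censor_at
  = "committed"`), the sharpest valid bound: a Toasty player who committed
  five cards and lost on the third still demonstrably wanted five. Under
  `censor_at = "revealed"` the bound is the flip count; in Hot the two
  coincide.

Cold rounds use a hidden random layout so scores are computable even though
the player never sees per-round feedback.

## Exact round analysis

With `m` loss cards placed uniformly among `N` positions, the first-loss
position is the first-failure order statistic of sampling without
replacement:

    P(no loss in k draws) = C(N−m, k) / C(N, k)
    P(first loss at j)    = m/(N−j+1) × Π_{i<j−1} (N−m−i)/(N−i)

All probabilities are `fractions.Fraction` ratios, so normalization is an
identity rather than a tolerance, and the argmax set of

    EV(k) = g·k·P(no loss in k) + Σ_{j≤k} (g(j−1) − l)·P(first loss at j)

is exact. This matters because the standard parameter grid contains exact
ties: {6, 7} at (10, 250, 1) and (30, 750, 1), and {4, 5} at (30, 250, 3).
The canonical published optimum table resolves these inconsistently (7, 6,
4), so `optimal_reveal` defaults to returning the full argmax set and
offers `smallest`, `largest`, and a `published` selector that reproduces
the printed table. Under uniform placement, fixed-count policies suffice
for EV maximization, so no dynamic programming over information states is
needed (a deliberate non-goal, along with risk-sensitive objectives).

`expected_bonus` reports three readings of "expected bonus" for a
deterministic count policy — raw ΣEV/100, an exact per-round floor
Σ E[max(score,0)]/100, and a Monte-Carlo session-total floor
E[max(total,0)]/100 — because the historically quoted optimal-play bonus
is not reproducible from ΣEV under the stated total-score rule; the modes
make the candidate interpretations computable without asserting one.

## Agent populations

Agents generate intended counts from the same linear mixed structure the
analysis model estimates: `y* = grand_mean + Σ fixed effects + b_i0 +
z'b_i + ε`, with `b_i ~ MVN(0, Σ)` over the intercept and sum-to-zero
coded within-subject slope columns, and the emitted count `clip(round(y*),
0, N)`. Rounding and boundary clamping are intentionally part of any
recovery-error budget, mirroring the field's practice of fitting a Gaussian
model to an integer response.

Two shipped populations:

- `study_scale_population` — grand mean 10.69 cards, residual sd 5.17
  (σ² ≈ 26.7), intercept sd 6.85 (τ00 ≈ 46.9), and version/incentive/
  parameter effects at published-study scale. It makes synthetic data
  *resemble* the human study's scale without claiming to replicate its
  participants.
- `recovery_population` — the same fixed-effect scale but intercept sd 2.0,
  slope sds 0.3–0.4, residual sd 2.5, grand mean 11.0. The tighter scales
  keep cell means well away from the 0 and 32 boundaries so clamping and
  rounding contribute negligibly, which is what a parameter-recovery study
  needs to interpret coverage cleanly.

Toasty continuation is a *descriptive* batching device, not a cognitive
model: a round is a single batch with probability `p_single_request`
(default 0.77, the observed single-request share in honest-placement data);
otherwise the first batch commits `initial_fraction` (0.7) of the target
and later batches shrink by `continuation_decay` (0.5, matching the roughly
halving per-request counts seen empirically), never below one card. Note
that with random placement, a loss inside the first batch truncates a
multi-batch plan to one observed request, so the *observed* single-request
share exceeds the plan-level parameter; on uncensored rounds the two
coincide, and tests measure it there.

## The censored multilevel model

The analysis model is

    y*_ij = x_ij'β + z_ij'b_i + ε_ij,  ε ~ N(0, σ²),  b_i ~ MVN(0, Σ)

with the observed count equal to `y*` for uncensored rounds and a lower
bound for censored ones (likelihood contribution = the normal upper-tail
probability). All categorical predictors are sum-to-zero coded with the
first level as reference, so the intercept is the grand mean, each
coefficient a deviation from it, and the reference level's effect is minus
the sum of the explicit ones. The default formula has main effects for
version, incentive, gain, loss, number of loss cards, and repetition
(3-level categorical), version × each-other-term interactions, and random
intercepts plus slopes for the within-subject main effects (gain, loss,
loss cards, repetition) with all correlations; interaction random slopes
are excluded because they are not identified for between-subject factors.
Factors with a single observed level are dropped automatically, so the same
builder serves one-version datasets.

### Inference

Sampling is by a fully conjugate data-augmentation Gibbs sampler:

1. censored responses are imputed from `N(μ, σ²)` truncated to
   `[y_obs, ∞)` (inverse-CDF sampling in the stable upper-tail
   parameterization);
2. `β` and the `b_i` have conjugate Gaussian updates (the per-participant
   updates are batched: the `Z_j'Z_j` blocks are constant across sweeps);
3. `σ` and `Σ` use Huang–Wand parameter expansion: inverse-gamma /
   inverse-Wishart conditionals whose marginals are half-t(3, 10) on σ,
   half-t(2, 10) on each random-effect sd, and uniform on each correlation.
   These match the spirit of conventional weakly-informative defaults while
   staying exactly conjugate;
4. additional exact Gibbs steps resample the shared *location* of each
   (fixed column, random column) pair in which the fixed column equals the
   random column times a participant-constant weight — the intercept,
   between-subject factors, and between×within interactions all have this
   form. Without these translation moves the intercept-like coefficients
   random-walk against the group means of the random effects (bulk ESS of
   tens); with them, ESS improves by an order of magnitude.

Coefficient priors are `N(0, 10²)` on the response (cards) scale. Defaults
mirror the field's reporting convention of 4 chains × 8,000 iterations
(4,000 warmup); the test profile uses 2 × 1,500 (750 warmup), which the
relocation moves make adequate for fixed effects. Convergence is
summarized by split-R-hat and bulk/tail ESS (arviz) for every reported
parameter; any R-hat above 1.05 attaches an explicit do-not-trust warning
to the result. Intervals are central 95% quantiles (the HDI/quantile choice
is unstated in the literature this mirrors; quantiles are used and
labelled). On uncensored data the sampler is validated against REML mixed-
model estimates (statsmodels MixedLM) as an independent oracle; agreement
is within a few hundredths of a posterior sd.

### Derived quantities

- **EMMs**: population-level cell predictions (random effects at zero)
  averaged over unlisted factors with equal cell weights — exact for the
  balanced factorial designs generated here.
- **ICC**: τ00/(τ00 + σ²) from an intercept-plus-random-intercept null
  model, averaged over the posterior.
- **R²**: variance-partition form; marginal = Var(x'β) / (Var(x'β) +
  E[z'Σz] + σ²), conditional adds the random-effect term to the numerator.
  Var(x'β) uses the empirical covariance of the design rows and E[z'Σz] the
  empirical second moment of the random covariates, so both are computable
  from stored fit metadata.
- **Estimator comparison**: the raw mean, the loss-rounds-excluded mean,
  and the censored-model grand mean of the same data. On censored
  simulations the raw mean is strongly attenuated, the exclusion estimator
  less so but still biased low (it selects against high-intent rounds),
  and the censored model recovers the generating mean.

## Problem sizes and numerical checks

The shipped test suite uses sizes chosen to make each check statistically
meaningful: the engine Monte Carlo compares mean simulated scores against
exact EV at 20,000 draws per (combination, k) cell with a 3-standard-error
criterion; version-limit equivalences replay 1,000 random layouts; the
recovery study runs 20 replicates of 100 agents × 24 Hot rounds (about half
the rounds censored) with the test sampler profile, requiring ≥ 17/20
interval coverage per generating fixed effect and ≥ 17/20 wins of the
censored-model grand mean over the raw mean. First-loss normalization is
checked as an exact rational identity over deck sizes up to 64.

## What the generator does and does not emulate

Simulated data reproduce the generative skeleton of real sessions —
between-participant heterogeneity, parameter sensitivity, hypergeometric
censoring, batched Toasty feedback — but not learning across rounds (the
repetition effect is injected as a fixed effect, not acquired), sequential
dependence on the previous round's outcome, reaction times, or any
cognitive-process account (prospect theory, drift diffusion are
non-goals). Passing recovery tests therefore shows the estimation machinery
is correct under the stated model, not that the model captures every
feature of human play.

## Known limitations

- The latent-Gaussian treatment of an integer, bounded response is the
  field's convention, not a generative truth; at study-scale variances the
  0/32 boundaries induce mild bias that the recovery population avoids by
  design.
- Censored rounds bound intent at an integer flip/commit count while the
  latent variable is continuous; the half-unit discrepancy from rounding is
  absorbed into the error budget.
- Slope standard deviations near zero mix slowly (a known funnel-like
  behavior of Gibbs samplers in variance components); fixed effects and
  variance totals are unaffected, and R-hat flags the affected parameters
  honestly.
- `compare_estimators`' null model ignores covariates, so its grand mean
  carries a small upward shift from unmodelled cell heterogeneity under
  heavy censoring; it is still far closer to the truth than the raw mean,
  which is the comparison it exists to make.
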