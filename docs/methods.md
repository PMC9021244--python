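# Methods

## The task

An agent makes 20 choices per block between a *sure* option that always
pays 10 cents and a *risky* option that pays 20 or 0 cents with an
unknown win probability. A session has 10 blocks; each introduces a
fresh risky option, so beliefs re-initialize at block boundaries. The
win probability is 0.3 in four blocks (risky EV 6 cents), 0.7 in four
(EV 14) and 0.5 in two (EV 10), and both the first and second half of a
session contain one neutral, two disadvantageous and two advantageous
blocks in random order.

Outcomes follow a predetermined *tape* per block: every window of ten
successive risky choices contains exactly `10·p` wins in uniformly
random order. The tape advances only on risky choices, so an agent
making fewer than 20 risky choices consumes a prefix. Tapes are seeded
per (master seed, block index), making whole cohorts reproducible
block-by-block; identical master seeds give byte-identical CSVs.

## Strategy models

All learning models estimate only the risky option's value (the sure
option's 10-cent value is known and never updated) and feed the value
difference into a logistic (softmax) policy

    P(risky) = 1 / (1 + exp(−β (v_risky − 10))),

with inverse temperature β in inverse cents (values live on the cents
scale). β = 0 is indifference; larger β means choices track values more
deterministically. The difference form is equivalent, for two options,
to a softmax over independent option values up to a rescaling of β.

**Reinforcement learning (RL).** A point value updated by a delta rule
after each risky outcome, `Q ← Q + α (u(o) − Q)`. Variants: single rate
α (m1a); separate win/no-win rates α₊, α₋ (m1b); single rate with
nonlinear utility (m1c). The initial value Q₁ ∈ (0, 20) is free in all
models.

**Bayesian ideal observer (BIO).** A Beta(a, b) belief over the win
probability; a win adds π₊ to a, a no-win adds π₋ to b. The value is
`u(20)·a/(a+b)`. The implied per-trial learning rate is
`π/(a + b + π)`, which decays as pseudo-counts accumulate — the
optimal regime when contingencies are stable within a block. Variants:
single update rate π (m2a); separate rates (m2b); single rate with
nonlinear utility (m2c); single rate with an uncertainty bonus/penalty
`φ · 20 · sd(p)` added to the value, `sd(p)` the Beta posterior sd
(m2d). Initialization is Beta(a₁, c₁ − a₁) with fixed concentration
c₁ = 2 and free a₁, reported as Q₁ = 20·a₁/c₁ — one free initial-value
parameter, like the RL family. The published sources state the
direction of these mechanisms but not the closed forms; the
parameterizations here (u, the φ·sd bonus, the Beta(a₁, 2−a₁)
initialization) are this package's documented reconstructions.

**Utility.** `u(o) = 10 · (o/10)^κ`, so u(0) = 0 and u(10) = 10 for
every κ: the sure payoff is the unit of account. κ > 1 makes the
20-cent win worth more than twice the sure payoff (risk seeking),
κ < 1 the opposite.

**Gambler's-fallacy (GF) models.** The two winning learners with
sign-flipped rates: gf_rl is m1c with α ∈ (−1, 0); gf_bio is m2b with
π₊, π₋ ∈ (−5, 0). A win *lowers* the risky option's value — the belief
that a frequent outcome has become less likely. Negative pseudo-count
increments are floored at 0.001 to keep the Beta proper. GF-RL values
grow geometrically (|1 − α| > 1), so all likelihood code works on the
log scale of the logistic.

**Epsilon-risky.** P(risky) = ε on every trial, ignoring outcomes;
captures guessing and outcome-insensitive risk attitudes.

Parameter boxes: α ∈ (0,1) (GF: (−1,0)), π ∈ (0,5) (GF: (−5,0)),
κ ∈ (0,3), φ ∈ (−5,5), β ∈ (0,10), Q₁ ∈ (0,20), a₁ ∈ (0,2),
ε ∈ (0,1). The boxes comfortably contain the group-level estimates this
task family produces; they are reconstructions, not published values.

## Hierarchical estimation

For one age group and one model, each subject s has an unconstrained
score z[s,p] ~ Normal(M[p], S[p]) per parameter p, mapped onto the
parameter's box by the scaled probit `lo + (hi − lo)·Φ(z)`. Priors
(reconstructed; the originals are not published): M ~ Normal(0, 1),
S ~ half-Normal(1) on the unconstrained scale. Group-level means are
reported after box mapping, so they live on interpretable scales.
Groups are fit separately, not jointly with covariates.

Sampling is an adaptive Metropolis-within-Gibbs scheme compiled with
numba, exploiting the two-level structure:

* subject blocks are conditionally independent given (M, S) and are
  updated by joint random-walk proposals whose covariance is each
  subject's running empirical posterior covariance (subject parameters
  are strongly correlated a posteriori — e.g. learning rate against
  inverse temperature);
* M has a conjugate Normal Gibbs update; S a log-scale Metropolis step;
* two parameter-expansion moves cut through the hierarchical funnel
  and along group-level ridges: a joint rescale
  (z, S) → (M + c(z − M), cS) and a joint translation
  (z, M) → (z + d, M + d) with d drawn from the running covariance of
  M.

All proposal scales adapt only during warmup. Defaults: 4 chains,
2 000 warmup + 2 500 kept draws each. Convergence is gated on split
R-hat < 1.05 and bulk ESS > 400 for every group-level quantity
(arviz); a failed gate flags the result rather than hiding it. The
asymmetric ideal observer is the slowest mixer — its two update rates
and β form a near-scale-invariant ridge — and can need several-fold
longer chains to pass the ESS gate; medians and HDIs are stable well
before that.

### Model comparison

DIC = D̄ + pD with D̄ the posterior mean deviance. The penalty is the
variance-based estimator pD = var(D)/2 rather than the plug-in
D̄ − D(θ̂): misspecified models here (e.g. the basic RL model fit to
epsilon-generated data) concentrate on curved ridges where the
posterior-mean plug-in point falls off the ridge, driving the plug-in
pD strongly negative and spuriously *rewarding* the wrong model. The
plug-in quantities are still recorded (`d_hat`, `p_d_plugin`) and
`compute_dic` implements the plug-in arithmetic. ΔDIC tables subtract
each DIC from the worst model's, so larger is better and the worst
model sits at 0.

## Latent-mixture strategy classification

Five components in fixed order (gf_rl, gf_bio, m1c, m2b, eps) with a
uniform categorical prior on the per-subject indicator. Inside each
component, subject parameters carry fixed weakly-informative priors —
uniform over the parameter box, which is exactly a standard-normal
prior on the unconstrained score — instead of a per-component
hierarchy. This is a deliberate design: at these sample sizes a fully
hierarchical mixture invites label switching and empty-component
degeneracy. With subject-level priors the subjects decouple, and the
indicator posterior is computed exactly (up to Monte-Carlo error) by
marginalizing parameters with plain prior Monte Carlo: 4 000 uniform
draws per component per subject, log-sum-exp. Ties in the modal
assignment break by the fixed component order. Removing components
(e.g. the GF pair) leaves a proper posterior over the remainder; GF
subjects are then absorbed by the epsilon or low-β learner components.

## Behavioral statistics

**Win-switch exclusion.** Within-block consecutive pairs only (a new
risky option appears each block, so cross-block switching is
meaningless). Denominator: risky-win trials with a successor trial;
numerator: those followed by a sure choice. Rate > 0.30 excludes; a
subject with no eligible win trials has an undefined rate and is never
excluded.

**Choice accuracy.** Share of highest-EV choices (sure in
disadvantageous, risky in advantageous blocks); neutral blocks are
excluded from numerator and denominator.

**Regression.** Multilevel logistic regression of the single-trial
choice (risky = 1) on block type (−1/0/+1), trial (orthogonal linear
and quadratic polynomials over 1..20 — orthogonal coding decorrelates
the trend terms), age group (linear (−1,0,1) and quadratic (1,−2,1)
contrasts) and their full factorial (18 terms with intercept), plus a
single random intercept per subject. Fitting delegates to statsmodels'
variational Bayesian mixed GLM; reported z statistics are posterior
mean / posterior sd with two-sided Normal p values, and the
random-intercept sd is exp of the variance-component posterior mean. A
fit failure falls back to MAP estimation and flags non-convergence.

**Chi-square.** Pearson Σ(O−E)²/E without continuity correction
(validated against both published statistics, 4.5 and 4.0).

## Synthetic cohorts

The generator mirrors the assumed hierarchy: per group and strategy,
unconstrained scores ~ Normal(loc, sd), probit-mapped. The default
scenario has the study's group sizes (31/39/35) and encodes the
qualitative group ordering this task family reports: early adolescents
with the highest constant learning rate (α ≈ 0.35) and lowest β (≈ 1),
mid-late adolescents lower α (≈ 0.15), adults mostly asymmetric ideal
observers with β ≈ 2, adolescent κ > 1, optimistic initial values
(Q₁ ≈ 12). Learner prevalence follows the published mixture counts
(18/31, 25/39, 28/35), split between m1c and m2b per the published
RL-vs-BIO gradient, with the remainder across gf_rl, gf_bio and eps.
The numeric parameter values are scenario choices — the sources print
no group-level numerals — and are configurable per group (YAML).

What the generator does *not* emulate: reaction times, attention
lapses, within-session fatigue, carry-over between blocks, and any
idiosyncratic human strategies outside the five modeled ones. Passing
tests therefore demonstrate that the pipeline recovers what it assumes,
not that real adolescents behave like the generator.

## Numerical choices and problem sizes

* Likelihoods run on the log scale (stable log-logistic); choice
  probabilities inside the kernel are never materialized.
* Beta pseudo-counts floored at 0.001; box mapping via Φ keeps every
  parameter strictly inside its box.
* One numba kernel is the single source of truth for the likelihood:
  `log_likelihood`, the hierarchical sampler, and the mixture all call
  it, and a pure-Python unroll of the single-step operations checks it
  to 1e-10 in the tests.
* Recovery harnesses use scaled-down designs chosen to make the checks
  sharp but cheap: parameter recovery with 10 cohorts × 30 subjects ×
  200 trials and 2 × (900 + 500) MCMC sweeps; model recovery with 10
  replicates × 3 generators × 20 subjects and 2 × (800 + 800) sweeps.
  Model-recovery DIC margins for the epsilon generator are a few units
  (the learner models can mimic a constant-rate chooser), so shorter
  chains than these leave the comparison dominated by Monte-Carlo
  noise.

## Known limitations

* Priors, transforms, exact utility/bonus forms and the mixture's
  internal structure are principled reconstructions; absolute DIC
  values are therefore not comparable to any published numbers — only
  orderings and recovery behavior are meaningful, and that is all the
  tests assert.
* The variational regression gives approximate posterior sds; its z
  statistics are Wald-type, not likelihood-ratio.
* The epsilon component of the mixture and the basic RL model are
  near-indistinguishable for subjects whose behavior is a constant
  risky rate; classification of such subjects is genuinely uncertain
  and the posterior probabilities say so.
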