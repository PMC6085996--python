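# Methods

This package implements, end to end, the computational apparatus for a
spatial two-step decision task for rats: the task process itself, the
reinforcement-learning agents used to model choice on it, Bayesian fitting
and model comparison of those agents, trajectory-derived measures of
deliberation and procedural automation, and the statistical battery used
to analyze them.  Everything runs on synthetic data with known ground
truth; no animal data are required or included.

## The task process

A trial (lap) is two sequential binary choices.  The first-stage choice
(state C1, options A/B) leads to one of two second-stage contexts: A
commonly leads to C2 and rarely to C3 (probabilities `p_common` = 0.8 and
0.2), reversed for B.  Each second-stage choice ends at one of four end
states (C, D, E, F), each carrying a delay-to-food cost in seconds.
Delays are initialized uniformly on [1, 30] s and evolve once per lap as a
Gaussian random walk with SD 1 s/lap.  Reward is modelled as
`max_delay − delay` (so 0–29 value units); the first stage delivers no
reward.  Sessions are lap-count based, 74 laps by default.

The walk must stay inside [1, 30] s.  Whether the original apparatus
clipped or reflected at the bounds is not observable from the numbers we
target; we clip by default (consistent with a hard ceiling on the
programmed delay) and expose reflection as `TaskConfig(boundary="reflect")`.

## Agents

Three valuation algorithms share one Q table over states {C1, C2, C3} ×
actions {left, right}; a terminal post-reward state has value fixed at 0.

* **Model-free**: SARSA(λ).  The stage-1 value is updated twice per
  trial — a delta-rule step with learning rate α₁ toward
  `r₁ + Q(s₂, a₂)` with r₁ = 0, and an end-of-trial eligibility-trace
  step `α₁ λ δ₂` driven by the stage-2 prediction error.  Stage-2 values
  use the delta rule with α₂ against the terminal value 0.
* **Model-based**: stage-2 values learned exactly as above; stage-1
  action values computed *at decision time* as the transition-probability-
  weighted maximum of the stage-2 values.  Transition probabilities are
  fixed constants (0.8/0.2), not learned — the subjects these models
  describe were extensively pretrained.
* **Constant-weight hybrid**: stage-1 values `w·Q_MB + (1−w)·Q_MF` with
  both components running simultaneously and sharing all parameters.
  `w = 1` reduces exactly to the model-based agent and `w = 0` to the
  model-free one (an invariant the tests enforce at machine precision).

Choices follow a softmax `P(a) ∝ exp(β_i [Q(s,a) + p·rep(a)])` with
stage-specific inverse temperatures β₁, β₂ and a perseveration weight p;
`rep(a) = 1` iff `a` was the same-stage action on the previous lap
(defined 0 for both actions on a session's first lap).  At stage 2 the
previous left/right action is compared regardless of which context was
visited; a context-specific comparison is available as a flag
(`stage2_rep_context_specific`), since either reading of "the same action
at that stage" is defensible.

Q values are initialized at the mean reward, read as
`max_delay − E[initial delay]` = 30 − 15.5 = 14.5 with defaults; this is
configurable because "mean reward" admits other expectations.

## Likelihood, priors, and sampling

The dataset log likelihood sums `log P(observed action | state)` over
sessions, trials and both stages, with the Q table reset at every session
start and parameters pooled across subjects.  The production
implementation is vectorized across sessions (one Python loop over lap
index); the test suite checks it to 1e-12 against a naive per-trial
walker on random datasets.

Priors: Beta(1.2, 1.2) on α₁, α₂, λ, w; Exponential(rate 0.5) on β₁, β₂;
Normal(0, 10) on p.  Sampling is an adaptive random-walk Metropolis on
unconstrained transforms (logit for unit-interval parameters, log for the
β's): during warm-up the scalar step size follows a Robbins–Monro
recursion toward a 0.3 acceptance rate and the proposal covariance is
re-estimated from the recent history at the 40% and 70% warm-up marks;
both are frozen for the sampling phase.  Chains initialize from moderate
boxes on the unconstrained scale rather than prior draws — an
Exponential(0.5) draw of β ≈ 8 puts a chain on a likelihood cliff that
short warm-ups cannot escape.  We chose this sampler because the target
is at most 7-dimensional and it keeps the package dependency-light; the
tests cross-check it against an affine-invariant ensemble sampler on the
identical posterior.  Convergence is summarized by split-R̂ (< 1.01) and
a Geyer-pairs bulk ESS (> 400); failures warn and set a flag, they do not
raise.  Desk-scale defaults are 4 chains × 2,000 iterations (1,000
warm-up), overridable to larger runs.

MAP estimation maximizes the constrained-scale log posterior in
unconstrained coordinates (L-BFGS restarts plus a Nelder–Mead polish).
DIC is `D(θ̄) + 2·p_D` with `p_D = D̄ − D(θ̄)` and `D = −2 log p(data|θ)`;
θ̄ is averaged on the unconstrained scale by default (guaranteeing θ̄
stays in support) with the constrained scale available.  DIC differences
above 7 are annotated as "considerably less support".

## Deliberation and automation metrics

**LogIdPhi** quantifies vicarious trial and error (VTE) for one pass
through a choice-point zone: the natural log of the integrated absolute
angular velocity of the head between zone entry and exit.  Heading is
computed from head positions after Gaussian smoothing (σ = 2 samples, a
jitter-taming choice the source measurements leave open) and unwrapped so
a continuous 180° sweep contributes 180°.  Angles are in degrees by
default: typical passes then log at ~log(40–75), matching the intercepts
reported for this class of measurement, whereas radians would sit ~4 log
units lower.  A zero-sweep pass is floored at ε = 10⁻³ degrees before the
log.  Passes with a tracking gap inside the zone (> 5× the median
sampling interval) are excluded with a recorded reason, mirroring the
lag-based exclusions such recordings require.  Multiple zone crossings in
a lap are resolved as first entry to last exit.

The **VTE threshold** is fit to the pooled LogIdPhi distribution as the
equal-responsibility crossing of a two-component Gaussian mixture.  No
published numeric threshold exists for this measurement, so the
mixture-based construction is this package's documented stand-in; fits
whose components are not genuinely bimodal (Ashman's D < 2) warn and fall
back to the range midpoint.  Classification is strict (`value >
threshold`), so a value exactly at the threshold is non-VTE.

**Path stereotypy** is the inverse of the mean distance between a lap's
path and all other same-session paths of the same type (LL/LR/RL/RR),
each path resampled to 100 points uniform in normalized lap time.
Distances are floored at 10⁻⁶ length units before inversion.  A lap that
is the only one of its type in its session is excluded (no comparison
set).

**Choice repeats** count consecutive laps on which both the first- and
second-stage choices match the previous lap (0 on the first lap or any
break).

## Statistics

* Stay-probability tables aggregate the repeat/switch of the first-stage
  choice by the *previous* lap's delay (2-s bins over [1, 30]) and
  transition type; model-free agents show stay probability falling with
  previous delay after common transitions, model-based agents show the
  reversed pattern after rare transitions.
* Per-session Spearman correlations (average-rank ties) feed a two-sided
  Wilcoxon signed-rank test of the per-session ρ's against zero.
* The exact signed-rank test enumerates the full 2ⁿ sign-assignment null
  for n ≤ 25 (ranks doubled so tie-averaged ranks stay integral; dynamic
  programming over the rank-sum distribution) and switches to a tie- and
  continuity-corrected normal approximation beyond.  For 7 same-sign
  differences the exact two-sided p is 2/2⁷ = 0.0156.
* Lap-wise comparisons test each of laps 1–50 against pooled laps ≥ 51
  (Wilcoxon rank sum), Bonferroni corrected over the tests performed.
* The linear mixed models are Gaussian with random intercepts for rat and
  for session nested within rat (sessions belong to one rat, so nesting
  reflects the design), fit by maximum likelihood — not REML — so fixed
  effects are comparable across specifications.  Fixed-effect degrees of
  freedom use the residual `n − rank` convention, which reproduces the
  very large DFs such per-lap models report.  Variance-component CIs are
  log-scale Wald intervals from the ML information matrix (the residual
  variance uses a χ² approximation, as it is profiled out); log-scale
  intervals match the asymmetric intervals standard mixed-model software
  prints.  Inputs to the VTE-correlation model are z-scored over all
  pooled laps.  Rows whose lagged covariates are undefined (first laps of
  a session) drop out of the previous-lap specifications.

## Synthetic data: what it emulates, what it does not

The cohort generator mirrors the study scale — 7 rats × 51 sessions × 74
laps — with per-rat multiplicative parameter jitter (10% CV) so mixed
models have real between-rat variance to find.  Simulation presets follow
the published simulation settings: α₁ = α₂ = 0.5, β₁ = β₂ = 3, p = 0.3,
λ = 0 for the model-free/model-based signature runs, and all-zero
learning rates for the random baseline (whose choice probabilities are
then exactly 0.5).  The hybrid preset adds w = 0.65, the mid-range weight
a hybrid fit to such data reports.

Trajectories run through an idealized maze (arbitrary length units, zone
rectangles shipped as `DEFAULT_ZONES`) at constant speed with the head
leading the body; VTE laps insert a 1.5-s dwell at the zone center with 2
back-and-forth head sweeps of 150° each, chosen to reproduce a cleanly
bimodal pooled LogIdPhi distribution.  Additive Gaussian positional noise
is the only tracking artifact modelled.  Real tracking has dropouts,
reflections, and variable speed; passing these tests therefore shows the
estimators are correct on their stated geometry, not that they are robust
to every artifact of real video tracking.

The mixed-model generator builds covariates (transition, repeat, previous
delay) from an actual cohort simulation so their joint structure matches
the task process, then adds rat/session intercepts and Gaussian residuals
with specified SDs.

## Desk-scale problem sizes

The shipped experiments are sized for a single CPU: parameter recovery
uses 20 replicates of 200 sessions × 74 laps with 2 chains × 1,200
iterations (600 warm-up); model-selection recovery uses 5 replicate
hybrid cohorts with all three algorithms fit per replicate;
stay-probability signatures use 2,000–3,000 sessions per algorithm rather
than the 10,000 of the original simulations (the signature is a sign
pattern across delay bins and is already decisive at this size); the
mixed-model recovery uses 20 replicates at the full 7 × 51 × 74 scale.
Coverage checks are reported per parameter (each generating value inside
its nominal-95% interval in ≥ 90% of replicates): simultaneous coverage
of four independent 95% intervals is only ≈ 0.95⁴ ≈ 81% even for a
perfectly calibrated method, so a joint criterion would conflate
calibration with multiplicity.

## Known limitations

* Pooled fitting only: hierarchical (per-rat) RL models are out of scope;
  fits return one θ per dataset.
* DIC absolute values depend on the dataset; only differences between
  algorithms fit to the *same* data are meaningful, and
  `compare_models` enforces that by dataset signature.
* The adaptive Metropolis mixes slowly for weakly identified parameters
  (λ near 0 makes α₁ nearly flat); ESS flags report this honestly.
* λ generated at its boundary value 0 cannot be covered by an open-
  interval posterior, which is why recovery is scored on the identified
  parameters α₂, β₁, β₂, p.
* The VTE threshold is a mixture-model construction, not a published
  constant; different smoothing or units shift LogIdPhi by a fixed
  offset, which moves the threshold but not the classification.
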