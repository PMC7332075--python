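# Methods

This note documents the generative task model, the learning models, the
fitting and comparison machinery, and the behavioural analyses implemented in
`twostep`, together with the numerical choices and their rationale.

## Task model (`twostep.task`)

A trial is: first-stage choice between two pictures at state A → stochastic
transition to second-stage state B or C → second-stage choice → outcome.
The transition structure is fixed throughout: action 0 reaches B with
probability `p_common` (default 0.7), action 1 reaches C; the minority
successor is labelled *rare*.

Each of the four second-stage options carries an independent outcome-level
process: the level (1 = low, 2 = medium, 3 = high) dwells for a uniformly
drawn integer number of trials in `[dwell_min, dwell_max]` (default 5–9) and
is then redrawn **uniformly over the three levels**, so it stays with
probability 1/3.  A fresh dwell length is drawn at every redraw event,
including same-level continuations — the dwell-then-redraw description does
not distinguish this from "extend by a new dwell only on change", and the
uniform-redraw reading makes the stay probability exactly 1/3 as specified.

Outcome levels map to juice durations: high and medium pay from
non-overlapping windows (defaults are the subject-C profile: 682–962 ms and
117–390 ms) with a Gaussian random-walk drift (SD 200 / 100 ms per trial)
**clipped at the window edges** so the windows stay non-overlapping; low pays
0 ms.  The per-level delays are carried as metadata only — they are constant
per level and therefore uninformative for valuation.  Model fitting uses the
normalized reward `r = juice / max(juice in session)`, so every session
containing a high outcome has max reward exactly 1.

15% of trials are forced (a single option shown), i.i.d. Bernoulli per trial
with the forced stage chosen uniformly; the trial-type sequence is
pre-generated per session.  Error trials (fixation breaks etc.) exist in the
data model for replication datasets; simulations inject them only via an
optional `error_rate` (default 0), since a simulated agent cannot commit
fixation errors.

## Learning models (`twostep.agents`)

State-action values `Q` are initialized at 0 at session start and nothing
carries across sessions (parameters are per-session in fitting).  With
rewards and initial values in [0, 1], Q values remain in [0, 1] for all
learning rates and traces in [0, 1] (property-tested).

**Model-free.** Stage-2 prediction error `δ2 = r − Q(s2, a2)`; stage-1 error
uses the second-stage value of the action actually chosen (SARSA) or of the
better action (Q-learning), with the successor of stage 2 being a fictitious
zero-valued terminal state.  Updates are `Q ← Q + α_i δ_i` per stage, plus a
within-trial eligibility pass `Q(s1,a1) ← Q(s1,a1) + α1 λ δ2`; eligibility
does not persist across trials (the task has an explicit inter-trial epoch).
Updates are applied sequentially: δ1 is computed before the stage-2 value is
refreshed by δ2.

**Model-sensitive.** Second-stage MS values coincide with the MF values
there (both just track immediate reward).  First-stage MS values weight the
best second-stage values by transition beliefs.  Three belief models:

* `Forward1` — the true probabilities {0.7, 0.3} are known throughout;
* `Forward2` — counts which action→state mapping has occurred more often and
  assigns 0.7 to the majority mapping; on exactly tied counts the beliefs
  are (0.5, 0.5) — no arbitrary winner until a strict majority exists;
* `Forward3` — a hypothesis test between the structured transition matrix
  ({0.7, 0.3} under the majority mapping) and the uniform one ({0.5, 0.5}).
  We interpret ζ ∈ (0, 1) as the prior weight of the structured hypothesis:
  the two hypotheses' likelihoods of the observed transition counts convert
  ζ into a posterior weight, and the belief is the posterior-weighted
  mixture of the two transition rows.  (Treating ζ instead as a fixed mixing
  weight is the special case of ignoring the counts; the posterior reading
  makes the model actually *learn* the structure incrementally, which is the
  stated intent.)  Count statistics for `Forward2/3` reset at session start.

**Hybrid and Hybrid+.** Hybrid first-stage values are
`(1−ω)·Q_MF + ω·Q_MS`; ω = 0 and ω = 1 reproduce the pure learners'
likelihoods exactly (tested).  Hybrid+ adds a transient adjustment
recomputed each trial from the immediately preceding completed trial only:
the previously chosen first-stage action gets `+L_j` (previous transition
common) or `−L_j` (rare), with `j` the previous outcome level.  It is an
additive term on the decision values, not an accumulating Q modification,
because the effect does not persist beyond a single trial.  The displayed
update rules touch only the chosen action; a `mirror_unchosen` switch
applies the opposite adjustment to the unchosen action for users who want
the symmetric variant, without asserting that reading.

**Choice rule.** Softmax over `β_i (Q + κ_i · rep(a))` per stage, where
`rep(a)` marks the action chosen on the previous visit to the *same* state
(B and C tracked separately).  β = 0 yields random choice.  The softmax is
evaluated in the log domain, so extreme β never under/overflows.

**Trial types.** Forced stages contribute likelihood 1, but the realized
action still updates `rep`, the values and the Hybrid+ summary.  Error
trials are skipped entirely — no likelihood, no value/perseveration/summary
update — since no outcome is observed; the learner's state is carried
through them unchanged.

The readable per-trial loop (`agents.Agent`) serves simulation and
likelihood evaluation through the same code path.  A numba kernel
(`_likelihood.py`) re-implements the loop over packed arrays for the
optimizers; a test asserts exact agreement between the two paths across the
whole model family, so the kernel is an optimization, never a second source
of truth.

## Fitting (`twostep.fitting`)

Parameters bounded to (0, 1) (α, λ, ω, ζ) are optimized through a logistic
transform, positive β through a log transform, and the unbounded κ and L
through the identity (the constraint list bounds only α, β, λ, ω);
round-trips are exact to 1e-10.  All optimisation is unconstrained BFGS
(finite-difference gradients) in transformed space.

*Fixed effects*: per-session ML from `n_restarts` random starts (default 20;
the E-step count below is the procedure's own convention, the fixed-effects
count is a free choice) drawn as standard normal deviates around neutral
values in transformed space.

*Mixed effects*: empirical-Bayes EM with a diagonal Gaussian prior.  The
E-step finds each session's MAP under the current prior (one warm start from
the previous iteration's MAP — or the ML fit initially — plus prior-drawn
restarts, 101 by default) and takes posterior variances from the diagonal of
the inverse of a finite-difference Hessian of the negative log posterior
(central differences, relative step 1e-3).  A non-positive-definite Hessian
falls back to per-coordinate curvature, floored positive and flagged.  The
M-step sets the prior mean to the average MAP and the prior variance to the
average of (MAP² + posterior variance) minus the squared mean, floored at
1e-6 with a warning when degenerate.  The loop is initialised from the
trimmed moments of the ML fits — 25% trimmed **in total**, i.e. 12.5% per
tail (`trim` is configurable for the per-tail reading) — and stops when no
MAP moves by more than 0.005 in transformed space, followed by one final
E-step.

Desk-scale defaults used by the test-suite and the acceptance script (2
restarts, ≤ 8 EM iterations, 10 sessions × 500 trials) were chosen so a full
recovery experiment completes in about a minute on one CPU; they recover the
generating hyperparameters comfortably at that scale, and all counts are
configurable upward.

## Model comparison (`twostep.selection`)

* **BIC** `−2 logL + k ln n` on the fixed-effects fits.
* **Integrated BIC**: each session's likelihood is averaged over K draws
  from the empirical prior (log-sum-exp minus log K; K = 1000 by default),
  summed over sessions, and penalised by `|M| ln |A|` where `|M|` counts two
  prior parameters (mean and variance) per free model parameter and `|A|` is
  the total number of analysed (non-error) trials.  With σ → 0 this reduces
  to the fixed-effects BIC at the prior mean (tested analytically).
* **Protected exceedance probability**: variational Dirichlet random-effects
  model selection over per-session log evidences (MAP likelihoods from the
  hierarchical fit by default; prior-averaged marginals can be supplied
  instead).  Exceedance is exact (Beta tail) for two models and Monte-Carlo
  for more; protection mixes with the equal-frequency null weighted by the
  null's posterior probability computed from the variational free energy.
  The implementation is validated against brute-force numerical integration
  of the exact random-effects posterior on the two-model simplex: agreement
  is < 0.01 when the posterior concentrates, while in weakly identified
  regimes (~15 sessions, evidence differences ~1 log-unit) the variational
  approximation overshoots the exact exceedance by up to ~0.05 — a known
  property of this family of approximations, shared by the standard
  toolboxes, and documented here rather than hidden.
* **LRT** `2 Δ logL ~ χ²(df)` with an explicit nesting check on the model
  specifications; a negative likelihood gain is reported as an optimizer
  failure rather than silently clipped.
* **Predictive probability**: the geometric mean per-choice probability
  `exp(logL / #choices)`, with a one-sided binomial test of above-chance
  prediction (chance 0.5 per two-option choice; a choice counts as predicted
  when its modelled probability exceeds 0.5, exact ties counting half).

## Behavioural analyses (`twostep.behaviour`)

Variable coding: C = first-stage choice (1 for the reference picture,
action 0), R = outcome level as a continuous 1/2/3, T = transition
(rare = 1).  Predictors are mean-centred within session; continuous ones
(R, and the fatigue term) are additionally divided by twice their population
SD (ddof = 0 — with balanced levels this gives the scaled values ±0.6124),
and interactions are formed *after* centring/scaling.  The choice design has
a constant plus 7 terms × 5 lags = 36 columns; the RT design has constant +
fatigue + 3 terms × 5 lags = 17.

Error trials and forced trials are excluded, and by default the lag
structure runs over the *analysed* sequence (exclusions removed first);
a `calendar` policy that preserves original adjacency is available, since
the source analyses do not state which convention was used.

Per-session fixed-effects fits use ML logistic / OLS regression
(statsmodels); separation or non-convergence triggers a small ridge penalty
with the session flagged.  Across sessions, coefficients are summarised by
two-tailed one-sample t-tests on the per-session point estimates.  The
mixed-effects summary treats each coefficient as a random effect across
sessions and combines the per-session estimates by DerSimonian–Laird
moment-based random-effects pooling (between-session variance estimated per
coefficient), with Wald χ² tests on coefficient sets; this implements the
random-coefficients contract without pulling in a full GLMM solver, and
falls back to the fixed-effects summary (flagged) where per-session standard
errors are unavailable.

RT preprocessing: log-transform, z-score within session × response side for
first-stage RT (sides differ systematically), within session for fixation
RT; points more than 3 SD from the individual mean are removed, and a side
with fewer than two observations is excluded with a warning.

Lag profiles are summarised by least-squares fits of `A·exp(b·lag)` over
lags 1–5 on the *signed* mean fixed-effects coefficients (the absolute-value
variant can be fit by passing |c|); `b` is reported as the decay constant,
negative for decaying magnitudes, with adjusted R² for the 2-parameter fit.
Constant input returns b = 0; sign-alternating input returns a fit with low
adjusted R² rather than an error.  Refitting on fitted values reproduces
(A, b) to 1e-6.

## Synthetic data and recovery (`twostep.synth`)

A `SubjectProfile` fixes the generating model, a Gaussian hyperprior over
per-session parameters in transformed space, session and trial counts, and
the task configuration.  The default hyperprior means emulate a well-trained,
strongly model-sensitive subject (shared α ≈ 0.78, β1 ≈ 4.6 > β2 ≈ 2.5,
small positive κ, ω ≈ 0.86, L1 ≈ 0.25 with mildly aversive L2/L3); the
between-session SDs (0.25–0.4 on transformed bounded/log parameters, 0.05–
0.08 on the additive ones) produce the session-to-session spread such
subjects show without leaving plausible ranges.  The default experiment size
is 10 sessions × 500 trials — the empirical per-session scale at a desk-sized
session count; the full 30-session scale is a configuration away.

`simulate_from_fit` replays fitted agents against the *observed* sessions'
outcome schedules (exactly, per stored schedule) while transitions and trial
types are regenerated: the agent's own first-stage choice determines which
transition row applies, so observed draws cannot be replayed.  Session MAPs
are reused across runs (100 runs per session by default) rather than
resampled from the prior.

What the generator does **not** emulate: reaction times (any synthetic RTs
used in pipeline tests come from a documented lognormal toy model and are
not claimed realistic), fixation-error processes (errors are injected i.i.d.
when enabled), and side biases (action identity is the picture, not the
side).  Passing tests on synthetic data therefore validate the estimation
and comparison machinery under the task's statistical structure; they do not
by themselves certify conclusions about any particular empirical dataset.

A caution discovered in validation: with this task's dwelling outcome
levels, a lag-1-only choice regression on pure model-free simulations picks
up an apparent reward × transition interaction (≈ −0.6) through value-state
confounding — the effect disappears when outcome levels are made i.i.d., and
the t−1 coefficients of the full 5-lag regression show the expected null.
The MF/MS signature checks therefore use the 5-lag design.

## Deposited-data replication (`twostep.dataio`)

The reader for deposited behavioural datasets is glossary-driven: a table
mapping container variable names to trial-record fields (the variable names
inside such deposits are not knowable a priori).  Mandatory fields (session
index, both choices, second-stage state, outcome level, juice) raise errors
naming the missing quantity; unmapped variables are preserved as
passthrough.  Negative values are treated as the container's missing-data
sentinel.  The test fixture writes a synthetic dataset in this reference
layout and round-trips it; the replication checks in the acceptance suite
run only when a real deposit is placed under `data/`.

## Known limitations

* Priors are diagonal Gaussians; parameter correlations across sessions are
  not modelled (no full-covariance prior, no MCMC).
* The `Forward3` hypothesis test is one defensible formalisation of a
  briefly described mechanism; alternatives (e.g. fixed mixing weight) are
  easy to add but not implemented.
* The mixed-effects regression is a two-stage random-effects summary, not a
  joint GLMM; with very short sessions the per-session ML step, not the
  pooling, limits accuracy.
* Finite-difference Hessians can be noisy for nearly flat directions
  (e.g. λ in a Hybrid fit where ω ≈ 1); the variance floor and the
  `hessian_ok` flag make this visible instead of silent.
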