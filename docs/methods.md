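# Methods

## The two-step environment

Each of the 201 trials has a first-stage binary choice, a probabilistic
transition to one of two second-stage states, a second binary choice, and a
binary reward (one 20-cent gain).  The transition structure is fixed: each
first-stage action reaches its "common" state with probability 0.7 and the
other state with probability 0.3, and the two actions have distinct common
states.  Reward probabilities of the four second-stage options evolve as
independent Gaussian random walks with reflecting boundaries at 0.25 and
0.75.

Design choices where the task description leaves freedom:

* **Walk step size** `sd_innovation = 0.025` (per trial, on the probability
  scale).  The walks are meant to change slowly relative to a 201-trial
  session so neither controller is ever trivially optimal; 0.025 gives a
  typical excursion of ~0.35 over a session inside a 0.5-wide corridor.
  Exposed in the API.
* **Walk initialization** uniform within the boundaries.
* **Reflection** folds an excursion once across the violated bound
  (boundaries are far wider than any plausible step, so one fold suffices);
  a loop guards pathological step sizes.
* Actions and states are 0-indexed, trial indices 1-based.  All 201 trials
  are treated as analyzable; no practice trials are modelled.
* Reaction times and screen layout are presentation details and are not
  modelled.

## The hybrid learner

Model-free values follow SARSA(λ) with stage-wise learning rates.  Within a
trial, δ₁ = Q_MF(s₂, a₂) − Q_MF(s_A, a₁) (no first-stage reward exists) and
δ₂ = r − Q_MF(s₂, a₂) (no third stage exists); the second-stage update
Q_MF(s₂, a₂) += α₂δ₂ and the first-stage update
Q_MF(s_A, a₁) += α₁δ₁ + α₁λδ₂ both use the *pre-update* values when forming
the prediction errors, the on-policy SARSA convention of backing up the value
that informed the choice.  λ appears only in the stage-skipping term: there
is no eligibility decay within the single-step second stage.

Model-based first-stage values weight the better second-stage option of each
state by the true transition probabilities; the transition matrix is fixed,
not learned, consistent with the instructed task structure.  The blend
Q = ω·Q_MB + (1 − ω)·Q_MF applies at the first stage only (the systems
coincide at the second stage).  Choices are softmax in β·(Q + ρ·rep), where
rep = 1 for repeating the previous first-stage choice; ρ is inactive on trial
one and at the second stage.  All Q values start at zero, which keeps
second-stage values in [0, 1] for binary rewards (each update is a convex
combination).

Numerics: the softmax subtracts the max before exponentiation; per-trial
choice probabilities are floored at 1e-300 before taking logs, so extreme β
never produces −∞.  The likelihood and agent-simulation inner loops are
numba-jitted array kernels with a pure-Python fallback; the readable
object-level implementation is kept as the reference path and the test suite
asserts agreement to 1e-10.  ω = 0 and ω = 1 are parameter restrictions, not
separate code paths.

## Hierarchical empirical-Bayes fitting

Parameters are estimated on unconstrained scales — log for β₁, β₂, logit for
α₁, α₂, λ, ω, identity for ρ — under an independent Gaussian group prior.
Unit-interval values exactly at a boundary are clipped to [1e-9, 1 − 1e-9]
with a warning before the logit.

* **E-step.**  Per-subject MAP by L-BFGS-B with 10 restarts (one from the
  prior mean, one warm start from the previous iteration, the rest drawn from
  the prior) — hybrid-RL likelihood surfaces are multimodal.  Posterior
  variances come from the inverse diagonal of a central-finite-difference
  Hessian of the penalized objective; the diagonal approximation trades
  exactness for robustness at seven parameters, and coordinates with
  non-positive curvature fall back to the prior variance.
* **M-step.**  Moment matching including posterior uncertainty:
  μ ← mean(y_MAP), σ² ← mean(y²_MAP + Var_Laplace) − μ², floored at 1e-4 to
  prevent prior collapse on small cohorts.
* **Convergence** is declared when the summed penalized log-likelihood
  improves by less than 1e-3 (measured on the objective, not parameter
  movement), up to 50 iterations; non-convergence is reported in the result,
  not raised.  Running a single iteration reproduces the variant in which the
  prior is set once from the pooled fit; the full iterative EM is the
  default.  β₁ and β₂ are fitted separately throughout.

The default initial prior is broad — zero mean (β centred at 1, unit-interval
parameters at 0.5) with variance 4 — and is configurable.  No model
comparison machinery and no full-covariance prior are provided; the
devaluation task is analysed behaviorally, not model-fitted.

## The devaluation environment and the dual-controller agent

Training delivers, per condition and trial: food with p = 0.5 plus fruit tea
with p = 0.25 after the high-probability stimulus of a food condition, tea
with p = 0.25 after the low-probability stimulus, and water with
p = 0.75 / 0.25 in the neutral condition.  The extinction test withholds food
and delivers tea with p = 0.3 after either stimulus of a food condition.  The
extinction tea probability (0.3) differs from training (0.25) and both are
encoded as designed, without reconciliation.  Whether water continues in the
neutral condition during extinction is not specified by the design; this
implementation continues it as in training (flagged as a choice, toggleable).
150 training and 150 extinction trials (50 per condition), condition order
fully randomized.

The synthetic subject blends a goal-directed controller G with a habitual
controller H, choice by softmax over w·G + (1 − w)·H with inverse temperature
`beta_d`:

* G(condition, choice) is the expected outcome utility under the *training*
  contingencies — the agent has accurate action-outcome knowledge after 50
  training trials per condition (a learned-G variant is out of scope).  G is
  re-derived instantly when the devaluation event changes the utilities,
  which is exactly what makes it goal-directed.
* H is a running average of delivered-outcome utility (rate `alpha_h`) for
  the chosen stimulus, updated during training only and frozen from the
  devaluation event onward, so it cannot react to the changed utility.

Default utilities: food 1, tea 0.5, water 0.5, nothing 0; only the ordering
matters for the qualitative signatures.  The devalued food's post-satiation
utility defaults to **−0.5**: subjects eat the food until they rate it
*unpleasant*, i.e. below neutral, and a strictly negative value is also what
makes a fully goal-directed agent actively avoid the devalued stimulus rather
than merely become indifferent (at u_deval = 0 the two stimuli of the
devalued condition tie exactly at 0.125 expected utility and choice falls to
chance, capping the pre/post drop at 0.5).  Defaults `alpha_h = 0.2` and
`beta_d = 8` make a purely habitual agent learn the high-probability stimulus
comfortably above the 75% training criterion within 50 trials per condition,
matching the attrition scale of a small human cohort (≈ 3 of 18 synthetic
subjects fail the criterion on average).  Satiety dynamics, pleasantness
ratings, and overtraining designs are not modelled.

## Behavioral statistics

Stay probabilities are tabulated from trial 2 onward by the previous trial's
reward × transition; empty cells are missing (NaN), never zero, and subjects
with any empty cell are dropped from group contrasts (complete-case).  The
2×2 within-subject ANOVA is computed in its exact paired-contrast form: the
main effect of reward is the mean of a per-subject contrast tested by paired
t, F = t², df = (1, n − 1); likewise the reward × transition interaction.
The two-step model-based index is (RC − RR) − (UC − UR) on stay
probabilities.

The devaluation index counts high-probability choices in the last 10 training
and first 10 extinction trials *of each condition*.  Its default orientation
is (devalued_pre − devalued_post) − (valued_pre − valued_post): a
devaluation-specific drop scores positive, so "higher = more goal-directed"
holds literally.  The opposite orientation — the difference written with the
valued condition first — is available behind a `literal_formula` flag since
the two appear interchangeably in the field's verbal descriptions.

The cross-task association uses the Spearman coefficient (robust at small n)
with a one-tailed p for the a-priori directed hypothesis of a *positive*
association.  For n ≤ 9 the tail is computed by exact enumeration of all n!
rank permutations (average ranks for ties); for larger n by the t
approximation with df = n − 2.  A 10,000-replicate null simulation at n = 13
confirms nominal size (rejection rate 0.049 at α = 0.05).

## The synthetic cohort and what it does / does not show

Each subject draws a latent trait g ~ N(0, 1); on the unconstrained scale
ω and w receive k·g plus independent residual noise, while every other
parameter is sampled independently of g.  The coupling-only-through-ω-and-w
default encodes the specificity hypothesis (no built-in association between
the devaluation score and model-free indices).  Hybrid-parameter centers are
the fitted group medians for this task battery (β₁ = 6.55, β₂ = 2.42,
α₁ = 0.56, α₂ = 0.58, λ = 0.70, ω = 0.43, ρ = 0.20); spreads derive from the
reported quartiles via IQR/1.349.  The default k = 3 is a package choice, not
an empirical estimate: it places paper-scale cohorts (n ≈ 13 after
exclusions) at an expected score-level rank correlation around 0.7, the
regime the construct-validity question is interesting in.

One caveat the simulations surface: because a large ω *suppresses* the
model-free staying pattern in the hybrid learner, the devaluation score
correlates mildly *negatively* (not exactly zero) with the reward main effect
under strong coupling.  The specificity claim that survives is directional —
no positive association — which is also all the one-tailed test asserts.

Passing tests on these cohorts show that the pipeline is correctly wired and
statistically calibrated, and that the scores behave as the theory predicts
for agents whose generative process is known.  They do not show that human
subjects are dual-controller agents, that the trait coupling in people has
any particular strength, or that the specific group-level F and ρ values of
any human sample are reproducible — no empirical cohort data ship with the
package.

## Problem sizes

Monte-Carlo checks use 200 agents per pure-agent cohort, 100–200 agents per
devaluation condition, 50 subjects × 201 trials for hierarchical ω recovery
(Pearson r ≈ 0.75 against the generative values), and 20 replicate cohorts of
200 subjects per coupling level for the correlation calibration — sizes at
which the qualitative signatures are stable from run to run on a single CPU.
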