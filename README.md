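# dualcontrol

Dual-system analysis of instrumental decision making: are "goal-directed"
behavior in an outcome-devaluation experiment and "model-based" behavior in a
two-step sequential decision task two measurements of the same underlying
trait?  `dualcontrol` provides tested simulators for both paradigms, the
hybrid model-free/model-based reinforcement-learning model, hierarchical
empirical-Bayes parameter estimation, and the behavioral statistics needed to
run the full construct-validity analysis end to end on synthetic cohorts.

## The model

In the two-step task a first-stage choice leads to one of two second-stage
states (70%/30% common vs. rare transitions), where a second choice is
rewarded according to Gaussian-random-walk probabilities bounded in
[0.25, 0.75].  The learner is a hybrid of two valuation systems:

* **Model-free (SARSA(λ))** with stage-wise learning rates α₁, α₂ and
  prediction errors δ; λ additionally lets the second-stage prediction error
  update the first-stage value directly:

  Q_MF(s₁, a₁) ← Q_MF(s₁, a₁) + α₁δ₁ + α₁λδ₂

* **Model-based**, which evaluates first-stage actions prospectively through
  the true transition matrix:

  Q_MB(s_A, a) = P(s_B | s_A, a) · max_{a′} Q_MF(s_B, a′) + P(s_C | s_A, a) · max_{a′} Q_MF(s_C, a′)

The systems are blended at the first stage, Q = ω·Q_MB + (1 − ω)·Q_MF, and
choices follow a softmax with inverse temperatures β₁, β₂ and a first-stage
perseveration bonus ρ — seven free parameters (β₁, β₂, α₁, α₂, λ, ω, ρ) with
ω, the model-based weight, the parameter of primary interest.  Parameters are
estimated per subject by MAP under a Gaussian group prior on transformed
scales (log β, logit for unit-interval parameters), with the prior moments
re-estimated from the cohort by expectation-maximization (diagonal Laplace
approximation in the E-step).

The devaluation paradigm (training → selective satiation → extinction test)
is simulated by a dual-controller agent whose goal-directed system re-values
actions instantly when an outcome is devalued, while its habit system — a
running average of experienced outcome utility — does not.  A latent trait
couples the agent's goal-directed weight w to ω across subjects, so the
construct-validity question (do the two interaction scores rank subjects the
same way?) can be posed and answered on simulated cohorts at any coupling
strength.

## Worked example

```python
import numpy as np
from dualcontrol import (CohortConfig, generate_cohort, run_construct_validity)

cohort = generate_cohort(CohortConfig(n_subjects=18, trait_coupling_k=3.0, seed=7))
print(f"included {len(cohort.included_subjects)} of 18 subjects")
report = run_construct_validity(cohort)
print(f"rho(deval, mb) = {report.rho_deval_mb:.3f}, one-tailed p = {report.p_deval_mb:.4f}")
c = report.contrast_interaction
print(f"reward x transition: F(1,{c.df[1]}) = {c.F:.2f}, p = {c.p:.4f}")
```

prints

```
included 13 of 18 subjects
rho(deval, mb) = 0.718, one-tailed p = 0.0029
reward x transition: F(1,12) = 8.93, p = 0.0113
```

Eighteen synthetic subjects are recruited; five fail the 75%-correct training
criterion and are excluded.  With strong trait coupling (k = 3) the
devaluation interaction score and the two-step stay-probability interaction
score rank the remaining subjects similarly (Spearman ρ = 0.72, significant
one-tailed at n = 13), and the cohort shows a group-level reward × transition
interaction — the stay-probability signature of model-based control.

The same pipeline is available from the shell:

```bash
dualcontrol cohort --subjects 18 --coupling 3 --seed 7 --out cohort/
dualcontrol analyze --cohort cohort/ --out analysis/
dualcontrol fit --logs cohort/twostep/S001.tsv --logs cohort/twostep/S002.tsv ... --out fit/
```

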