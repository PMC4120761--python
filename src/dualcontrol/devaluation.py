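"""Selective outcome-devaluation paradigm: environment and dual-controller agent.

The paradigm has three interleaved stimulus-pair conditions (two food
conditions and a neutral one) and three steps: instrumental training,
selective devaluation of one food (satiation), and a test in extinction.
During training the high-probability stimulus of a food condition delivers
food with p = 0.5 and a common fruit-tea outcome with p = 0.25, the
low-probability stimulus delivers tea with p = 0.25; the neutral condition
delivers water with p = 0.75 / 0.25.  In extinction the foods are withheld
and both stimuli of a food condition deliver tea with p = 0.3.

The synthetic agent standing in for human subjects blends a goal-directed
controller G (expected outcome utility under the known training
contingencies, re-evaluated instantly when an outcome is devalued) and a
habitual controller H (a running average of delivered-outcome utility,
insensitive to devaluation), with a weight w on the goal-directed side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

CONDITIONS = ("devalued", "valued", "neutral")
PHASES = ("training", "extinction")
CHOICES = ("high", "low")
OUTCOMES = ("food", "tea", "water", "none")

TRAINING = "training"
EXTINCTION = "extinction"


def _default_utilities() -> dict[str, float]:
    return {"food": 1.0, "tea": 0.5, "water": 0.5, "none": 0.0}


@dataclass(frozen=True)
class DevalDesign:
    """Outcome probabilities and trial counts of the devaluation paradigm."""

    p_food_high: float = 0.5
    p_tea_training: float = 0.25
    p_water_high: float = 0.75
    p_water_low: float = 0.25
    p_tea_extinction: float = 0.3
    n_training: int = 150
    n_extinction: int = 150
    analysis_window: int = 10
    #: water keeps being delivered for the neutral pair during extinction
    neutral_water_in_extinction: bool = True

    def __post_init__(self) -> None:
        for cond in CONDITIONS:
            for choice in CHOICES:
                for phase in PHASES:
                    total = sum(self.outcome_probs(cond, choice, phase).values())
                    if total > 1.0 + 1e-12:
                        raise ValidationError(
                            f"outcome probabilities for ({cond}, {choice}, {phase}) "
                            f"sum to {total} > 1"
                        )
        if self.n_training % len(CONDITIONS) or self.n_extinction % len(CONDITIONS):
            raise ValidationError("trial counts must divide evenly across the 3 conditions")

    @property
    def n_per_condition_training(self) -> int:
        return self.n_training // len(CONDITIONS)

    @property
    def n_per_condition_extinction(self) -> int:
        return self.n_extinction // len(CONDITIONS)

    def outcome_probs(self, condition: str, choice: str, phase: str) -> dict[str, float]:
        """Categorical outcome distribution for a (condition, choice, phase) cell.

        The probability mass not listed goes to the "none" outcome.  Food is
        never delivered in extinction.
        """
        if condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {condition!r}")
        if choice not in CHOICES:
            raise ValidationError(f"unknown choice {choice!r}")
        if phase not in PHASES:
            raise ValidationError(f"unknown phase {phase!r}")
        if condition == "neutral":
            p_water = self.p_water_high if choice == "high" else self.p_water_low
            if phase == EXTINCTION and not self.neutral_water_in_extinction:
                return {}
            return {"water": p_water}
        if phase == TRAINING:
            if choice == "high":
                return {"food": self.p_food_high, "tea": self.p_tea_training}
            return {"tea": self.p_tea_training}
        return {"tea": self.p_tea_extinction}


@dataclass(frozen=True, slots=True)
class DevalTrial:
    """One trial: 1-based index within its phase, condition, choice, delivered outcome."""

    t: int
    phase: str
    condition: str
    choice: str
    outcome: str


@dataclass(eq=False)
class DevalSession:
    """One subject's trials across training and extinction."""

    subject_id: str
    devalued_condition: str
    trials: list[DevalTrial]
    design: DevalDesign = field(default_factory=DevalDesign)

    def __post_init__(self) -> None:
        for tr in self.trials:
            if tr.phase == EXTINCTION and tr.outcome == "food":
                raise ValidationError(
                    f"session {self.subject_id}: food delivered in extinction (trial {tr.t})"
                )

    def phase_trials(self, phase: str, condition: str | None = None) -> list[DevalTrial]:
        return [
            tr
            for tr in self.trials
            if tr.phase == phase and (condition is None or tr.condition == condition)
        ]


@dataclass(frozen=True)
class DualControllerParams:
    """Dual-controller agent: w blends goal-directed (G) vs. habitual (H) values.

    Utilities are on an arbitrary scale where only the ordering matters for
    the qualitative signatures; ``u_deval`` replaces the devalued food's
    utility after satiation (negative by default: the food is eaten until it
    is rated unpleasant).
    """

    w: float
    alpha_h: float = 0.2
    beta_d: float = 8.0
    utilities: dict[str, float] = field(default_factory=_default_utilities)
    u_deval: float = -0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValidationError(f"w must lie in [0, 1], got {self.w}")
        if not 0.0 <= self.alpha_h <= 1.0:
            raise ValidationError(f"alpha_h must lie in [0, 1], got {self.alpha_h}")
        if self.beta_d < 0:
            raise ValidationError(f"beta_d must be >= 0, got {self.beta_d}")
        if not all(np.isfinite(list(self.utilities.values()))):
            raise ValidationError("utilities must be finite")


def sample_outcome(
    condition: str, choice: str, phase: str, design: DevalDesign, rng: np.random.Generator
) -> str:
    """Draw one outcome from the design's categorical distribution for the cell."""
    probs = design.outcome_probs(condition, choice, phase)
    u = rng.uniform()
    acc = 0.0
    for outcome, p in probs.items():
        acc += p
        if u < acc:
            return outcome
    return "none"


def _utility(outcome: str, condition: str, params: DualControllerParams, devalued: bool) -> float:
    if devalued and condition == "devalued" and outcome == "food":
        return params.u_deval
    return params.utilities.get(outcome, 0.0)


def _goal_directed_values(
    design: DevalDesign, params: DualControllerParams, devalued: bool
) -> dict[str, np.ndarray]:
    """G(condition, choice): expected utility under the *training* contingencies.

    The extinction test probes stored action-outcome knowledge, so G keeps the
    training probabilities; only the utilities change at devaluation.
    """
    g = {}
    for cond in CONDITIONS:
        vals = np.empty(2)
        for j, choice in enumerate(CHOICES):
            probs = design.outcome_probs(cond, choice, TRAINING)
            vals[j] = sum(p * _utility(o, cond, params, devalued) for o, p in probs.items())
        g[cond] = vals
    return g


def _softmax_high(v_high: float, v_low: float, beta: float) -> float:
    x = beta * (v_high - v_low)
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


def simulate_dual_controller(
    params: DualControllerParams,
    design: DevalDesign | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    subject_id: str = "agent",
    devalued_food: str | None = None,
) -> DevalSession:
    """Simulate one dual-controller subject through training and extinction.

    Training: choices are softmax over w·G + (1−w)·H per condition; H is a
    running average of delivered-outcome utility (rate ``alpha_h``) for the
    chosen stimulus.  The devaluation event sets the devalued food's utility
    to ``u_deval`` and re-derives G; H is frozen from then on.  Condition
    order is fully randomized within each phase.
    """
    if design is None:
        design = DevalDesign()
    if rng is None:
        rng = np.random.default_rng(seed)
    if devalued_food is None:
        devalued_food = str(rng.choice(["chocolate", "tomato"]))

    g_pre = _goal_directed_values(design, params, devalued=False)
    h = {cond: np.zeros(2) for cond in CONDITIONS}
    w = params.w

    trials: list[DevalTrial] = []

    def run_phase(phase: str, n_per_cond: int, g: dict[str, np.ndarray], update_h: bool) -> None:
        order = np.repeat(np.arange(len(CONDITIONS)), n_per_cond)
        rng.shuffle(order)
        for t, cond_idx in enumerate(order, start=1):
            cond = CONDITIONS[cond_idx]
            v = w * g[cond] + (1.0 - w) * h[cond]
            p_high = _softmax_high(v[0], v[1], params.beta_d)
            j = 0 if rng.uniform() < p_high else 1
            choice = CHOICES[j]
            outcome = sample_outcome(cond, choice, phase, design, rng)
            if update_h:
                util = _utility(outcome, cond, params, devalued=False)
                h[cond][j] += params.alpha_h * (util - h[cond][j])
            trials.append(DevalTrial(t=t, phase=phase, condition=cond, choice=choice, outcome=outcome))

    run_phase(TRAINING, design.n_per_condition_training, g_pre, update_h=True)
    # devaluation event: utilities change, G is re-derived, H stays frozen
    g_post = _goal_directed_values(design, params, devalued=True)
    run_phase(EXTINCTION, design.n_per_condition_extinction, g_post, update_h=False)

    return DevalSession(
        subject_id=subject_id, devalued_condition=devalued_food, trials=trials, design=design
    )


def training_criterion_met(session: DevalSession, threshold: float = 0.75) -> dict[str, bool]:
    """Per-condition learning criterion: fraction of high-probability choices
    during training meets or exceeds ``threshold`` (inclusive boundary)."""
    out = {}
    for cond in CONDITIONS:
        trials = session.phase_trials(TRAINING, cond)
        if not trials:
            raise ValidationError(
                f"session {session.subject_id}: no training trials for condition {cond!r}"
            )
        frac = sum(tr.choice == "high" for tr in trials) / len(trials)
        out[cond] = frac >= threshold
    return out
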