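"""Hybrid model-free/model-based learner for the two-step task.

The model-free component is SARSA(λ) over the two stages with separate
learning rates α₁, α₂; λ lets the second-stage prediction error also update
the first-stage value ("stage-skipping" update).  The model-based component
evaluates first-stage actions prospectively: the better second-stage option of
each state, weighted by the true transition probabilities (the transition
matrix is not learned).  The two systems are blended at the first stage,

    Q(s_A, a) = ω·Q_MB(s_A, a) + (1 − ω)·Q_MF(s_A, a),

and coincide at the second stage.  Choices follow a softmax with stage-wise
inverse temperatures β₁, β₂ and a first-stage perseveration bonus ρ for
repeating the previous first-stage choice.  Seven free parameters in total:
(β₁, β₂, α₁, α₂, λ, ω, ρ).  All Q values start at 0.

Per-trial update order: both prediction errors are computed from pre-update
values (δ₁ from the second-stage value that informed the choice, matching the
on-policy SARSA convention), then the second-stage and first-stage values are
updated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _core
from .errors import ValidationError
from .twostep import RewardWalk, TransitionStructure, TwoStepSession, TwoStepTrial, COMMON, RARE

#: canonical parameter order used throughout the package
PARAM_NAMES = ("beta1", "beta2", "alpha1", "alpha2", "lam", "omega", "rho")

_P_FLOOR = 1e-300


@dataclass(frozen=True)
class HybridParams:
    """The 7-parameter vector of the hybrid learner."""

    beta1: float
    beta2: float
    alpha1: float
    alpha2: float
    lam: float
    omega: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValidationError("inverse temperatures beta1, beta2 must be >= 0")
        for name in ("alpha1", "alpha2", "lam", "omega"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if not math.isfinite(self.rho):
            raise ValidationError("rho must be finite")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "HybridParams":
        x = np.asarray(x, dtype=float)
        if x.shape != (len(PARAM_NAMES),):
            raise ValidationError(f"expected a 7-vector, got shape {x.shape}")
        return cls(**dict(zip(PARAM_NAMES, x)))

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


@dataclass
class QValues:
    """Model-free action values: ``q1`` at the first stage, ``q2[state, action]`` at the second."""

    q1: np.ndarray
    q2: np.ndarray

    @classmethod
    def zeros(cls) -> "QValues":
        return cls(q1=np.zeros(2), q2=np.zeros((2, 2)))

    def copy(self) -> "QValues":
        return QValues(q1=self.q1.copy(), q2=self.q2.copy())


@dataclass(frozen=True)
class TrialComputation:
    """Per-trial quantities: prediction errors, perseveration indicator, choice probabilities."""

    delta1: float
    delta2: float
    rep1: int
    p_a1: float
    p_a2: float


def mb_values(q: QValues, structure: TransitionStructure) -> np.ndarray:
    """Model-based first-stage values: transition-weighted best second-stage options."""
    best = q.q2.max(axis=1)
    out = np.empty(2)
    for a in (0, 1):
        out[a] = (
            structure.p_common * best[structure.common_map[a]]
            + (1.0 - structure.p_common) * best[1 - structure.common_map[a]]
        )
    return out


def net_values(q: QValues, structure: TransitionStructure, omega: float) -> np.ndarray:
    """ω-weighted blend of model-based and model-free first-stage values."""
    if not 0.0 <= omega <= 1.0:
        raise ValidationError(f"omega must lie in [0, 1], got {omega}")
    return omega * mb_values(q, structure) + (1.0 - omega) * q.q1


def choice_probs(
    values: np.ndarray,
    beta: float,
    rho: float = 0.0,
    prev_action: int | None = None,
) -> np.ndarray:
    """Softmax choice probabilities, p(a) ∝ exp(β·(Q(a) + ρ·rep(a))).

    ``rep(a)`` is 1 iff ``a`` equals ``prev_action``; with ``prev_action=None``
    (first trial, or the second stage) perseveration is inactive.
    """
    if beta < 0:
        raise ValidationError(f"beta must be >= 0, got {beta}")
    v = np.array(values, dtype=float)
    if prev_action is not None:
        v[prev_action] += rho
    x = beta * v
    x -= x.max()
    e = np.exp(x)
    return e / e.sum()


def apply_trial_updates(
    q: QValues,
    trial: TwoStepTrial,
    params: HybridParams,
    structure: TransitionStructure | None = None,
    prev_a1: int | None = None,
) -> tuple[QValues, TrialComputation]:
    """Apply one trial's SARSA(λ) updates; returns new values and trial diagnostics.

    Choice probabilities are computed from the *pre-update* values (they are
    the probabilities under which the recorded choices were made) and require
    ``structure``; without it they are reported as NaN.
    """
    q_new = q.copy()
    delta2 = trial.r - q.q2[trial.s2, trial.a2]
    delta1 = q.q2[trial.s2, trial.a2] - q.q1[trial.a1]
    q_new.q2[trial.s2, trial.a2] += params.alpha2 * delta2
    q_new.q1[trial.a1] += params.alpha1 * delta1 + params.alpha1 * params.lam * delta2

    rep1 = int(prev_a1 is not None and trial.a1 == prev_a1)
    if structure is not None:
        p1 = choice_probs(net_values(q, structure, params.omega), params.beta1, params.rho, prev_a1)
        p2 = choice_probs(q.q2[trial.s2], params.beta2)
        p_a1 = float(p1[trial.a1])
        p_a2 = float(p2[trial.a2])
    else:
        p_a1 = p_a2 = float("nan")
    return q_new, TrialComputation(
        delta1=float(delta1), delta2=float(delta2), rep1=rep1, p_a1=p_a1, p_a2=p_a2
    )


def session_loglik(
    session: TwoStepSession, params: HybridParams
) -> tuple[float, list[TrialComputation]]:
    """Total choice log-likelihood of a session plus per-trial diagnostics.

    Reference (object-level) path; :func:`fast_session_loglik` is the
    array-level kernel used by the fitter, and both agree to 1e-10.
    """
    if session.n_trials == 0:
        raise ValidationError(f"session {session.subject_id} is empty")
    q = QValues.zeros()
    prev: int | None = None
    total = 0.0
    comps: list[TrialComputation] = []
    for trial in session.trials:
        q, comp = apply_trial_updates(q, trial, params, structure=session.structure, prev_a1=prev)
        total += math.log(max(comp.p_a1, _P_FLOOR)) + math.log(max(comp.p_a2, _P_FLOOR))
        comps.append(comp)
        prev = trial.a1
    return total, comps


def fast_session_loglik(session: TwoStepSession, params: HybridParams) -> float:
    """Array-level total log-likelihood (numba kernel)."""
    a1, s2, a2, r = session.to_arrays()
    st = session.structure
    return float(
        _core.loglik_core(
            a1, s2, a2, r,
            st.common_map[0], st.common_map[1], st.p_common,
            params.beta1, params.beta2, params.alpha1, params.alpha2,
            params.lam, params.omega, params.rho,
        )
    )


def simulate_agent(
    params: HybridParams,
    structure: TransitionStructure,
    walk: RewardWalk,
    n_trials: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    subject_id: str = "agent",
) -> TwoStepSession:
    """Simulate one hybrid agent on the task; deterministic given the seed."""
    if n_trials is None:
        n_trials = walk.n_trials
    if n_trials > walk.n_trials:
        raise ValidationError(
            f"n_trials={n_trials} exceeds walk length {walk.n_trials}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.uniform(size=(n_trials, 4))
    a1, s2, a2, r = _core.simulate_core(
        n_trials,
        structure.common_map[0], structure.common_map[1], structure.p_common,
        walk.probs,
        params.beta1, params.beta2, params.alpha1, params.alpha2,
        params.lam, params.omega, params.rho,
        u,
    )
    return TwoStepSession.from_arrays(
        subject_id, a1, s2, a2, r, structure=structure, walk=walk
    )
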