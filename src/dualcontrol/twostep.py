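"""Generative environment for the two-step sequential decision task.

The task has a first stage (one pair of stimuli, actions 0/1) and two
second-stage states (each with actions 0/1).  Each first-stage action leads to
its "common" second-stage state with probability ``p_common`` (0.7 by default)
and to the other state otherwise.  Every second-stage action pays a unit
reward (one 20-cent gain) with a probability that drifts across trials as an
independent Gaussian random walk with reflecting boundaries.

Conventions
-----------
Actions and second-stage states are 0-indexed; trial indices are 1-based so
that "trial t" reads naturally.  The four reward-walk columns are ordered
``(state, action)`` = (0,0), (0,1), (1,0), (1,1); see :meth:`RewardWalk.arm`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError

COMMON = "common"
RARE = "rare"

#: number of second-stage (state, action) reward arms
N_ARMS = 4


@dataclass(frozen=True)
class TransitionStructure:
    """Fixed first-stage transition structure.

    Parameters
    ----------
    common_map : pair of ints
        ``common_map[a]`` is the second-stage state (0 or 1) that first-stage
        action ``a`` reaches on common transitions.  The two actions must map
        to distinct states.
    p_common : float
        Probability of the common transition; must satisfy ``0.5 < p <= 1``.
    """

    common_map: tuple[int, int] = (0, 1)
    p_common: float = 0.7

    def __post_init__(self) -> None:
        if sorted(self.common_map) != [0, 1]:
            raise ValidationError(
                f"common_map must map the two actions to distinct states 0 and 1, "
                f"got {self.common_map!r}"
            )
        if not 0.5 < self.p_common <= 1.0:
            raise ValidationError(f"p_common must lie in (0.5, 1], got {self.p_common}")

    def common_state(self, a1: int) -> int:
        return self.common_map[a1]

    def rare_state(self, a1: int) -> int:
        return 1 - self.common_map[a1]

    def transition_probs(self, a1: int) -> np.ndarray:
        """P(second-stage state | first-stage action ``a1``) as a length-2 vector."""
        p = np.empty(2)
        p[self.common_map[a1]] = self.p_common
        p[1 - self.common_map[a1]] = 1.0 - self.p_common
        return p


@dataclass(frozen=True)
class RewardWalk:
    """Drifting reward probabilities for the four second-stage arms."""

    probs: np.ndarray
    sd_innovation: float
    bounds: tuple[float, float] = (0.25, 0.75)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != N_ARMS:
            raise ValidationError(f"walk must be n_trials x {N_ARMS}, got shape {probs.shape}")
        lo, hi = self.bounds
        if probs.min() < lo - 1e-12 or probs.max() > hi + 1e-12:
            raise ValidationError("reward walk leaves its reflecting bounds")
        object.__setattr__(self, "probs", probs)

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]

    @staticmethod
    def arm(s2: int, a2: int) -> int:
        """Column index of the (state, action) arm."""
        return 2 * s2 + a2


def _reflect(x: float, lo: float, hi: float) -> float:
    # Single fold per excursion; the loop only matters for pathological step sizes.
    while x < lo or x > hi:
        if x < lo:
            x = lo + (lo - x)
        else:
            x = hi - (x - hi)
    return x


def generate_reward_walk(
    n_trials: int,
    sd_innovation: float = 0.025,
    bounds: tuple[float, float] = (0.25, 0.75),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RewardWalk:
    """Generate four independent bounded Gaussian random walks.

    The first row is drawn uniformly within ``bounds``; each subsequent row
    adds Gaussian noise with standard deviation ``sd_innovation`` and reflects
    excursions back across the violated bound.
    """
    if not isinstance(n_trials, (int, np.integer)) or n_trials <= 0:
        raise ValidationError(f"n_trials must be a positive integer, got {n_trials!r}")
    if sd_innovation <= 0:
        raise ValidationError(f"sd_innovation must be positive, got {sd_innovation}")
    lo, hi = bounds
    if not (0.0 < lo < hi < 1.0):
        raise ValidationError(f"bounds must satisfy 0 < lower < upper < 1, got {bounds}")
    if rng is None:
        rng = np.random.default_rng(seed)

    probs = np.empty((n_trials, N_ARMS))
    probs[0] = rng.uniform(lo, hi, N_ARMS)
    if n_trials > 1:
        steps = rng.normal(0.0, sd_innovation, (n_trials - 1, N_ARMS))
        for t in range(1, n_trials):
            for j in range(N_ARMS):
                probs[t, j] = _reflect(probs[t - 1, j] + steps[t - 1, j], lo, hi)
    return RewardWalk(probs=probs, sd_innovation=sd_innovation, bounds=bounds)


@dataclass(frozen=True, slots=True)
class TwoStepTrial:
    """One two-step trial: first-stage choice, transition, second-stage choice, reward."""

    t: int
    a1: int
    s2: int
    a2: int
    r: int
    transition: str


@dataclass(eq=False)
class TwoStepSession:
    """One subject's ordered two-step trials.

    ``walk`` is optional: sessions read back from trial logs carry no walk.
    """

    subject_id: str
    trials: list[TwoStepTrial]
    structure: TransitionStructure = field(default_factory=TransitionStructure)
    walk: RewardWalk | None = None

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def validate(self) -> None:
        for i, tr in enumerate(self.trials):
            if tr.t != i + 1:
                raise ValidationError(
                    f"session {self.subject_id}: trial indices must be consecutive "
                    f"from 1; position {i} holds t={tr.t}"
                )
            expected = COMMON if tr.s2 == self.structure.common_map[tr.a1] else RARE
            if tr.transition != expected:
                raise ValidationError(
                    f"session {self.subject_id}, trial {tr.t}: transition label "
                    f"{tr.transition!r} inconsistent with structure (expected {expected!r})"
                )
            if tr.a1 not in (0, 1) or tr.a2 not in (0, 1) or tr.s2 not in (0, 1):
                raise ValidationError(
                    f"session {self.subject_id}, trial {tr.t}: actions/states must be 0/1"
                )
            if tr.r not in (0, 1):
                raise ValidationError(
                    f"session {self.subject_id}, trial {tr.t}: reward must be 0 or 1"
                )

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (a1, s2, a2, r) as int64 arrays (cached)."""
        cached = getattr(self, "_arrays", None)
        if cached is None:
            a1 = np.fromiter((tr.a1 for tr in self.trials), dtype=np.int64, count=self.n_trials)
            s2 = np.fromiter((tr.s2 for tr in self.trials), dtype=np.int64, count=self.n_trials)
            a2 = np.fromiter((tr.a2 for tr in self.trials), dtype=np.int64, count=self.n_trials)
            r = np.fromiter((tr.r for tr in self.trials), dtype=np.int64, count=self.n_trials)
            cached = (a1, s2, a2, r)
            self._arrays = cached
        return cached

    @classmethod
    def from_arrays(
        cls,
        subject_id: str,
        a1: Sequence[int],
        s2: Sequence[int],
        a2: Sequence[int],
        r: Sequence[int],
        structure: TransitionStructure | None = None,
        walk: RewardWalk | None = None,
    ) -> "TwoStepSession":
        structure = structure if structure is not None else TransitionStructure()
        trials = [
            TwoStepTrial(
                t=i + 1,
                a1=int(a1[i]),
                s2=int(s2[i]),
                a2=int(a2[i]),
                r=int(r[i]),
                transition=COMMON if int(s2[i]) == structure.common_map[int(a1[i])] else RARE,
            )
            for i in range(len(a1))
        ]
        return cls(subject_id=subject_id, trials=trials, structure=structure, walk=walk)


def step(
    a1: int,
    t: int,
    structure: TransitionStructure,
    walk: RewardWalk,
    a2_supplier: Callable[[int], int],
    rng: np.random.Generator,
) -> TwoStepTrial:
    """Advance the environment one trial.

    The second-stage state is the common one with probability ``p_common``;
    the reward is Bernoulli with the walk probability of the chosen arm at
    trial ``t`` (1-based).  ``a2_supplier`` receives the realized second-stage
    state and returns the second-stage choice.
    """
    if not 1 <= t <= walk.n_trials:
        raise IndexError(f"trial index {t} outside walk range 1..{walk.n_trials}")
    if rng.uniform() < structure.p_common:
        s2 = structure.common_state(a1)
    else:
        s2 = structure.rare_state(a1)
    a2 = int(a2_supplier(s2))
    p_r = walk.probs[t - 1, RewardWalk.arm(s2, a2)]
    r = int(rng.uniform() < p_r)
    transition = COMMON if s2 == structure.common_state(a1) else RARE
    return TwoStepTrial(t=t, a1=int(a1), s2=s2, a2=a2, r=r, transition=transition)
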