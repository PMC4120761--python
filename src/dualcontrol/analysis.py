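"""Model-agnostic behavioral statistics.

Stay-probability tables for the two-step task, the 2x2 within-subject
contrasts (paired-t form of the repeated-measures ANOVA, F = t^2), the two
interaction scores used as per-subject indices of model-based and
goal-directed control, devaluation choice-window counts, and the one-tailed
Spearman rank correlation with an exact permutation tail at small n.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .devaluation import CONDITIONS, EXTINCTION, TRAINING, DevalSession
from .errors import UndefinedScoreError, ValidationError
from .twostep import COMMON, TwoStepSession

logger = logging.getLogger(__name__)

REWARDED, UNREWARDED = 0, 1  # row index of the stay table
COMMON_COL, RARE_COL = 0, 1  # column index


@dataclass(frozen=True)
class StayTable:
    """2x2 stay probabilities by previous-trial reward x previous-trial transition.

    ``p_stay[i, j]`` with rows (rewarded, unrewarded) and columns
    (common, rare); empty cells are NaN with ``n == 0``, never 0.
    """

    p_stay: np.ndarray
    n: np.ndarray

    @property
    def has_all_cells(self) -> bool:
        return bool((self.n > 0).all())

    def cell(self, rewarded: bool, common: bool) -> float:
        return float(self.p_stay[0 if rewarded else 1, 0 if common else 1])


@dataclass(frozen=True)
class ContrastResult:
    """Paired within-subject contrast with its ANOVA-equivalent F = t^2."""

    effect: str
    mean: float
    t: float
    F: float
    df: tuple[int, int]
    p: float


@dataclass(frozen=True)
class ScorePair:
    """Per-subject construct-validity scores.

    ``deval_score`` is in choices out of the analysis windows; ``mb_score``
    is a stay-probability difference in [-2, 2].
    """

    subject_id: str
    deval_score: float
    mb_score: float
    omega_map: float | None = None


def stay_table(session: TwoStepSession) -> StayTable:
    """Tabulate first-stage stay behavior by the previous trial's reward and transition.

    Trial 1 has no predecessor and is excluded.
    """
    if session.n_trials < 2:
        raise ValidationError(
            f"session {session.subject_id}: need >= 2 trials for a stay table"
        )
    a1, _, _, r = session.to_arrays()
    common = np.fromiter(
        (tr.transition == COMMON for tr in session.trials), dtype=bool, count=session.n_trials
    )
    stay = (a1[1:] == a1[:-1]).astype(float)
    row = np.where(r[:-1] == 1, REWARDED, UNREWARDED)
    col = np.where(common[:-1], COMMON_COL, RARE_COL)

    p = np.full((2, 2), np.nan)
    n = np.zeros((2, 2), dtype=int)
    for i in (0, 1):
        for j in (0, 1):
            mask = (row == i) & (col == j)
            n[i, j] = int(mask.sum())
            if n[i, j]:
                p[i, j] = stay[mask].mean()
    return StayTable(p_stay=p, n=n)


def mb_interaction_score(table: StayTable) -> float:
    """Reward x transition interaction on stay probabilities:
    (rewarded-common − rewarded-rare) − (unrewarded-common − unrewarded-rare).

    Higher values indicate more model-based control.
    """
    if not table.has_all_cells:
        raise UndefinedScoreError("stay table has empty cells; interaction score undefined")
    p = table.p_stay
    return float((p[0, 0] - p[0, 1]) - (p[1, 0] - p[1, 1]))


def reward_main_effect_score(table: StayTable) -> float:
    """Main effect of previous reward on stay probability (model-free index)."""
    if not table.has_all_cells:
        raise UndefinedScoreError("stay table has empty cells; main-effect score undefined")
    p = table.p_stay
    return float(p[0].mean() - p[1].mean())


def _paired_contrast(values: np.ndarray, effect: str) -> ContrastResult:
    n = len(values)
    res = stats.ttest_1samp(values, 0.0)
    t = float(res.statistic)
    if not math.isfinite(t):  # zero variance around a zero mean
        t = 0.0
    p = float(res.pvalue) if math.isfinite(res.pvalue) else 1.0
    return ContrastResult(
        effect=effect, mean=float(values.mean()), t=t, F=t * t, df=(1, n - 1), p=p
    )


def reward_and_interaction_contrasts(
    tables: list[StayTable],
) -> tuple[ContrastResult, ContrastResult]:
    """Group-level main effect of reward and reward x transition interaction.

    Each subject contributes one main-effect contrast (mean of rewarded cells
    minus mean of unrewarded cells) and one interaction contrast; paired t
    tests against zero give the exact 2x2 within-subject ANOVA (F = t^2,
    df = (1, n-1)).  Subjects with empty cells are dropped.
    """
    main, inter = [], []
    n_dropped = 0
    for tab in tables:
        if not tab.has_all_cells:
            n_dropped += 1
            continue
        main.append(reward_main_effect_score(tab))
        inter.append(mb_interaction_score(tab))
    if n_dropped:
        logger.warning("dropped %d subject(s) with incomplete stay tables", n_dropped)
    if len(main) < 3:
        raise ValidationError(
            f"need >= 3 subjects with all four stay-table cells, got {len(main)}"
        )
    return (
        _paired_contrast(np.asarray(main), "reward"),
        _paired_contrast(np.asarray(inter), "reward_x_transition"),
    )


def deval_choice_counts(session: DevalSession, window: int = 10) -> pd.DataFrame:
    """High-probability choice counts per condition in the last ``window``
    training trials and first ``window`` extinction trials of that condition.

    Returns a 2x3 DataFrame indexed ("pre", "post") x condition.
    """
    counts = pd.DataFrame(
        0, index=["pre", "post"], columns=list(CONDITIONS), dtype=int
    )
    for cond in CONDITIONS:
        train = session.phase_trials(TRAINING, cond)
        ext = session.phase_trials(EXTINCTION, cond)
        if len(train) < window or len(ext) < window:
            raise ValidationError(
                f"session {session.subject_id}, condition {cond!r}: "
                f"need >= {window} trials per phase "
                f"(got {len(train)} training, {len(ext)} extinction)"
            )
        counts.loc["pre", cond] = sum(tr.choice == "high" for tr in train[-window:])
        counts.loc["post", cond] = sum(tr.choice == "high" for tr in ext[:window])
    return counts


def deval_interaction_score(counts: pd.DataFrame, literal_formula: bool = False) -> float:
    """Devaluation interaction score from the pre/post choice counts.

    Default orientation: (devalued_pre − devalued_post) − (valued_pre −
    valued_post), under which a higher score means more goal-directed
    behavior (a devaluation-specific drop in choosing the devalued stimulus).
    ``literal_formula=True`` returns the opposite orientation,
    (valued_pre − valued_post) − (devalued_pre − devalued_post).
    """
    score = (counts.loc["pre", "devalued"] - counts.loc["post", "devalued"]) - (
        counts.loc["pre", "valued"] - counts.loc["post", "valued"]
    )
    return float(-score if literal_formula else score)


def spearman_onetailed(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a one-tailed p for positive association.

    rho is the Pearson correlation of (average-tie) ranks.  For n <= 9 the
    p-value is the exact permutation tail (fraction of the n! rank
    permutations with rho at least as large as observed); for larger n a
    t approximation with df = n - 2 is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d arrays")
    n = len(x)
    if n < 4:
        raise ValidationError(f"need n >= 4, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedScoreError("constant input: Spearman rho undefined")

    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt((rxc**2).sum() * (ryc**2).sum())
    rho = float((rxc * ryc).sum() / denom)

    if n <= 9:
        perms = np.array(list(itertools.permutations(ryc)))
        rhos = perms @ rxc / denom
        p = float((rhos >= rho - 1e-12).mean())
    else:
        if abs(rho) >= 1.0:
            p = 0.0 if rho > 0 else 1.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(stats.t.sf(t, df=n - 2))
    return rho, p
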