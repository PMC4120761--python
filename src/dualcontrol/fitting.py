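"""Hierarchical empirical-Bayes estimation of the hybrid learner's parameters.

Parameters are fitted on an unconstrained scale (log for the inverse
temperatures, logit for the unit-interval parameters, identity for the
perseveration bonus) under an independent Gaussian group prior.  The E-step
computes per-subject maximum-a-posteriori estimates by multi-start L-BFGS-B
with a diagonal-Laplace approximation of the posterior variance; the M-step
moment-matches the prior to the subject-level estimates, including the
Laplace variances, with a floor preventing prior collapse.  Iterating to
convergence gives the full empirical-Bayes EM; a single iteration reproduces
the "set the prior once from the pooled fit" reading.

The estimator class :class:`EmpiricalBayesHybridFitter` wraps this in the
scikit-learn fit/attributes idiom; :func:`em_fit` and :func:`map_fit` are the
functional interface.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import _core
from .errors import FitError, ValidationError
from .hybrid import PARAM_NAMES, HybridParams
from .twostep import TwoStepSession

logger = logging.getLogger(__name__)

#: indices of log-transformed (beta) and logit-transformed coordinates
_EXP_IDX = np.array([0, 1])
_LOGIT_IDX = np.array([2, 3, 4, 5])
_BOUND_CLIP = 1e-9
_Y_EXP_MAX = 100.0  # keeps exp() finite; far beyond any plausible temperature


def transform(params: HybridParams) -> np.ndarray:
    """Map parameters to the unconstrained scale (log / logit / identity).

    Unit-interval parameters exactly at 0 or 1 are clipped to
    [1e-9, 1 - 1e-9] with a logged warning.
    """
    x = params.to_array()
    y = np.empty_like(x)
    y[_EXP_IDX] = np.log(np.maximum(x[_EXP_IDX], 1e-12))
    b = x[_LOGIT_IDX]
    if (b <= 0).any() or (b >= 1).any():
        logger.warning("clipping unit-interval parameter(s) at the boundary before logit")
        b = np.clip(b, _BOUND_CLIP, 1.0 - _BOUND_CLIP)
    y[_LOGIT_IDX] = np.log(b / (1.0 - b))
    y[6] = x[6]
    return y


def inverse_transform(y: np.ndarray) -> HybridParams:
    """Map an unconstrained 7-vector back to the natural parameter scale."""
    y = np.asarray(y, dtype=float)
    if y.shape != (7,):
        raise ValidationError(f"expected a 7-vector, got shape {y.shape}")
    x = np.empty(7)
    x[_EXP_IDX] = np.exp(np.minimum(y[_EXP_IDX], _Y_EXP_MAX))
    x[_LOGIT_IDX] = expit(y[_LOGIT_IDX])
    x[6] = y[6]
    return HybridParams.from_array(x)


@dataclass(frozen=True)
class PriorMoments:
    """Independent Gaussian group prior on the unconstrained scale."""

    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma2 = np.asarray(self.sigma2, dtype=float)
        if mu.shape != (7,) or sigma2.shape != (7,):
            raise ValidationError("prior moments must be 7-vectors")
        if (sigma2 <= 0).any():
            raise ValidationError("prior variances must be strictly positive")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma2", sigma2)


#: broad default prior: beta centered at 1, unit-interval parameters at 0.5
DEFAULT_PRIOR = PriorMoments(mu=np.zeros(7), sigma2=np.full(7, 4.0))


@dataclass
class SubjectFit:
    subject_id: str
    y_map: np.ndarray
    params_map: HybridParams
    laplace_var: np.ndarray
    log_post: float
    n_restarts_used: int


@dataclass
class GroupFit:
    """Group prior, per-subject MAP fits, and EM diagnostics."""

    prior: PriorMoments
    subjects: list[SubjectFit]
    em_iterations: int
    converged: bool
    trajectory: list[float]

    def trajectory_is_monotone(self, tol: float = 1e-3) -> bool:
        return all(b - a >= -tol for a, b in zip(self.trajectory, self.trajectory[1:]))

    def params_table(self) -> pd.DataFrame:
        rows = [
            {"subject_id": s.subject_id, **s.params_map.to_dict(), "log_post": s.log_post}
            for s in self.subjects
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "prior": {"mu": self.prior.mu.tolist(), "sigma2": self.prior.sigma2.tolist()},
            "param_names": list(PARAM_NAMES),
            "em_iterations": self.em_iterations,
            "converged": self.converged,
            "trajectory": [float(v) for v in self.trajectory],
            "subjects": [
                {
                    "subject_id": s.subject_id,
                    "y_map": s.y_map.tolist(),
                    "params_map": s.params_map.to_dict(),
                    "laplace_var": s.laplace_var.tolist(),
                    "log_post": float(s.log_post),
                    "n_restarts_used": s.n_restarts_used,
                }
                for s in self.subjects
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupFit":
        prior = PriorMoments(np.asarray(d["prior"]["mu"]), np.asarray(d["prior"]["sigma2"]))
        subjects = [
            SubjectFit(
                subject_id=s["subject_id"],
                y_map=np.asarray(s["y_map"]),
                params_map=HybridParams(**s["params_map"]),
                laplace_var=np.asarray(s["laplace_var"]),
                log_post=s["log_post"],
                n_restarts_used=s["n_restarts_used"],
            )
            for s in d["subjects"]
        ]
        return cls(
            prior=prior,
            subjects=subjects,
            em_iterations=d["em_iterations"],
            converged=d["converged"],
            trajectory=list(d["trajectory"]),
        )


def _session_data(session: TwoStepSession) -> tuple:
    a1, s2, a2, r = session.to_arrays()
    st = session.structure
    return (a1, s2, a2, r, st.common_map[0], st.common_map[1], st.p_common)


def _loglik_y(y: np.ndarray, data: tuple) -> float:
    beta1 = math.exp(min(y[0], _Y_EXP_MAX))
    beta2 = math.exp(min(y[1], _Y_EXP_MAX))
    alpha1 = float(expit(y[2]))
    alpha2 = float(expit(y[3]))
    lam = float(expit(y[4]))
    omega = float(expit(y[5]))
    return _core.loglik_core(
        *data, beta1, beta2, alpha1, alpha2, lam, omega, y[6]
    )


def _neg_log_post(y: np.ndarray, data: tuple, prior: PriorMoments) -> float:
    lp = -0.5 * np.sum((y - prior.mu) ** 2 / prior.sigma2) - 0.5 * np.sum(
        np.log(2.0 * np.pi * prior.sigma2)
    )
    return -(_loglik_y(y, data) + lp)


def map_fit(
    session: TwoStepSession,
    prior: PriorMoments = DEFAULT_PRIOR,
    n_restarts: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    warm_start: np.ndarray | None = None,
) -> SubjectFit:
    """Per-subject MAP estimate with diagonal-Laplace posterior variances.

    Runs ``n_restarts`` L-BFGS-B optimizations: one from the prior mean, one
    from ``warm_start`` if given, the rest from draws of the prior.  Raises
    :class:`FitError` (carrying the best partial result) only if no start
    yields a finite objective.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    data = _session_data(session)
    sd = np.sqrt(prior.sigma2)

    starts = [prior.mu.copy()]
    if warm_start is not None:
        starts.append(np.asarray(warm_start, dtype=float))
    while len(starts) < n_restarts:
        starts.append(prior.mu + sd * rng.standard_normal(7))

    best = None
    for y0 in starts:
        res = minimize(
            _neg_log_post,
            y0,
            args=(data, prior),
            method="L-BFGS-B",
            options={"maxiter": 300},
        )
        if math.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitError(f"all {len(starts)} restarts diverged for {session.subject_id}")

    y_map = best.x
    f0 = best.fun
    laplace_var = np.empty(7)
    for k in range(7):
        h = 1e-3 * (1.0 + abs(y_map[k]))
        yp = y_map.copy(); yp[k] += h
        ym = y_map.copy(); ym[k] -= h
        d2 = (_neg_log_post(yp, data, prior) - 2.0 * f0 + _neg_log_post(ym, data, prior)) / (h * h)
        # fall back to the prior variance where curvature is non-positive
        laplace_var[k] = 1.0 / d2 if d2 > 1e-12 else prior.sigma2[k]

    return SubjectFit(
        subject_id=session.subject_id,
        y_map=y_map,
        params_map=inverse_transform(y_map),
        laplace_var=laplace_var,
        log_post=-f0,
        n_restarts_used=len(starts),
    )


@dataclass
class EMConfig:
    max_iter: int = 50
    tol: float = 1e-3
    n_restarts: int = 10
    variance_floor: float = 1e-4
    seed: int = 0
    prior: PriorMoments = field(default_factory=lambda: DEFAULT_PRIOR)


def em_fit(sessions: list[TwoStepSession], config: EMConfig | None = None) -> GroupFit:
    """Empirical-Bayes EM over a cohort of sessions.

    E-step: MAP fit per subject under the current prior (warm-started from
    the previous iteration).  M-step: prior mean = mean of the MAP estimates;
    prior variance = second moment including Laplace variances minus the
    squared mean, floored at ``variance_floor``.  Stops when the summed
    per-subject penalized log-likelihood improves by less than ``tol``.
    Non-convergence yields ``converged=False``, not an exception.
    """
    if config is None:
        config = EMConfig()
    if len(sessions) < 2:
        raise ValidationError(f"EM needs >= 2 sessions, got {len(sessions)}")
    rng = np.random.default_rng(config.seed)
    prior = config.prior
    warm: list[np.ndarray | None] = [None] * len(sessions)
    trajectory: list[float] = []
    fits: list[SubjectFit] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        fits = [
            map_fit(
                s, prior, n_restarts=config.n_restarts, rng=rng, warm_start=warm[i]
            )
            for i, s in enumerate(sessions)
        ]
        obj = float(sum(f.log_post for f in fits))
        trajectory.append(obj)
        if len(trajectory) >= 2 and obj - trajectory[-2] < config.tol:
            converged = True
            break
        y = np.stack([f.y_map for f in fits])
        v = np.stack([f.laplace_var for f in fits])
        mu = y.mean(axis=0)
        sigma2 = np.maximum((y**2 + v).mean(axis=0) - mu**2, config.variance_floor)
        prior = PriorMoments(mu=mu, sigma2=sigma2)
        warm = [f.y_map for f in fits]
    return GroupFit(
        prior=prior,
        subjects=fits,
        em_iterations=it,
        converged=converged,
        trajectory=trajectory,
    )


class EmpiricalBayesHybridFitter(BaseEstimator):
    """Scikit-learn-style estimator for the hierarchical empirical-Bayes fit.

    Parameters
    ----------
    max_iter : int
        Maximum EM iterations (``max_iter=1`` reproduces the set-the-prior-
        once variant).
    tol : float
        Convergence tolerance on the summed penalized log-likelihood.
    n_restarts : int
        Optimizer restarts per subject and EM iteration.
    variance_floor : float
        Lower bound on the group prior variances.
    prior_mu, prior_sigma2 : array-like of shape (7,), optional
        Initial prior moments on the unconstrained scale; defaults to a broad
        prior centered at beta = 1 and midpoints of the unit intervals.
    random_state : int, optional
        Seed for the restart draws.

    Attributes
    ----------
    group_fit_ : GroupFit
    prior_mu_, prior_sigma2_ : final prior moments
    omega_map_ : per-subject fitted model-based weights
    trajectory_, n_iter_, converged_ : EM diagnostics
    """

    def __init__(
        self,
        max_iter: int = 50,
        tol: float = 1e-3,
        n_restarts: int = 10,
        variance_floor: float = 1e-4,
        prior_mu=None,
        prior_sigma2=None,
        random_state: int | None = None,
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.variance_floor = variance_floor
        self.prior_mu = prior_mu
        self.prior_sigma2 = prior_sigma2
        self.random_state = random_state

    def fit(self, X: list[TwoStepSession], y=None) -> "EmpiricalBayesHybridFitter":
        """Fit the group prior and per-subject MAP estimates from sessions ``X``."""
        prior = PriorMoments(
            mu=np.asarray(self.prior_mu, float) if self.prior_mu is not None else np.zeros(7),
            sigma2=np.asarray(self.prior_sigma2, float)
            if self.prior_sigma2 is not None
            else np.full(7, 4.0),
        )
        config = EMConfig(
            max_iter=self.max_iter,
            tol=self.tol,
            n_restarts=self.n_restarts,
            variance_floor=self.variance_floor,
            seed=self.random_state if self.random_state is not None else 0,
            prior=prior,
        )
        gf = em_fit(list(X), config)
        self.group_fit_ = gf
        self.prior_mu_ = gf.prior.mu
        self.prior_sigma2_ = gf.prior.sigma2
        self.subjects_ = gf.subjects
        self.omega_map_ = np.array([s.params_map.omega for s in gf.subjects])
        self.trajectory_ = list(gf.trajectory)
        self.n_iter_ = gf.em_iterations
        self.converged_ = gf.converged
        return self

    def params_table(self) -> pd.DataFrame:
        check_is_fitted(self, "group_fit_")
        return self.group_fit_.params_table()


def save_group_fit(group_fit: GroupFit, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(group_fit.to_dict(), fh, indent=2)


def load_group_fit(path) -> GroupFit:
    with open(path, encoding="utf-8") as fh:
        return GroupFit.from_dict(json.load(fh))
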