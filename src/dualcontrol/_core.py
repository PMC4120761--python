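"""Numerical inner loops for the hybrid learner.

These array-level kernels back the likelihood evaluation used by the
hierarchical fit and the large-cohort simulations.  They are jitted with
numba when available and fall back to pure Python otherwise; the rich
object-level path in :mod:`dualcontrol.hybrid` is the readable reference
implementation, and the test suite asserts both paths agree to 1e-10.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(func):
            return func

        return deco


_P_FLOOR = 1e-300


@njit(cache=True)
def loglik_core(
    a1, s2, a2, r,
    c0, c1, p_common,
    beta1, beta2, alpha1, alpha2, lam, omega, rho,
):
    """Total choice log-likelihood of one session under the hybrid learner."""
    n = a1.shape[0]
    q1 = np.zeros(2)
    q2 = np.zeros((2, 2))
    prev = -1
    total = 0.0
    for t in range(n):
        # model-based first-stage values from the true transition probabilities
        best0 = q2[0, 0] if q2[0, 0] >= q2[0, 1] else q2[0, 1]
        best1 = q2[1, 0] if q2[1, 0] >= q2[1, 1] else q2[1, 1]
        mb0 = p_common * (best0 if c0 == 0 else best1) + (1.0 - p_common) * (best1 if c0 == 0 else best0)
        mb1 = p_common * (best0 if c1 == 0 else best1) + (1.0 - p_common) * (best1 if c1 == 0 else best0)
        v0 = omega * mb0 + (1.0 - omega) * q1[0]
        v1 = omega * mb1 + (1.0 - omega) * q1[1]
        if prev == 0:
            v0 += rho
        elif prev == 1:
            v1 += rho
        x0 = beta1 * v0
        x1 = beta1 * v1
        m = x0 if x0 >= x1 else x1
        e0 = np.exp(x0 - m)
        e1 = np.exp(x1 - m)
        p = (e0 if a1[t] == 0 else e1) / (e0 + e1)
        total += np.log(p if p > _P_FLOOR else _P_FLOOR)

        s = s2[t]
        y0 = beta2 * q2[s, 0]
        y1 = beta2 * q2[s, 1]
        m2 = y0 if y0 >= y1 else y1
        f0 = np.exp(y0 - m2)
        f1 = np.exp(y1 - m2)
        p2 = (f0 if a2[t] == 0 else f1) / (f0 + f1)
        total += np.log(p2 if p2 > _P_FLOOR else _P_FLOOR)

        # SARSA(lambda) updates; delta1 uses the pre-update second-stage value
        d2 = r[t] - q2[s, a2[t]]
        d1 = q2[s, a2[t]] - q1[a1[t]]
        q2[s, a2[t]] += alpha2 * d2
        q1[a1[t]] += alpha1 * d1 + alpha1 * lam * d2
        prev = a1[t]
    return total


@njit(cache=True)
def simulate_core(
    n, c0, c1, p_common, probs,
    beta1, beta2, alpha1, alpha2, lam, omega, rho,
    u,
):
    """Simulate one hybrid agent on the two-step task.

    ``u`` is an (n, 4) matrix of uniform draws consumed in the order
    first-stage choice, transition, second-stage choice, reward; ``probs``
    is the reward walk.  Returns (a1, s2, a2, r) int64 arrays.
    """
    a1 = np.empty(n, dtype=np.int64)
    s2 = np.empty(n, dtype=np.int64)
    a2 = np.empty(n, dtype=np.int64)
    r = np.empty(n, dtype=np.int64)
    q1 = np.zeros(2)
    q2 = np.zeros((2, 2))
    prev = -1
    for t in range(n):
        best0 = q2[0, 0] if q2[0, 0] >= q2[0, 1] else q2[0, 1]
        best1 = q2[1, 0] if q2[1, 0] >= q2[1, 1] else q2[1, 1]
        mb0 = p_common * (best0 if c0 == 0 else best1) + (1.0 - p_common) * (best1 if c0 == 0 else best0)
        mb1 = p_common * (best0 if c1 == 0 else best1) + (1.0 - p_common) * (best1 if c1 == 0 else best0)
        v0 = omega * mb0 + (1.0 - omega) * q1[0]
        v1 = omega * mb1 + (1.0 - omega) * q1[1]
        if prev == 0:
            v0 += rho
        elif prev == 1:
            v1 += rho
        x0 = beta1 * v0
        x1 = beta1 * v1
        m = x0 if x0 >= x1 else x1
        e0 = np.exp(x0 - m)
        e1 = np.exp(x1 - m)
        p0 = e0 / (e0 + e1)
        a = 0 if u[t, 0] < p0 else 1
        a1[t] = a

        common = c0 if a == 0 else c1
        s = common if u[t, 1] < p_common else 1 - common
        s2[t] = s

        y0 = beta2 * q2[s, 0]
        y1 = beta2 * q2[s, 1]
        m2 = y0 if y0 >= y1 else y1
        f0 = np.exp(y0 - m2)
        f1 = np.exp(y1 - m2)
        p20 = f0 / (f0 + f1)
        b = 0 if u[t, 2] < p20 else 1
        a2[t] = b

        rew = 1 if u[t, 3] < probs[t, 2 * s + b] else 0
        r[t] = rew

        d2 = rew - q2[s, b]
        d1 = q2[s, b] - q1[a]
        q2[s, b] += alpha2 * d2
        q1[a] += alpha1 * d1 + alpha1 * lam * d2
        prev = a
    return a1, s2, a2, r
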