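"""Independent step-wise oracle for the hybrid learner's likelihood.

Deliberately written in a different style from the package implementation
(dict-keyed state values, explicit softmax normalization, no log-sum-exp, no
arrays) so that agreement between the two is a meaningful cross-check.
"""

import math


def oracle_session_loglik(a1s, s2s, a2s, rs, params, common_map=(0, 1), p_common=0.7):
    """Hand-rolled trial-by-trial log-likelihood.

    ``params`` is a dict with keys beta1, beta2, alpha1, alpha2, lam, omega,
    rho.  Second-stage states 0/1 are named B/C internally.
    """
    name = {0: "B", 1: "C"}
    Q = {(s, a): 0.0 for s in "ABC" for a in (0, 1)}
    prev = None
    ll = 0.0
    for a1, s2, a2, r in zip(a1s, s2s, a2s, rs):
        mb = {}
        for a in (0, 1):
            sc, sr = name[common_map[a]], name[1 - common_map[a]]
            mb[a] = p_common * max(Q[(sc, 0)], Q[(sc, 1)]) + (1 - p_common) * max(
                Q[(sr, 0)], Q[(sr, 1)]
            )
        net = {a: params["omega"] * mb[a] + (1 - params["omega"]) * Q[("A", a)] for a in (0, 1)}
        rep = {a: (1.0 if prev == a else 0.0) for a in (0, 1)}
        weight = {
            a: math.exp(params["beta1"] * (net[a] + params["rho"] * rep[a])) for a in (0, 1)
        }
        p1 = weight[a1] / (weight[0] + weight[1])

        sn = name[s2]
        weight2 = {a: math.exp(params["beta2"] * Q[(sn, a)]) for a in (0, 1)}
        p2 = weight2[a2] / (weight2[0] + weight2[1])

        ll += math.log(p1) + math.log(p2)

        delta2 = r - Q[(sn, a2)]
        delta1 = Q[(sn, a2)] - Q[("A", a1)]
        Q[(sn, a2)] += params["alpha2"] * delta2
        Q[("A", a1)] += params["alpha1"] * delta1 + params["alpha1"] * params["lam"] * delta2
        prev = a1
    return ll
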