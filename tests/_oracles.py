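"""Independent reference implementations used as oracles in the tests.

Everything here is written with explicit per-node loops and the transition
formulas substituted directly, deliberately sharing no code with the
vectorized solver it checks.
"""

import numpy as np


def reference_step(P, beta_bar, lam_bar, params, adj, mode="conserving", leading="rate"):
    """One probability update by direct symbolic substitution, node by node."""
    n = P.shape[0]
    mu, delta, eps, s0 = params.mu, params.delta, params.eps, params.s
    out = np.zeros_like(P)
    for i in range(n):
        q = (1 - beta_bar[i]) if leading == "rate" else (1 - s0)
        r = 1 - lam_bar[i]
        for j in range(n):
            if adj[j, i]:
                p_inf = P[j, 3] + P[j, 4]
                p_aw = P[j, 1] + P[j, 3] + P[j, 5]
                q *= 1 - p_inf * beta_bar[i]
                r *= 1 - p_aw * lam_bar[j]
        pSU, pSA, pSF, pIA, pIAP, pRA, pRAP, pRF = P[i]
        out[i, 0] = r * pSU
        out[i, 1] = q * pSA + (1 - r) * (1 - delta) * pSU
        out[i, 2] = delta * (1 - r) * pSU
        out[i, 3] = (1 - q) * (1 - eps) * pSA + (1 - mu) * pIA
        out[i, 4] = eps * (1 - q) * (1 - mu) * pSA
        out[i, 5] = mu * (1 - delta) * (1 - eps) * pIA
        out[i, 6] = mu * eps * (1 - q) * pSA + mu * eps * (1 - delta) * pIA
        out[i, 7] = mu * delta * pIA
        if mode == "conserving":
            out[i, 2] += pSF
            out[i, 4] += (1 - mu) * pIAP
            out[i, 5] += pRA
            out[i, 6] += pRAP + mu * pIAP
            out[i, 7] += pRF
    return out


def random_valid_state(rng, n):
    """A random N x 8 probability matrix with unit row sums."""
    P = rng.random((n, 8))
    return P / P.sum(axis=1, keepdims=True)
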