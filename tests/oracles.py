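"""Independent scalar-loop implementations used as test oracles.

Everything here is written with explicit Python loops over rows and
columns, straight from the defining formulas, deliberately sharing no code
with the package implementation.
"""

import math

import numpy as np


def psi_s(x: float) -> float:
    return 0.0 if x <= 0.0 or x >= 1.0 else -x * math.log(x)


def effective_weights_oracle(g, w=None):
    g = np.asarray(g, dtype=float)
    n, k = g.shape
    w = [1.0] * n if w is None else list(w)
    W = sum(w)
    return [sum(w[r] * g[r, c] for r in range(n)) / W for c in range(k)]


def ent_oracle(g, i, j):
    g = np.asarray(g, dtype=float)
    total = 0.0
    for r in range(g.shape[0]):
        total += psi_s(g[r, i]) + psi_s(g[r, j]) - psi_s(min(g[r, i] + g[r, j], 1.0))
    return -total


def nent1_oracle(g, i, j):
    g = np.asarray(g, dtype=float)
    rho = effective_weights_oracle(g)
    return ent_oracle(g, i, j) / (g.shape[0] * (rho[i] + rho[j]))


def pair_entropy_oracle(g, i, j):
    rho = effective_weights_oracle(g)
    t = rho[i] + rho[j]
    return psi_s(rho[i] / t) + psi_s(rho[j] / t)


def _zhat_row(row, candidates):
    best = candidates[0]
    for c in candidates[1:]:
        if row[c] > row[best]:
            best = c
    return best


def demp_oracle(g, i, j):
    g = np.asarray(g, dtype=float)
    n, k = g.shape
    mass_i = sum(g[r, i] for r in range(n))
    mass_j = sum(g[r, j] for r in range(n))
    m_ji = sum(g[r, i] for r in range(n)
               if _zhat_row(g[r], list(range(k))) == j) / mass_i
    m_ij = sum(g[r, j] for r in range(n)
               if _zhat_row(g[r], list(range(k))) == i) / mass_j
    return -max(m_ji, m_ij)


def demp2_oracle(g, i, j):
    g = np.asarray(g, dtype=float)
    n = g.shape[0]
    cand = sorted([i, j])
    mass_i = sum(g[r, i] for r in range(n))
    mass_j = sum(g[r, j] for r in range(n))
    m_ji = sum(g[r, i] for r in range(n) if _zhat_row(g[r], cand) == j) / mass_i
    m_ij = sum(g[r, j] for r in range(n) if _zhat_row(g[r], cand) == i) / mass_j
    return -max(m_ji, m_ij)


def mc_oracle(g, w=None):
    g = np.asarray(g, dtype=float)
    n, k = g.shape
    w = [1.0] * n if w is None else list(w)
    W = sum(w)
    rho = effective_weights_oracle(g, w)
    first = sum(psi_s(r) for r in rho)
    second = sum((w[r] / W) * sum(psi_s(g[r, c]) for c in range(k))
                 for r in range(n))
    return first - second


def mc_pair_oracle(g, i, j):
    g = np.asarray(g, dtype=float)
    n = g.shape[0]
    s = [g[r, i] + g[r, j] for r in range(n)]
    cond = [[g[r, i] / s[r], g[r, j] / s[r]] if s[r] > 0 else [0.5, 0.5]
            for r in range(n)]
    return mc_oracle(np.array(cond), s)


def nmc_pair_oracle(g, i, j):
    return mc_pair_oracle(g, i, j) / pair_entropy_oracle(g, i, j)


def nmc0_oracle(g):
    rho = effective_weights_oracle(g)
    return mc_oracle(g) / sum(psi_s(r) for r in rho)


ORACLES = {
    "ent": ent_oracle,
    "nent1": nent1_oracle,
    "demp": demp_oracle,
    "demp2": demp2_oracle,
    "mc": mc_pair_oracle,
    "nmc": nmc_pair_oracle,
}


def random_gamma(rng, n, k, concentration=0.6):
    """A random row-stochastic matrix with Dirichlet rows."""
    return rng.dirichlet(np.full(k, concentration), size=n)
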