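"""Pairwise merging criteria and mixture complexity.

Six criteria measure how overlapped a pair of mixture components (i, j) is,
all computed from the posterior matrix alone and all oriented so that a
*smaller* value means "merge first":

- ``ent``   : entropy criterion — the reduction in latent-variable entropy
              achieved by merging the pair (always <= 0).
- ``nent1`` : ``ent`` normalized by the pair's effective mass N(rho_i+rho_j),
              making it invariant to the scale of the pair's weights.
- ``demp``  : negative directly-estimated misclassification probability,
              with the hard assignment taken over *all* current components.
- ``demp2`` : as ``demp`` but with the argmax restricted to {i, j}.
- ``mc``    : mixture complexity of the pair's conditional two-column
              sub-problem, weighted by the pair's posterior mass.
- ``nmc``   : ``mc`` divided by the pair's weight entropy — the normalized
              mixture complexity, in [0, 1].  Identity: nmc = 1 + nent2
              where nent2 = nent1 / pair_entropy.

``mixture_complexity`` is the model-level functional
MC = sum_k Psi(rho_k) - sum_n (w_n / W) sum_k Psi(gamma_k(x_n)),
a real-valued generalization of ln(#clusters) in [0, ln K]; ``nmc0`` is its
weight-entropy-normalized version used as the stopping threshold.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from math import log

import numpy as np

from .errors import DegeneratePairError, DomainError, UndefinedNMCError
from .posterior import (
    PosteriorMatrix,
    _gamma_array,
    _weight_array,
    effective_weights,
    psi,
)

__all__ = [
    "Criterion",
    "ALL_CRITERIA",
    "PairScore",
    "crit_ent",
    "crit_nent1",
    "crit_demp",
    "crit_demp2",
    "crit_mc",
    "crit_nmc",
    "pair_entropy",
    "mixture_complexity",
    "nmc0",
    "evaluate_criterion",
    "criterion_best",
    "criterion_worst",
]

LN2 = log(2.0)


class Criterion(str, enum.Enum):
    """Closed enumeration of merging criteria (nmc is identical to nent2)."""

    ENT = "ent"
    NENT1 = "nent1"
    DEMP = "demp"
    DEMP2 = "demp2"
    MC = "mc"
    NMC = "nmc"

    @classmethod
    def coerce(cls, value) -> "Criterion":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise DomainError(
                f"unknown criterion {value!r}; expected one of "
                f"{[c.value for c in cls]}") from None


ALL_CRITERIA = tuple(Criterion)


@dataclass(frozen=True)
class PairScore:
    """A criterion value for an unordered component pair, canonically i < j."""

    i: int
    j: int
    value: float

    def __post_init__(self):
        if self.i >= self.j:
            object.__setattr__(self, "i", min(self.i, self.j))
            object.__setattr__(self, "j", max(self.i, self.j))


def _pair(gamma, i, j):
    g = _gamma_array(gamma)
    i, j = int(i), int(j)
    if i == j:
        raise DomainError("criterion requires two distinct components")
    K = g.shape[1]
    if not (0 <= i < K and 0 <= j < K):
        raise DomainError(f"column out of range for K={K}")
    return g, i, j


def crit_ent(gamma, i, j) -> float:
    """Entropy criterion: -(sum_n Psi(g_i) + Psi(g_j) - Psi(g_i + g_j)).

    By concavity of Psi each summand is nonnegative, so the value is <= 0;
    it is 0 exactly when the pair's supports are disjoint.
    """
    g, i, j = _pair(gamma, i, j)
    gi, gj = g[:, i], g[:, j]
    return float(-(psi(gi) + psi(gj) - psi(np.minimum(gi + gj, 1.0))).sum())


def crit_nent1(gamma, i, j) -> float:
    """Scale-corrected entropy criterion crit_ent / (N (rho_i + rho_j))."""
    g, i, j = _pair(gamma, i, j)
    mass = g[:, i].sum() + g[:, j].sum()  # = N (rho_i + rho_j)
    if mass <= 0:
        raise DegeneratePairError("pair has zero effective mass")
    return crit_ent(g, i, j) / mass


def pair_entropy(gamma, i, j, w=None) -> float:
    """Entropy of the pair's relative weights, in [0, ln 2].

    H_{i,j}(Z) = Psi(rho_i / (rho_i + rho_j)) + Psi(rho_j / (rho_i + rho_j)).
    Maximal iff the two effective weights are equal.
    """
    g, i, j = _pair(gamma, i, j)
    rho = effective_weights(g, w)
    t = rho[i] + rho[j]
    if t <= 0:
        raise DegeneratePairError("pair has zero effective mass")
    return float(psi(rho[i] / t) + psi(rho[j] / t))


def _demp_from_assignment(g, i, j, zhat) -> float:
    mass_i, mass_j = g[:, i].sum(), g[:, j].sum()
    if mass_i <= 0 or mass_j <= 0:
        raise DegeneratePairError("demp requires both components nonempty")
    m_ji = g[zhat == j, i].sum() / mass_i  # P(zhat = j | Z = i)
    m_ij = g[zhat == i, j].sum() / mass_j
    return -max(m_ji, m_ij)


def crit_demp(gamma, i, j) -> float:
    """Negative misclassification probability, argmax over all components.

    M_{j,i} estimates P(zhat(X) = j | Z = i) where zhat is the hard argmax
    assignment over every current column (ties to the lowest index).  The
    value is in [-1, 0]; it can miss -1 for fully overlapped pairs when a
    third component captures the argmax.
    """
    g, i, j = _pair(gamma, i, j)
    return _demp_from_assignment(g, i, j, np.argmax(g, axis=1))


def crit_demp2(gamma, i, j) -> float:
    """As crit_demp but with the argmax restricted to {i, j}."""
    g, i, j = _pair(gamma, i, j)
    lo, hi = min(i, j), max(i, j)
    zhat = np.where(g[:, lo] >= g[:, hi], lo, hi)  # ties to the lower index
    return _demp_from_assignment(g, i, j, zhat)


def mixture_complexity(gamma, w=None) -> float:
    """MC = sum_k Psi(rho_k) - sum_n (w_n / W) sum_k Psi(gamma_k(x_n)).

    The effective number of clusters on a log scale: 0 when all rows are
    identical (entire overlap), ln K for a balanced hard assignment.
    ``w`` are optional point weights (unit by default).
    """
    g = _gamma_array(gamma)
    wa = _weight_array(w, g.shape[0])
    W = wa.sum()
    rho = wa @ g / W
    mc = psi(rho).sum() - (wa / W) @ psi(g).sum(axis=1)
    return float(mc)


def _pair_conditional(g, i, j):
    """Two-column conditional matrix of the pair and its mass weights."""
    s = g[:, i] + g[:, j]
    total = s.sum()
    if total <= 0:
        raise DegeneratePairError("pair has zero posterior mass")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(s > 0, g[:, i] / np.where(s > 0, s, 1.0), 0.5)
    p = np.clip(p, 0.0, 1.0)
    cond = np.column_stack([p, 1.0 - p])
    return cond, s


def crit_mc(gamma, i, j) -> float:
    """Mixture complexity of the pair's conditional sub-problem.

    The two-column matrix gamma_k / gamma_{i∪j} (k in {i, j}), point-weighted
    by w_n = gamma_{i∪j}(x_n), fed to ``mixture_complexity``.  Rows where the
    pair mass is zero get zero weight (their conditional is set to 0.5 by
    convention and never contributes).
    """
    g, i, j = _pair(gamma, i, j)
    cond, s = _pair_conditional(g, i, j)
    return mixture_complexity(cond, s)


def crit_nmc(gamma, i, j) -> float:
    """Normalized mixture complexity crit_mc / pair_entropy, in [0, 1]."""
    g, i, j = _pair(gamma, i, j)
    h = pair_entropy(g, i, j)
    if h <= 0:
        raise DegeneratePairError("pair weight entropy is zero")
    return crit_mc(g, i, j) / h


def nmc0(gamma) -> float:
    """Model-level NMC with unit weights: MC / sum_k Psi(rho_k), in [0, 1].

    The average degree of separation of the unmerged model, used as the
    stopping threshold.  Undefined (raises) for a single component or when
    the weight entropy vanishes.
    """
    g = _gamma_array(gamma)
    rho = effective_weights(g)
    h = float(psi(rho).sum())
    if h <= 0:
        raise UndefinedNMCError("weight entropy is zero; NMC0 is undefined")
    return mixture_complexity(g) / h


_DISPATCH = {
    Criterion.ENT: crit_ent,
    Criterion.NENT1: crit_nent1,
    Criterion.DEMP: crit_demp,
    Criterion.DEMP2: crit_demp2,
    Criterion.MC: crit_mc,
    Criterion.NMC: crit_nmc,
}


def criterion_best(criterion, n_points: int | None = None) -> float:
    """The best (smallest) attainable value of a criterion.

    For ``ent`` the optimum scales with the number of data points, so
    ``n_points`` is required there; all other criteria have fixed extremes.
    """
    c = Criterion.coerce(criterion)
    if c is Criterion.ENT:
        if n_points is None:
            raise DomainError("best value of 'ent' depends on n_points")
        return -n_points * LN2
    return {
        Criterion.NENT1: -LN2,
        Criterion.DEMP: -1.0,
        Criterion.DEMP2: -1.0,
        Criterion.MC: 0.0,
        Criterion.NMC: 0.0,
    }[c]


def criterion_worst(criterion) -> float:
    """The worst (largest) attainable value of a criterion."""
    c = Criterion.coerce(criterion)
    return {
        Criterion.ENT: 0.0,
        Criterion.NENT1: 0.0,
        Criterion.DEMP: 0.0,
        Criterion.DEMP2: 0.0,
        Criterion.MC: LN2,
        Criterion.NMC: 1.0,
    }[c]


def evaluate_criterion(criterion, gamma, i, j) -> float:
    """Dispatch a criterion id to its implementation (unit point weights).

    Degenerate pairs — one member with zero effective mass — evaluate to the
    criterion's best value, so empty components are absorbed first: an empty
    component is vacuously "entirely overlapped" with anything.
    """
    c = Criterion.coerce(criterion)
    try:
        return _DISPATCH[c](gamma, i, j)
    except DegeneratePairError:
        n = _gamma_array(gamma).shape[0]
        return criterion_best(c, n_points=n)


# check_conditions and ConditionReport live in a companion module but belong
# to this namespace.
from .conditions import ConditionReport, check_conditions  # noqa: E402,F401

__all__ += ["ConditionReport", "check_conditions"]
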