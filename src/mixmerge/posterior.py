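"""Soft assignments and their elementary transforms.

The whole merging framework operates on the N x K posterior (responsibility)
matrix gamma[n, k] = P(Z = k | X = x_n) of a finite mixture model
f(x) = sum_k rho_k g_k(x).  This module provides the matrix container, the
Gaussian posterior adapter, column merging (which is how two components become
one cluster: gamma_{i∪j} = gamma_i + gamma_j), effective mixture weights, and
the entropy kernel Psi(x) = -x ln x that every criterion is built from.

All logarithms are natural.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import multivariate_normal

from .errors import (
    DegenerateWeightsError,
    DomainError,
    NumericalUnderflowError,
)

__all__ = [
    "psi",
    "GaussianMixtureParams",
    "PosteriorMatrix",
    "PointWeights",
    "posteriors_from_mixture",
    "merge_columns",
    "effective_weights",
]

_ATOL = 1e-9


def psi(x):
    """Entropy kernel Psi(x) = -x ln x on [0, 1].

    Defined exactly at the endpoints by the limit convention 0 * log 0 = 0;
    no epsilon-clipping is applied to interior values.  Accepts scalars or
    arrays; inputs outside [0, 1] (beyond float fuzz) raise ``DomainError``.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < -1e-12) or np.any(arr > 1.0 + 1e-12):
        raise DomainError(f"psi requires values in [0, 1], got range "
                          f"[{arr.min()}, {arr.max()}]")
    arr = np.clip(arr, 0.0, 1.0)
    out = -xlogy(arr, arr)
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


@dataclass(frozen=True)
class GaussianMixtureParams:
    """Parameters (rho_k, mu_k, Sigma_k) of a Gaussian mixture.

    Parameters
    ----------
    weights : (K,) array
        Mixture proportions; must be nonnegative and sum to 1 (within 1e-9)
        unless ``normalize=True`` is passed, in which case they are rescaled.
    means : (K, d) array
    covariances : (K, d, d) array
        Symmetric positive-definite matrices.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def __init__(self, weights, means, covariances, *, normalize: bool = False):
        w = np.atleast_1d(np.asarray(weights, dtype=float))
        m = np.atleast_2d(np.asarray(means, dtype=float))
        c = np.asarray(covariances, dtype=float)
        if c.ndim == 1:  # K scalar variances in 1-D
            c = c.reshape(-1, 1, 1)
        if np.any(w < 0):
            raise DomainError("mixture weights must be nonnegative")
        total = w.sum()
        if normalize:
            if total <= 0:
                raise DomainError("cannot normalize all-zero weights")
            w = w / total
        elif abs(total - 1.0) > _ATOL:
            raise DomainError(f"mixture weights sum to {total}, expected 1")
        K = w.shape[0]
        if m.shape[0] != K or c.shape != (K, m.shape[1], m.shape[1]):
            raise DomainError("inconsistent shapes for weights/means/covariances")
        for k in range(K):
            if not np.allclose(c[k], c[k].T, atol=1e-8):
                raise DomainError(f"covariance {k} is not symmetric")
            if np.linalg.eigvalsh(c[k]).min() <= 0:
                raise DomainError(f"covariance {k} is not positive definite")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "covariances", c)

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def log_densities(self, data: np.ndarray) -> np.ndarray:
        """Per-component log densities, an (N, K) matrix."""
        X = np.atleast_2d(np.asarray(data, dtype=float))
        if X.shape[1] != self.dim:
            raise DomainError(f"data has dimension {X.shape[1]}, model {self.dim}")
        out = np.empty((X.shape[0], self.n_components))
        for k in range(self.n_components):
            out[:, k] = multivariate_normal.logpdf(
                X, mean=self.means[k], cov=self.covariances[k]
            )
        return out

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianMixtureParams":
        return cls(d["weights"], d["means"], d["covariances"])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GaussianMixtureParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _label_str(label: frozenset) -> str:
    return "+".join(str(k) for k in sorted(label))


def _parse_label(s: str) -> frozenset:
    return frozenset(int(tok) for tok in str(s).split("+"))


class PosteriorMatrix:
    """N x K matrix of posterior probabilities gamma_k(x_n).

    Rows are data points and must sum to 1 (within 1e-9); columns are
    (possibly merged) components.  Each column carries a label: the frozen
    set of original component indices it aggregates, so the partition
    induced by any merge sequence is always recoverable.
    """

    def __init__(self, gamma, labels: Sequence[Iterable[int]] | None = None,
                 *, validate: bool = True):
        g = np.atleast_2d(np.asarray(gamma, dtype=float))
        if labels is None:
            labels = [frozenset({k}) for k in range(g.shape[1])]
        labels = tuple(frozenset(l) for l in labels)
        if len(labels) != g.shape[1]:
            raise DomainError("one label per column is required")
        if validate:
            if g.shape[0] < 1 or g.shape[1] < 1:
                raise DomainError("gamma must be at least 1 x 1")
            if np.any(g < -1e-12) or np.any(g > 1 + 1e-12):
                raise DomainError("posterior entries must lie in [0, 1]")
            rows = g.sum(axis=1)
            if np.any(np.abs(rows - 1.0) > _ATOL):
                bad = int(np.argmax(np.abs(rows - 1.0)))
                raise DomainError(f"row {bad} sums to {rows[bad]}, expected 1")
        self.gamma = np.clip(g, 0.0, 1.0)
        self.labels = labels

    @property
    def n_points(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_components(self) -> int:
        return self.gamma.shape[1]

    def column(self, label_or_index) -> int:
        """Resolve a column identifier (position or label set) to a position."""
        if isinstance(label_or_index, (set, frozenset)):
            return self.labels.index(frozenset(label_or_index))
        return int(label_or_index)

    def merge_columns(self, i, j) -> "PosteriorMatrix":
        return merge_columns(self, i, j)

    def effective_weights(self, w=None) -> np.ndarray:
        return effective_weights(self, w)

    def hard_labels(self) -> np.ndarray:
        """argmax assignment per point (ties to the lowest column index)."""
        return np.argmax(self.gamma, axis=1)

    def to_csv(self, path: str | Path, sep: str = ",") -> None:
        df = pd.DataFrame(self.gamma,
                          columns=[_label_str(l) for l in self.labels])
        df.to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = ",") -> "PosteriorMatrix":
        df = pd.read_csv(path, sep=sep)
        labels = [_parse_label(c) for c in df.columns]
        return cls(df.to_numpy(dtype=float), labels)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"PosteriorMatrix(n_points={self.n_points}, "
                f"n_components={self.n_components})")


@dataclass(frozen=True)
class PointWeights:
    """Nonnegative weights w_n over the data points, with positive total W."""

    w: np.ndarray

    def __init__(self, w):
        arr = np.atleast_1d(np.asarray(w, dtype=float))
        if np.any(arr < 0):
            raise DomainError("point weights must be nonnegative")
        if arr.sum() <= 0:
            raise DegenerateWeightsError("point weights sum to zero")
        object.__setattr__(self, "w", arr)

    @property
    def W(self) -> float:
        return float(self.w.sum())


def _gamma_array(gamma) -> np.ndarray:
    if isinstance(gamma, PosteriorMatrix):
        return gamma.gamma
    return np.atleast_2d(np.asarray(gamma, dtype=float))


def _weight_array(w, n: int) -> np.ndarray:
    if w is None:
        return np.ones(n)
    if isinstance(w, PointWeights):
        arr = w.w
    else:
        arr = np.atleast_1d(np.asarray(w, dtype=float))
    if arr.shape[0] != n:
        raise DomainError(f"expected {n} point weights, got {arr.shape[0]}")
    if np.any(arr < 0):
        raise DomainError("point weights must be nonnegative")
    if arr.sum() <= 0:
        raise DegenerateWeightsError("point weights sum to zero")
    return arr


def posteriors_from_mixture(params: GaussianMixtureParams,
                            data: np.ndarray) -> PosteriorMatrix:
    """Posterior responsibilities gamma_k(x_n) = rho_k g_k(x_n) / f(x_n).

    Computed in log-density space with a per-row maximum subtraction, so the
    result is stable for well-separated components.  A data row where every
    component's density underflows to zero raises ``NumericalUnderflowError``
    naming the row.
    """
    with np.errstate(divide="ignore"):
        log_num = params.log_densities(data) + np.log(params.weights)[None, :]
    row_max = log_num.max(axis=1)
    if np.any(~np.isfinite(row_max)):
        bad = int(np.argmax(~np.isfinite(row_max)))
        raise NumericalUnderflowError(
            f"all component densities underflowed at data row {bad}")
    shifted = np.exp(log_num - row_max[:, None])
    gamma = shifted / shifted.sum(axis=1, keepdims=True)
    return PosteriorMatrix(gamma)


def merge_columns(gamma: PosteriorMatrix, i, j) -> PosteriorMatrix:
    """Merge components i and j: the new column is the elementwise sum.

    The merged column sits at the position of ``min(i, j)`` and carries the
    union of the two labels; all other columns are unchanged, so row sums
    are preserved exactly.
    """
    if not isinstance(gamma, PosteriorMatrix):
        gamma = PosteriorMatrix(gamma)
    a, b = gamma.column(i), gamma.column(j)
    K = gamma.n_components
    if a == b:
        raise DomainError("cannot merge a column with itself")
    if not (0 <= a < K and 0 <= b < K):
        raise DomainError(f"column out of range for K={K}")
    a, b = min(a, b), max(a, b)
    g = gamma.gamma.copy()
    g[:, a] = g[:, a] + g[:, b]
    g = np.delete(g, b, axis=1)
    labels = list(gamma.labels)
    labels[a] = labels[a] | labels[b]
    del labels[b]
    return PosteriorMatrix(g, labels, validate=False)


def effective_weights(gamma, w=None) -> np.ndarray:
    """Effective mixture weights rho_tilde_k = sum_n w_n gamma_k(x_n) / W.

    With unit weights this is the column mean of the posterior matrix; the
    result sums to 1 whenever the rows of ``gamma`` do.
    """
    g = _gamma_array(gamma)
    wa = _weight_array(w, g.shape[0])
    return wa @ g / wa.sum()
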