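"""Evaluation metrics and the artificial ranking benchmark.

Cluster quality on the artificial experiment is measured by

    D_intra = max_k  sum_n gamma_k(x_n) ||x_n - mu_k|| / sum_n gamma_k(x_n)
    D_inter = min_{i<j} ||mu_i - mu_j||

with mu_k the posterior-weighted cluster centers; smaller D_intra and
larger D_inter are better.  ||.|| is the Euclidean norm by default; the
squared-distance variant of D_intra is exposed via ``squared=True`` (the
published rankings are robust to the choice).

Per trial and cluster count the six criteria are ranked (1 = best:
smallest D_intra, largest D_inter; ties get average ranks) and averaged
over trials.  Also here: label entropy H_C of true labels within a
cluster, ARI, pair-counting F-measure, and a k-NN outlier diagnostic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .criteria import ALL_CRITERIA, Criterion
from .errors import DomainError
from .merging import merged_matrix, partition_at, run_merging
from .posterior import PosteriorMatrix, _gamma_array, psi, posteriors_from_mixture
from .simulation import SimConfig, random_mixture, sample_data

__all__ = ["cluster_centers", "d_intra", "d_inter", "TrialResult",
           "rank_table", "label_entropy", "ari", "f_measure",
           "knn_outlier_proportions", "run_benchmark"]

logger = logging.getLogger(__name__)

DEFAULT_K_GRID = (40, 30, 20, 10, 5)


def cluster_centers(gamma, data) -> np.ndarray:
    """Posterior-weighted cluster means, a (K, d) matrix."""
    g = _gamma_array(gamma)
    X = np.atleast_2d(np.asarray(data, dtype=float))
    mass = g.sum(axis=0)
    if np.any(mass <= 0):
        raise DomainError("a zero-mass column has no defined center")
    return (g.T @ X) / mass[:, None]


def d_intra(gamma, data, *, squared: bool = False) -> float:
    """Maximum posterior-weighted mean distance to the cluster center."""
    g = _gamma_array(gamma)
    X = np.atleast_2d(np.asarray(data, dtype=float))
    centers = cluster_centers(g, X)
    mass = g.sum(axis=0)
    spreads = np.empty(g.shape[1])
    for k in range(g.shape[1]):
        d2 = ((X - centers[k]) ** 2).sum(axis=1)
        dist = d2 if squared else np.sqrt(d2)
        spreads[k] = g[:, k] @ dist / mass[k]
    return float(spreads.max())


def d_inter(gamma, data, *, squared: bool = False) -> float:
    """Minimum pairwise distance between cluster centers."""
    g = _gamma_array(gamma)
    if g.shape[1] < 2:
        raise DomainError("d_inter needs at least two clusters")
    centers = cluster_centers(g, data)
    diffs = centers[:, None, :] - centers[None, :, :]
    d2 = (diffs ** 2).sum(axis=-1)
    iu = np.triu_indices(g.shape[1], k=1)
    best = d2[iu].min()
    return float(best if squared else np.sqrt(best))


@dataclass(frozen=True)
class TrialResult:
    """Per-trial D_intra / D_inter for each criterion at each cluster count."""

    trial: int
    intra: dict  # {Criterion: {K: float}}
    inter: dict


def _rank_frame(results, attr: str, larger_is_better: bool) -> pd.DataFrame:
    criteria = list(ALL_CRITERIA)
    k_grid = sorted({k for r in results for v in getattr(r, attr).values()
                     for k in v}, reverse=True)
    ranks = np.zeros((len(criteria), len(k_grid)))
    for r in results:
        table = getattr(r, attr)
        for kk, K in enumerate(k_grid):
            try:
                vals = np.array([table[c][K] for c in criteria])
            except KeyError as e:
                raise DomainError(f"trial {r.trial} is missing a cell: {e}")
            ranks[:, kk] += rankdata(-vals if larger_is_better else vals)
    ranks /= len(results)
    return pd.DataFrame(ranks, index=[c.value for c in criteria],
                        columns=k_grid)


def rank_table(results):
    """Average criterion ranks over trials.

    Returns ``(intra, inter)`` DataFrames (criteria x cluster counts);
    rank 1 is the smallest D_intra / the largest D_inter, ties averaged.
    """
    results = list(results)
    if not results:
        raise DomainError("rank_table needs at least one trial")
    return (_rank_frame(results, "intra", larger_is_better=False),
            _rank_frame(results, "inter", larger_is_better=True))


def label_entropy(true_labels, member_mask) -> float:
    """Entropy of the true-label counts within one cluster.

    ``member_mask`` selects the points assigned to the cluster.  In
    [0, ln(#labels)]; 0 for a pure cluster.  Empty clusters are undefined
    and raise (callers omit them).
    """
    true_labels = np.asarray(true_labels)
    member = np.asarray(member_mask, dtype=bool)
    n = member.sum()
    if n == 0:
        raise DomainError("label entropy of an empty cluster is undefined")
    _, counts = np.unique(true_labels[member], return_counts=True)
    return float(psi(counts / n).sum())


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings (chance-corrected)."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise DomainError("labelings must have the same length")
    return float(adjusted_rand_score(a, b))


def f_measure(labels_true, labels_pred) -> float:
    """Pair-counting F1 over co-clustered pairs.

    Precision and recall are computed over pairs of points placed in the
    same cluster; permutation-invariant and defined for unequal cluster
    counts.
    """
    t = np.asarray(labels_true)
    p = np.asarray(labels_pred)
    if t.shape != p.shape:
        raise DomainError("labelings must have the same length")
    ct = pd.crosstab(t, p).to_numpy()

    def pairs(x):
        return (x * (x - 1) / 2).sum()

    tp = pairs(ct)
    pairs_pred = pairs(ct.sum(axis=0))
    pairs_true = pairs(ct.sum(axis=1))
    if pairs_pred == 0 or pairs_true == 0:
        return 1.0 if pairs_pred == pairs_true else 0.0
    prec, rec = tp / pairs_pred, tp / pairs_true
    if prec + rec == 0:
        return 0.0
    return float(2 * prec * rec / (prec + rec))


def knn_outlier_proportions(data, k: int = 5, thresholds=(2.0, 3.0, 4.0, 5.0)):
    """Fraction of points whose k-NN distance exceeds multiples of its mean.

    For each point the distance to its k-th nearest neighbor (self
    excluded) is divided by the data-set average of that distance; the
    returned dict maps each threshold to the fraction of ratios above it.
    """
    X = np.atleast_2d(np.asarray(data, dtype=float))
    n = X.shape[0]
    if n <= k:
        raise DomainError(f"need more than k={k} points, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dist, _ = nn.kneighbors(X)
    dk = dist[:, k]  # column 0 is the point itself
    ratio = dk / dk.mean()
    return {float(t): float((ratio > t).mean()) for t in thresholds}


def run_benchmark(cfg: SimConfig, k_grid=DEFAULT_K_GRID,
                  criteria=ALL_CRITERIA, *, squared: bool = True,
                  progress=None):
    """Run the artificial ranking experiment.

    For each trial: draw a random mixture, sample data, compute posteriors,
    merge down to ``min(k_grid)`` clusters under every criterion, and score
    D_intra / D_inter at each cluster count in ``k_grid``.  Returns
    ``(intra_ranks, inter_ranks, results)``.

    The experiment scores D_intra with squared distances (the within-cluster
    scatter convention); D_inter rankings are identical either way because
    the square root is monotone.  Pass ``squared=False`` for Euclidean.
    """
    k_grid = tuple(sorted(set(int(k) for k in k_grid), reverse=True))
    if k_grid[0] >= cfg.n_components or k_grid[-1] < 1:
        raise DomainError("k_grid must lie strictly inside [1, K)")
    criteria = [Criterion.coerce(c) for c in criteria]
    results = []
    for trial in range(cfg.n_trials):
        params = random_mixture(cfg, trial)
        data, _ = sample_data(params, cfg.n_samples,
                              np.random.default_rng([cfg.seed, trial, 1]))
        pm = posteriors_from_mixture(params, data)
        intra: dict = {}
        inter: dict = {}
        for crit in criteria:
            tree = run_merging(pm, crit, stop=k_grid[-1])
            intra[crit] = {}
            inter[crit] = {}
            for K in k_grid:
                sub = merged_matrix(pm, partition_at(tree, K))
                intra[crit][K] = d_intra(sub, data, squared=squared)
                inter[crit][K] = d_inter(sub, data, squared=squared)
        results.append(TrialResult(trial=trial, intra=intra, inter=inter))
        logger.info("benchmark trial %d/%d done", trial + 1, cfg.n_trials)
        if progress is not None:
            progress(trial + 1, cfg.n_trials)
    intra_ranks, inter_ranks = rank_table(results)
    return intra_ranks, inter_ranks, results
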