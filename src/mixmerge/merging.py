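"""Agglomerative merging of mixture components.

The loop repeatedly selects the pair of current components minimizing the
chosen criterion and merges their posterior columns.  Three stopping
policies are supported:

- ``"none"``      : merge all the way down to a single cluster;
- an integer m    : stop when m clusters remain;
- ``"nmc"``       : the NMC stopping rule — compute NMC0 once on the initial
  unmerged matrix, then before each merge compare the selected pair's NMC
  against it and halt (without merging) as soon as pair-NMC >= NMC0.

The full history is recorded as a :class:`MergeTree`, from which the
partition at any level can be replayed.  Pair scores are cached
incrementally (only scores involving the newly merged cluster are
recomputed); the ``demp`` criterion depends on the global argmax and is
therefore fully recomputed after every merge.  Either way the results are
contractually identical to full recomputation (``use_cache=False``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .criteria import (
    Criterion,
    crit_nmc,
    evaluate_criterion,
    nmc0,
)
from .errors import DegeneratePairError, DomainError, UndefinedNMCError
from .posterior import PosteriorMatrix

__all__ = ["MergeStep", "MergeTree", "best_pair", "run_merging",
           "partition_at", "merged_matrix"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MergeStep:
    """One merge: which label sets were joined, at what criterion value."""

    index: int
    i: frozenset
    j: frozenset
    criterion_value: float
    pair_nmc: float
    k_after: int


@dataclass(frozen=True)
class MergeTree:
    """Ordered record of a merging run and the partition it induces."""

    criterion: Criterion
    initial_k: int
    initial_labels: tuple
    steps: tuple
    stop_reason: str
    nmc0: float | None = None

    @property
    def partition(self) -> tuple:
        """Final partition of the original component indices."""
        return partition_at(self, self.initial_k - len(self.steps))

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion.value,
            "K0": self.initial_k,
            "initial_labels": [sorted(l) for l in self.initial_labels],
            "nmc0": self.nmc0,
            "stop_reason": self.stop_reason,
            "steps": [
                {
                    "i": sorted(s.i),
                    "j": sorted(s.j),
                    "crit": s.criterion_value,
                    "pair_nmc": s.pair_nmc,
                    "K_after": s.k_after,
                }
                for s in self.steps
            ],
            "partition": [sorted(p) for p in self.partition],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MergeTree":
        steps = tuple(
            MergeStep(
                index=t,
                i=frozenset(s["i"]),
                j=frozenset(s["j"]),
                criterion_value=s["crit"],
                pair_nmc=s["pair_nmc"],
                k_after=s["K_after"],
            )
            for t, s in enumerate(d["steps"])
        )
        return cls(
            criterion=Criterion.coerce(d["criterion"]),
            initial_k=d["K0"],
            initial_labels=tuple(frozenset(l) for l in d["initial_labels"]),
            steps=steps,
            stop_reason=d["stop_reason"],
            nmc0=d.get("nmc0"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MergeTree":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_linkage(self) -> np.ndarray:
        """Dendrogram linkage table: one row (id_i, id_j, height, size) per
        merge, heights being the criterion values; scipy-compatible layout
        for plotting (heights need not be monotone)."""
        idx = {l: t for t, l in enumerate(self.initial_labels)}
        rows = []
        for t, s in enumerate(self.steps):
            a, b = idx.pop(s.i), idx.pop(s.j)
            merged = s.i | s.j
            idx[merged] = self.initial_k + t
            rows.append([a, b, s.criterion_value, len(merged)])
        return np.asarray(rows, dtype=float)


def partition_at(tree: MergeTree, n_clusters: int) -> tuple:
    """Replay the tree to the level with ``n_clusters`` clusters.

    ``partition_at(tree, initial_k)`` is the identity partition; each step
    down joins exactly one recorded pair.
    """
    K0 = tree.initial_k
    n_steps = K0 - n_clusters
    if not (0 <= n_steps <= len(tree.steps)):
        raise DomainError(
            f"no recorded level with {n_clusters} clusters "
            f"(tree spans {K0}..{K0 - len(tree.steps)})")
    parts = list(tree.initial_labels)
    for s in tree.steps[:n_steps]:
        parts.remove(s.i)
        parts.remove(s.j)
        parts.append(s.i | s.j)
    return tuple(sorted(parts, key=lambda p: sorted(p)))


def merged_matrix(gamma: PosteriorMatrix, partition) -> PosteriorMatrix:
    """Sum posterior columns within each block of ``partition``."""
    if not isinstance(gamma, PosteriorMatrix):
        gamma = PosteriorMatrix(gamma)
    blocks = [frozenset(p) for p in partition]
    if not blocks:
        raise DomainError("partition is empty")
    covered = frozenset().union(*blocks)
    all_labels = frozenset().union(*gamma.labels)
    if covered != all_labels or sum(len(b) for b in blocks) != len(covered):
        raise DomainError("partition must cover every column label exactly once")
    for l in gamma.labels:
        if sum(1 for b in blocks if l <= b) != 1:
            raise DomainError(f"column label {sorted(l)} does not sit inside "
                              f"exactly one partition block")
    cols = []
    for b in blocks:
        members = [t for t, l in enumerate(gamma.labels) if l <= b]
        cols.append(gamma.gamma[:, members].sum(axis=1))
    return PosteriorMatrix(np.column_stack(cols), blocks, validate=False)


def best_pair(gamma, criterion) -> "PairScore":
    """The pair minimizing the criterion over all unordered pairs; ties are
    broken by the lexicographically smallest (i, j) column positions."""
    from .criteria import PairScore

    if not isinstance(gamma, PosteriorMatrix):
        gamma = PosteriorMatrix(gamma)
    K = gamma.n_components
    if K < 2:
        raise DomainError("need at least two components to pick a pair")
    crit = Criterion.coerce(criterion)
    best = None
    for i in range(K):
        for j in range(i + 1, K):
            v = evaluate_criterion(crit, gamma.gamma, i, j)
            if best is None or (v, i, j) < best:
                best = (v, i, j)
    v, i, j = best
    return PairScore(i=i, j=j, value=v)


def _demp_all_scores(G: np.ndarray, active: list) -> dict:
    """All-pairs demp scores in one pass.

    Shares the single global argmax over the active columns instead of
    recomputing it per pair; exactly equivalent to calling
    ``evaluate_criterion('demp', ...)`` pair by pair (``active`` is kept
    sorted, so tie-breaking to the lowest index agrees).
    """
    sub = G[:, active]
    zhat = np.argmax(sub, axis=1)
    mass = sub.sum(axis=0)
    S = np.zeros((len(active), len(active)))
    np.add.at(S, zhat, sub)  # S[c, k] = sum of gamma_k over points with zhat=c
    scores = {}
    for a, i in enumerate(active):
        for b in range(a + 1, len(active)):
            j = active[b]
            if mass[a] <= 0 or mass[b] <= 0:
                scores[(i, j)] = -1.0  # degenerate pair -> best value
            else:
                scores[(i, j)] = -max(S[b, a] / mass[a], S[a, b] / mass[b])
    return scores


def _pair_nmc_or_best(g, i, j) -> float:
    try:
        return crit_nmc(g, i, j)
    except DegeneratePairError:
        return 0.0


def run_merging(gamma, criterion, stop="nmc", *,
                refresh_nmc0: bool = False,
                use_cache: bool = True) -> MergeTree:
    """Run the agglomerative merging loop.

    Parameters
    ----------
    gamma : PosteriorMatrix or array
    criterion : criterion id (case-insensitive string or ``Criterion``)
    stop : ``"nmc"``, ``"none"``, or a target cluster count (int)
    refresh_nmc0 : recompute the NMC0 threshold on the merged matrix before
        every comparison instead of fixing it at the initial model
        (experimental; the stopping rule as defined uses the initial model).
    use_cache : incrementally cache pair scores (results are identical to
        full recomputation; exposed for testing the contract).
    """
    if not isinstance(gamma, PosteriorMatrix):
        gamma = PosteriorMatrix(gamma)
    crit = Criterion.coerce(criterion)

    if isinstance(stop, bool) or not (isinstance(stop, int) or
                                      stop in ("nmc", "none")):
        raise DomainError(f"invalid stopping policy {stop!r}")
    target = stop if isinstance(stop, int) else 1
    if isinstance(stop, int) and not (1 <= stop <= gamma.n_components):
        raise DomainError(f"target cluster count {stop} out of range")

    G = gamma.gamma.copy()
    active = list(range(gamma.n_components))
    labels = list(gamma.labels)

    threshold = None
    if stop == "nmc":
        try:
            threshold = nmc0(G)
        except UndefinedNMCError:
            threshold = None  # single component; loop below exits immediately
    logger.info("merging: criterion=%s stop=%s K0=%d NMC0=%s",
                crit.value, stop, gamma.n_components, threshold)

    # demp's argmax ranges over all current components, so a merge can move
    # any pair's score; its cache is rebuilt from scratch every step.
    local = crit is not Criterion.DEMP

    def compute(i, j):
        return evaluate_criterion(crit, G, i, j)

    cache: dict = {}
    if use_cache:
        cache = (_demp_all_scores(G, active) if not local else
                 {(i, j): compute(i, j)
                  for a, i in enumerate(active) for j in active[a + 1:]})

    steps = []
    stop_reason = None
    while len(active) > target:
        if use_cache:
            items = cache
        else:
            items = {(i, j): compute(i, j)
                     for a, i in enumerate(active) for j in active[a + 1:]}
        (bi, bj), bval = min(items.items(), key=lambda kv: (kv[1], kv[0]))

        pnmc = _pair_nmc_or_best(G, bi, bj)
        if stop == "nmc":
            thr = threshold
            if refresh_nmc0:
                try:
                    thr = nmc0(G[:, active])
                except UndefinedNMCError:
                    thr = None
            if thr is None or pnmc >= thr:
                stop_reason = "nmc-stop"
                logger.info("nmc-stop: pair NMC %.6f >= NMC0 %s", pnmc, thr)
                break

        G[:, bi] = G[:, bi] + G[:, bj]
        G[:, bj] = 0.0
        active.remove(bj)
        merged = labels[bi] | labels[bj]
        steps.append(MergeStep(index=len(steps), i=labels[bi], j=labels[bj],
                               criterion_value=bval, pair_nmc=pnmc,
                               k_after=len(active)))
        labels[bi] = merged

        if use_cache:
            if local:
                cache = {k: v for k, v in cache.items()
                         if bi not in k and bj not in k}
                for i in active:
                    if i != bi:
                        pair = (min(i, bi), max(i, bi))
                        cache[pair] = compute(*pair)
            else:
                cache = _demp_all_scores(G, active)

    if stop_reason is None:
        stop_reason = "target-K" if isinstance(stop, int) else "singleton"

    return MergeTree(
        criterion=crit,
        initial_k=gamma.n_components,
        initial_labels=gamma.labels,
        steps=tuple(steps),
        stop_reason=stop_reason,
        nmc0=threshold,
    )
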