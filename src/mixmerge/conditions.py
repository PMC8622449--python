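"""Numerical certification of the essential conditions for merging criteria.

A reasonable pairwise merging criterion should:

- **BO** (best in entire overlap): attain its best value whenever the two
  components have identical densities g_i = g_j — for any weight bias, which
  makes the posterior columns *proportional* (ratio rho_i : rho_j), not
  necessarily identical.
- **WS** (worst in entire separation): converge to its worst value along any
  sequence of models whose component densities separate, again for any
  weight setting.
- **SI** (scale invariance): be unaffected by rescaling the mixture weights
  of an isolated pair by a common factor, with the data reflecting the
  rescaled model.

Extreme (best/worst) values are taken from closed forms and cross-checked by
a brute-force grid search over the posterior simplex on tiny instances.  The
checks are asymptotic where the definitions are (separation up to 40
standard deviations; tolerance 1e-3 on limits), both adjustable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .posterior import GaussianMixtureParams, posteriors_from_mixture

__all__ = ["ConditionReport", "check_conditions", "check_all_conditions",
           "brute_force_extremes"]


@dataclass(frozen=True)
class ConditionReport:
    """Outcome of the essential-condition checks for one criterion.

    ``bo`` is the strict check over every entire-overlap fixture;
    ``bo_pair_only`` restricts the fixtures to those where the hard argmax
    cannot escape the pair — the two differ exactly for criteria (demp)
    whose best value can be stolen by a third component.
    """

    criterion: "Criterion"
    bo: bool
    ws: bool
    si: bool
    bo_pair_only: bool
    diagnostics: dict = field(repr=False, default_factory=dict)


def brute_force_extremes(criterion, n_points: int = 4, grid: int = 5):
    """Min and max of a pair criterion over a gridded posterior simplex.

    Enumerates all K=2 posterior matrices with ``n_points`` rows whose first
    column takes values on a uniform grid in [0, 1]; serves as the
    independent verification of the closed-form extremes.
    """
    from .criteria import evaluate_criterion

    levels = np.linspace(0.0, 1.0, grid)
    lo, hi = np.inf, -np.inf
    for p in itertools.product(levels, repeat=n_points):
        col = np.asarray(p)
        g = np.column_stack([col, 1.0 - col])
        v = evaluate_criterion(criterion, g, 0, 1)
        lo, hi = min(lo, v), max(hi, v)
    return lo, hi


def _quantile_grid(mean: float, sd: float, m: int) -> np.ndarray:
    q = (np.arange(m) + 0.5) / m
    return (mean + sd * norm.ppf(q)).reshape(-1, 1)


def _overlap_fixtures():
    """Entire-overlap fixtures: models with g_i = g_j, varied weight bias.

    Yields (name, gamma, i, j, pair_only); ``pair_only`` marks fixtures in
    which no third component can win the argmax.
    """
    fixtures = []
    n = 60
    for p in (0.5, 0.25, 0.1):
        gamma = np.tile([p, 1.0 - p], (n, 1))
        fixtures.append((f"pair-bias-{p}", gamma, 0, 1, True))
    # Third component equal to the pair everywhere, dominant weight: the
    # global argmax never lands on the pair.
    gamma = np.tile([0.2, 0.2, 0.6], (n, 1))
    fixtures.append(("captured-balanced", gamma, 0, 1, False))
    gamma = np.tile([0.1, 0.3, 0.6], (n, 1))
    fixtures.append(("captured-biased", gamma, 0, 1, False))
    # Third component elsewhere in space: the pair's joint mass varies by row.
    params = GaussianMixtureParams(
        weights=[0.25, 0.25, 0.5],
        means=[[0.0], [0.0], [4.0]],
        covariances=np.ones(3),
    )
    data = np.vstack([_quantile_grid(0.0, 1.0, 30), _quantile_grid(4.0, 1.0, 30)])
    fixtures.append(("side-component", posteriors_from_mixture(params, data).gamma,
                     0, 1, False))
    return fixtures


def _separation_gamma(weights, mean_gap: float, n_total: int = 400) -> np.ndarray:
    """Posteriors for two 1-D unit-variance components ``mean_gap`` apart,
    with deterministic per-component quantile grids sized by the weights."""
    w = np.asarray(weights, dtype=float)
    counts = np.maximum(1, np.round(n_total * w).astype(int))
    params = GaussianMixtureParams(w, [[0.0], [mean_gap]], np.ones(2),
                                   normalize=True)
    data = np.vstack([_quantile_grid(0.0, 1.0, counts[0]),
                      _quantile_grid(mean_gap, 1.0, counts[1])])
    return posteriors_from_mixture(params, data).gamma


def _si_gamma(a: float, m: int = 20) -> np.ndarray:
    """Posteriors for an isolated, partially overlapped pair whose mixture
    weights are rescaled by ``a``, with data multiplicities matching the
    rescaled model exactly (integer replication of fixed quantile grids)."""
    base = np.array([0.03, 0.06])
    rest = 1.0 - a * base.sum()
    weights = np.array([a * base[0], a * base[1], rest])
    counts = np.round(weights * 1000).astype(int)  # exact for a in {0.1,1,10}
    means = [[0.0], [1.5], [500.0]]
    params = GaussianMixtureParams(weights, means, np.ones(3))
    grids = [_quantile_grid(mu[0], 1.0, m) for mu in means]
    data = np.vstack([np.repeat(g, c, axis=0) for g, c in zip(grids, counts)])
    return posteriors_from_mixture(params, data).gamma


def check_conditions(criterion, tol: float = 1e-3,
                     max_sd: float = 40.0, t_steps: int = 8) -> ConditionReport:
    """Certify the essential conditions BO, WS and SI for one criterion.

    Runs the criterion over constructed entire-overlap fixtures (BO), a
    diverging-mean separation sequence under balanced and biased weights
    (WS), and weight rescalings a in {0.1, 10} of an isolated pair (SI),
    comparing against closed-form extremes that are themselves re-verified
    by brute-force grid search on a tiny instance.
    """
    from .criteria import (
        Criterion,
        criterion_best,
        criterion_worst,
        evaluate_criterion,
    )

    c = Criterion.coerce(criterion)
    diag: dict = {}

    # Closed-form extremes, verified by brute force at n=4.
    bf_lo, bf_hi = brute_force_extremes(c, n_points=4, grid=5)
    diag["extremes"] = {
        "brute_force": (bf_lo, bf_hi),
        "analytic": (criterion_best(c, n_points=4), criterion_worst(c)),
    }
    diag["extremes_verified"] = (
        abs(bf_lo - criterion_best(c, n_points=4)) <= 1e-9
        and abs(bf_hi - criterion_worst(c)) <= 1e-9
    )

    # BO: entire overlap must score Best for every weight bias.
    bo_trace = {}
    for name, gamma, i, j, pair_only in _overlap_fixtures():
        best = criterion_best(c, n_points=gamma.shape[0])
        bo_trace[name] = {
            "value": evaluate_criterion(c, gamma, i, j),
            "best": best,
            "pair_only": pair_only,
        }
    diag["bo"] = bo_trace
    bo = all(abs(t["value"] - t["best"]) <= tol for t in bo_trace.values())
    bo_pair_only = all(abs(t["value"] - t["best"]) <= tol
                       for t in bo_trace.values() if t["pair_only"])

    # WS: separation sequence must approach Worst for every weight setting.
    worst = criterion_worst(c)
    ws_trace = {}
    gaps = np.linspace(max_sd / t_steps, max_sd, t_steps)
    for weights in ((0.5, 0.5), (0.1, 0.9)):
        values = [evaluate_criterion(c, _separation_gamma(weights, gap), 0, 1)
                  for gap in gaps]
        ws_trace[f"weights-{weights}"] = {"values": values, "worst": worst}
    diag["ws"] = ws_trace
    ws = all(abs(t["values"][-1] - t["worst"]) <= tol
             for t in ws_trace.values())

    # SI: rescaling the isolated pair's weights must not move the value.
    ref = evaluate_criterion(c, _si_gamma(1.0), 0, 1)
    si_trace = {"a=1": ref}
    for a in (0.1, 10.0):
        si_trace[f"a={a}"] = evaluate_criterion(c, _si_gamma(a), 0, 1)
    diag["si"] = si_trace
    si = all(abs(v - ref) <= tol for v in si_trace.values())

    return ConditionReport(criterion=c, bo=bo, ws=ws, si=si,
                           bo_pair_only=bo_pair_only, diagnostics=diag)


def check_all_conditions(tol: float = 1e-3) -> dict:
    """Reports for every criterion, keyed by ``Criterion``."""
    from .criteria import ALL_CRITERIA

    return {c: check_conditions(c, tol=tol) for c in ALL_CRITERIA}
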