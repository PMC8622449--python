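"""Clustering summarization: MC/NMC between and within merged clusters.

After merging a K-component mixture into L upper-components I_1, ..., I_L,
two levels of structure remain to quantify:

- between the upper-components: MC(up) of the L-column merged matrix, and
  NMC(up) = MC(up) / sum_l Psi(tau_l), where tau_l is the posterior weight
  of upper-component l;
- within each upper-component l: MC(l) of the conditional sub-matrix of its
  members, point-weighted by the cluster's posterior mass, and
  NMC(l) = MC(l) / sum_{k in I_l} Psi(rho_k / tau_l).

NMC is undefined when its denominator is zero (a single cluster at the
upper level; a singleton cluster within).  Undefinedness is represented as
``None`` — never 0 or a silent NaN — and rendered as ``-``.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateClusterError, DomainError
from .merging import merged_matrix
from .posterior import PosteriorMatrix, psi
from .criteria import mixture_complexity

__all__ = ["ClusterSummary", "SubSummary", "upper_summary", "sub_summary",
           "summarize", "render_summary", "parse_summary"]


@dataclass(frozen=True)
class SubSummary:
    """Within-cluster report for one upper-component."""

    members: tuple
    weight: float
    mc: float
    nmc: float | None


@dataclass(frozen=True)
class ClusterSummary:
    """Table-style report of the between- and within-cluster structure."""

    mc_up: float
    nmc_up: float | None
    clusters: tuple  # SubSummary, ordered by descending weight

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def to_dict(self) -> dict:
        return {
            "upper": {"mc": self.mc_up, "nmc": self.nmc_up,
                      "L": self.n_clusters},
            "clusters": [
                {"members": sorted(c.members), "weight": c.weight,
                 "mc": c.mc, "nmc": c.nmc}
                for c in self.clusters
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _coerce(gamma) -> PosteriorMatrix:
    return gamma if isinstance(gamma, PosteriorMatrix) else PosteriorMatrix(gamma)


def upper_summary(gamma, partition):
    """MC, NMC and weights among the upper-components.

    Returns ``(mc_up, nmc_up, tau)`` where ``tau`` holds the upper-component
    weights in partition order; ``nmc_up`` is ``None`` when the weight
    entropy is zero (L = 1).
    """
    gamma = _coerce(gamma)
    up = merged_matrix(gamma, partition)
    mc_up = mixture_complexity(up.gamma)
    tau = up.gamma.mean(axis=0)
    denom = float(psi(np.clip(tau, 0, 1)).sum())
    nmc_up = mc_up / denom if denom > 0 else None
    return mc_up, nmc_up, tau


def sub_summary(gamma, members):
    """MC and NMC of the sub-components within one upper-component.

    ``members`` is the set of original component labels in the cluster.
    The conditional within-cluster matrix gamma_k / gamma_cluster is fed to
    ``mixture_complexity`` with the cluster's posterior mass as point
    weights.  ``nmc`` is ``None`` for singleton clusters (zero-entropy
    denominator).
    """
    gamma = _coerce(gamma)
    members = frozenset(members)
    cols = [t for t, l in enumerate(gamma.labels) if l <= members]
    if frozenset().union(*(gamma.labels[t] for t in cols)) != members:
        raise DomainError(f"members {sorted(members)} do not match columns")
    sub = gamma.gamma[:, cols]
    s = sub.sum(axis=1)
    total = s.sum()
    if total <= 0:
        raise DegenerateClusterError("cluster has zero posterior mass")
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(s[:, None] > 0, sub / np.where(s > 0, s, 1.0)[:, None],
                        1.0 / len(cols))
    mc_l = mixture_complexity(np.clip(cond, 0, 1), s)
    rho = s @ np.clip(cond, 0, 1) / total  # relative sub-component weights
    denom = float(psi(np.clip(rho, 0, 1)).sum())
    nmc_l = mc_l / denom if denom > 0 else None
    return mc_l, nmc_l


def summarize(gamma, partition) -> ClusterSummary:
    """Full clustering summarization for a partition of the components.

    Composes :func:`upper_summary` with :func:`sub_summary` per cluster;
    clusters are reported in order of descending weight.
    """
    gamma = _coerce(gamma)
    blocks = [frozenset(p) for p in partition]
    mc_up, nmc_up, tau = upper_summary(gamma, blocks)
    subs = []
    for b, t in zip(blocks, tau):
        mc_l, nmc_l = sub_summary(gamma, b)
        subs.append(SubSummary(members=tuple(sorted(b)), weight=float(t),
                               mc=mc_l, nmc=nmc_l))
    subs.sort(key=lambda c: (-c.weight, c.members))
    return ClusterSummary(mc_up=mc_up, nmc_up=nmc_up, clusters=tuple(subs))


def _fmt(x: float | None, decimals: int = 3) -> str:
    return "-" if x is None else f"{x:.{decimals}f}"


def _fmt_mc(x: float, decimals: int = 3) -> str:
    return f"{x:.{decimals}f} ({math.exp(x):.2f})"


def render_summary(summary: ClusterSummary, fmt: str = "markdown") -> str:
    """Render a summary as a Markdown table or a parseable TSV.

    Values are printed with 3 decimals, MC with its exponential in
    parentheses, and undefined NMC as ``-``.
    """
    if fmt == "tsv":
        rows = [{"cluster": "upper", "members": "all", "weight": 1.0,
                 "mc": f"{summary.mc_up:.6f}", "nmc": _fmt(summary.nmc_up, 6)}]
        for t, c in enumerate(summary.clusters, start=1):
            rows.append({"cluster": str(t),
                         "members": "+".join(str(m) for m in c.members),
                         "weight": f"{c.weight:.6f}",
                         "mc": f"{c.mc:.6f}", "nmc": _fmt(c.nmc, 6)})
        buf = io.StringIO()
        pd.DataFrame(rows).to_csv(buf, sep="\t", index=False)
        return buf.getvalue()
    if fmt != "markdown":
        raise DomainError(f"unknown format {fmt!r}")
    lines = [
        "| Cluster | Members | Weight | MC (exp) | NMC |",
        "|---|---|---|---|---|",
        f"| upper | all | 1.000 | {_fmt_mc(summary.mc_up)} "
        f"| {_fmt(summary.nmc_up)} |",
    ]
    for t, c in enumerate(summary.clusters, start=1):
        members = "+".join(str(m) for m in c.members)
        lines.append(f"| {t} | {members} | {c.weight:.3f} "
                     f"| {_fmt_mc(c.mc)} | {_fmt(c.nmc)} |")
    return "\n".join(lines) + "\n"


def parse_summary(text: str) -> ClusterSummary:
    """Parse a TSV rendering back into a :class:`ClusterSummary`."""
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    upper = df[df["cluster"] == "upper"].iloc[0]
    subs = []
    for _, r in df[df["cluster"] != "upper"].iterrows():
        subs.append(SubSummary(
            members=tuple(int(m) for m in r["members"].split("+")),
            weight=float(r["weight"]),
            mc=float(r["mc"]),
            nmc=None if r["nmc"] == "-" else float(r["nmc"]),
        ))
    return ClusterSummary(
        mc_up=float(upper["mc"]),
        nmc_up=None if upper["nmc"] == "-" else float(upper["nmc"]),
        clusters=tuple(subs),
    )
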