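"""Random mixture generators and deterministic demonstration fixtures.

The artificial-experiment generator draws 2-D Gaussian mixtures with

    K = 50,      rho ~ Dirichlet(1, ..., 1),
    mu_k ~ i.i.d. N([0, 0], 3^2 I_2),
    Sigma_k = diag(a_k, b_k),   a_k, b_k ~ i.i.d. U[0.5, 1.5],

and samples N = 5000 points ancestrally.  Every artifact of a trial is a
pure function of (root seed, trial index): each trial gets an independent
substream via ``numpy``'s ``SeedSequence([seed, trial])`` counter scheme.

Also provided: a deterministic four-component "two well-separated
overlapped pairs" model for demonstrations, a diverging-mean separation
sequence for the essential-condition checks, and a grouped mixture whose
true labels are well-separated groups of overlapping sub-components, for
studying how within-cluster MC/NMC track label purity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError
from .posterior import GaussianMixtureParams

__all__ = ["SimConfig", "random_mixture", "sample_data", "two_pair_fixture",
           "separation_sequence", "grouped_mixture"]


@dataclass(frozen=True)
class SimConfig:
    """Settings of the artificial ranking experiment.

    Defaults are the study conditions: 50 components in 2-D, flat Dirichlet
    weights, component means scattered with standard deviation 3 per axis,
    diagonal covariances with entries uniform on [0.5, 1.5], 5000 samples,
    100 trials.
    """

    n_components: int = 50
    n_samples: int = 5000
    dim: int = 2
    mean_scale: float = 3.0
    cov_range: tuple = (0.5, 1.5)
    dirichlet_alpha: float = 1.0
    n_trials: int = 100
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.cov_range
        if not (0 < lo <= hi):
            raise DomainError("cov_range must satisfy 0 < lo <= hi")
        if min(self.n_components, self.n_samples, self.dim,
               self.n_trials) < 1 or self.mean_scale <= 0 \
                or self.dirichlet_alpha <= 0:
            raise DomainError("all simulation settings must be positive")


def _trial_rng(cfg: SimConfig, trial: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, trial, stream])


def random_mixture(cfg: SimConfig, trial: int) -> GaussianMixtureParams:
    """Draw one random mixture, fully determined by (cfg.seed, trial)."""
    rng = _trial_rng(cfg, trial, 0)
    K, d = cfg.n_components, cfg.dim
    weights = rng.dirichlet(np.full(K, cfg.dirichlet_alpha))
    means = rng.normal(0.0, cfg.mean_scale, size=(K, d))
    lo, hi = cfg.cov_range
    diags = rng.uniform(lo, hi, size=(K, d))
    covs = np.zeros((K, d, d))
    for k in range(K):
        covs[k] = np.diag(diags[k])
    return GaussianMixtureParams(weights, means, covs, normalize=True)


def sample_data(params: GaussianMixtureParams, n: int, seed):
    """Ancestral sampling: component by weight, then its Gaussian.

    ``seed`` may be an int or a ``numpy`` Generator.  Returns ``(data,
    labels)`` with the generating component index per point.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = int(n)
    labels = rng.choice(params.n_components, size=n, p=params.weights)
    data = np.empty((n, params.dim))
    for k in np.unique(labels):
        idx = labels == k
        data[idx] = rng.multivariate_normal(
            params.means[k], params.covariances[k], size=int(idx.sum()))
    return data, labels


def two_pair_fixture(n: int = 2000, seed: int = 7):
    """Four 1-D components forming two tightly overlapped, well-separated
    pairs: means (0, 1.2, 10, 11.2), unit variances, equal weights.

    Within-pair separation is 1.2 standard deviations (heavy overlap, pair
    NMC well below the model's NMC0); the pairs sit 10 standard deviations
    apart (cross-pair NMC ~ 1), so NMC-stopped merging lands on exactly two
    clusters.  Deterministic for a fixed seed.
    """
    params = GaussianMixtureParams(
        weights=np.full(4, 0.25),
        means=[[0.0], [1.2], [10.0], [11.2]],
        covariances=np.ones(4),
    )
    data, labels = sample_data(params, n, np.random.default_rng([seed, 0]))
    return params, data, labels


def separation_sequence(t_max: int = 20, weights=(0.5, 0.5),
                        max_sd: float = 40.0):
    """Two 1-D unit-variance components with means diverging linearly in t.

    Element t (t = 0..t_max) has means 0 and ``max_sd * t / t_max``; at t=0
    the components are identical, and the product of their densities at any
    point vanishes as t grows — the regime of the worst-in-separation
    condition.
    """
    if t_max < 1:
        raise DomainError("t_max must be at least 1")
    out = []
    for t in range(t_max + 1):
        gap = max_sd * t / t_max
        out.append(GaussianMixtureParams(
            np.asarray(weights, dtype=float), [[0.0], [gap]], np.ones(2),
            normalize=True))
    return out


def grouped_mixture(n_groups: int = 4, comps_per_group: int = 3,
                    group_spacing: float = 20.0, within_scale: float = 1.5,
                    seed: int = 0):
    """A mixture whose components form well-separated labelled groups.

    Group centers sit on a circle of radius ``group_spacing`` in 2-D; each
    group contributes ``comps_per_group`` unit-variance components with
    means jittered N(center, within_scale^2 I), equal weights.  Returns
    ``(params, group_of_component)`` where the second item maps each
    component index to its group label — the "true" labels for studying
    cluster purity.
    """
    rng = np.random.default_rng([seed, 17])
    K = n_groups * comps_per_group
    angles = 2 * np.pi * np.arange(n_groups) / n_groups
    centers = group_spacing * np.column_stack([np.cos(angles), np.sin(angles)])
    means = np.vstack([
        centers[g] + rng.normal(0.0, within_scale, size=(comps_per_group, 2))
        for g in range(n_groups)
    ])
    covs = np.tile(np.eye(2), (K, 1, 1))
    weights = np.full(K, 1.0 / K)
    group_of_component = np.repeat(np.arange(n_groups), comps_per_group)
    return (GaussianMixtureParams(weights, means, covs, normalize=True),
            group_of_component)
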