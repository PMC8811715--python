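"""Power for two-arm cluster-randomised comparisons of proportions.

Analytic power uses the normal approximation for a two-proportion comparison
with the effective sample size deflated by the design effect for clustered
designs with unequal cluster sizes:

    DE = 1 + ((cv^2 + 1) * m_bar - 1) * rho

where ``m_bar`` is the mean cluster size, ``cv`` the coefficient of variation
of cluster size and ``rho`` the intracluster correlation coefficient.  The
simulation oracle draws cluster-level event probabilities from a beta
distribution whose dispersion matches ``rho`` (the standard exchangeable-
correlation generative model), counts events per cluster, and tests arms
with a t test on cluster-level proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerParams:
    """Design parameters for a two-arm cluster-randomised comparison.

    p0/p1 are the control and intervention proportions, ``m_bar`` the mean
    cluster size, ``size_cv`` its coefficient of variation, ``icc`` the
    intracluster correlation, ``alpha`` the two-sided significance level.
    """

    p0: float
    p1: float
    clusters_per_arm: int
    m_bar: float
    size_cv: float = 0.0
    icc: float = 0.0
    alpha: float = 0.05

    def __post_init__(self):
        if not (0 < self.p0 < 1 and 0 < self.p1 < 1):
            raise ValueError("proportions must lie strictly in (0, 1)")
        if not (0 <= self.icc < 1):
            raise ValueError("icc must lie in [0, 1)")
        if self.size_cv < 0:
            raise ValueError("size_cv must be nonnegative")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.clusters_per_arm < 2 or self.m_bar <= 0:
            raise ValueError("need at least 2 clusters per arm and positive mean size")


def design_effect(m_bar: float, size_cv: float, icc: float) -> float:
    """Variance inflation for unequal-cluster-size designs; >= 1, and 1 when
    there is no clustering (icc 0) or no grouping (m_bar 1, cv 0)."""
    return 1.0 + ((size_cv**2 + 1.0) * m_bar - 1.0) * icc


def analytic_power(params: PowerParams) -> float:
    """Normal-approximation power, both rejection tails included.

    At p0 == p1 this returns the two-sided type-I error ``alpha`` (alpha/2
    per tail).  The effective per-arm sample size is
    clusters_per_arm * m_bar / DE.
    """
    de = design_effect(params.m_bar, params.size_cv, params.icc)
    n_eff = params.clusters_per_arm * params.m_bar / de
    delta = params.p1 - params.p0
    se = np.sqrt((params.p0 * (1 - params.p0) + params.p1 * (1 - params.p1)) / n_eff)
    z = stats.norm.ppf(1 - params.alpha / 2)
    return float(stats.norm.cdf(delta / se - z) + stats.norm.cdf(-delta / se - z))


def _cluster_sizes(n: int, m_bar: float, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-distributed sizes matched to (mean, cv), rounded, floor 1."""
    if cv == 0:
        return np.full(n, max(1, round(m_bar)))
    shape = 1.0 / cv**2
    sizes = rng.gamma(shape, m_bar / shape, size=n)
    return np.maximum(1, np.rint(sizes)).astype(int)


def _cluster_events(p: float, icc: float, sizes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if icc == 0:
        probs = np.full(len(sizes), p)
    else:
        a = p * (1 - icc) / icc
        b = (1 - p) * (1 - icc) / icc
        probs = rng.beta(a, b, size=len(sizes))
    return rng.binomial(sizes, probs)


def simulated_power(
    params: PowerParams, n_reps: int, rng: np.random.Generator
) -> tuple[float, tuple[float, float]]:
    """Monte-Carlo power of the cluster-level t test under the beta-binomial
    model; returns (power, 95% MC interval)."""
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a usable estimate")
    rejections = 0
    for _ in range(n_reps):
        s0 = _cluster_sizes(params.clusters_per_arm, params.m_bar, params.size_cv, rng)
        s1 = _cluster_sizes(params.clusters_per_arm, params.m_bar, params.size_cv, rng)
        y0 = _cluster_events(params.p0, params.icc, s0, rng)
        y1 = _cluster_events(params.p1, params.icc, s1, rng)
        _, pval = stats.ttest_ind(y1 / s1, y0 / s0)
        rejections += pval < params.alpha
    est = rejections / n_reps
    half = 1.96 * np.sqrt(est * (1 - est) / n_reps)
    return est, (max(0.0, est - half), min(1.0, est + half))
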