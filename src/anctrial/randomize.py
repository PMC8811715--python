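"""Covariate-constrained, stratified 1:1 cluster randomisation.

Procedure: generate a large number of candidate stratified 1:1 allocations,
score each for covariate balance, retain the best-balanced subset, and pick
one of the retained allocations uniformly at random.  Balance is the sum over
the four constraining covariates (annual enrolments, laboratory availability,
proportion of women over 40, proportion primiparous) of the absolute
standardised difference in arm means; the standardisation (by the overall
between-cluster SD of each covariate) makes counts, binary indicators and
proportions commensurable.  Any monotone balance metric satisfies the
constrained-randomisation procedure; this one is declared and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_types import ClinicCluster

#: Constraining covariates; overridable in balance_score.
DEFAULT_COVARIATES = ("annual_enrolments", "lab_available", "prop_over40", "prop_primiparous")


@dataclass
class AllocationPlan:
    """A cluster -> arm assignment with its balance score."""

    assignment: dict  # cluster_id -> "intervention" | "control"
    stratum_sizes: dict = field(default_factory=dict)
    balance_score: Optional[float] = None
    seed: Optional[int] = None

    def arms(self, cluster_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[cid] for cid in cluster_ids])


def _strata(clusters: Sequence[ClinicCluster]) -> dict[str, list[ClinicCluster]]:
    if not clusters:
        raise ValueError("no clusters to randomise")
    strata: dict[str, list[ClinicCluster]] = {}
    for c in clusters:
        strata.setdefault(c.stratum, []).append(c)
    for name, members in strata.items():
        if not members:
            raise ValueError(f"stratum {name!r} has no clusters")
    return strata


def generate_candidates(
    clusters: Sequence[ClinicCluster], n_candidates: int, rng: np.random.Generator
) -> list[AllocationPlan]:
    """Draw ``n_candidates`` stratified 1:1 allocations (with replacement).

    Within each stratum the two arms differ in size by at most one cluster;
    for odd strata the arm receiving the extra cluster is itself randomised.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    strata = _strata(clusters)
    plans = []
    for _ in range(n_candidates):
        assignment: dict[str, str] = {}
        for members in strata.values():
            k = len(members)
            n_int = k // 2 + (rng.integers(2) if k % 2 else 0)
            perm = rng.permutation(k)
            for j, idx in enumerate(perm):
                assignment[members[idx].cluster_id] = "intervention" if j < n_int else "control"
        plans.append(AllocationPlan(assignment, {s: len(m) for s, m in strata.items()}))
    return plans


def balance_score(
    plan: AllocationPlan,
    clusters: Sequence[ClinicCluster],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> float:
    """Sum of absolute standardised arm-mean differences over the covariates.

    Zero iff the two arms have identical means on all four covariates.  A
    covariate with zero between-cluster SD contributes its raw absolute
    difference (necessarily zero when constant).
    """
    ids = [c.cluster_id for c in clusters]
    arms = plan.arms(ids)
    mask_i = arms == "intervention"
    mask_c = arms == "control"
    score = 0.0
    for name in covariates:
        try:
            x = np.array([float(getattr(c, name)) for c in clusters])
        except (AttributeError, TypeError) as e:
            raise ValueError(f"missing constraining covariate {name!r}") from e
        if np.any(np.isnan(x)):
            raise ValueError(f"missing values in constraining covariate {name!r}")
        sd = x.std()
        diff = abs(x[mask_i].mean() - x[mask_c].mean())
        score += diff / sd if sd > 0 else diff
    return float(score)


def select_allocation(
    candidates: Sequence[AllocationPlan],
    keep_best: int,
    rng: np.random.Generator,
    clusters: Optional[Sequence[ClinicCluster]] = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> AllocationPlan:
    """Retain the ``keep_best`` best-balanced candidates, pick one uniformly.

    Scores are computed here when absent.  Ties at the retention boundary are
    broken by candidate index, making selection reproducible for a given rng.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if keep_best > len(candidates):
        raise ValueError("keep_best exceeds the number of candidates")
    for plan in candidates:
        if plan.balance_score is None:
            if clusters is None:
                raise ValueError("clusters required to score unscored candidates")
            plan.balance_score = balance_score(plan, clusters, covariates)
    order = sorted(range(len(candidates)), key=lambda i: (candidates[i].balance_score, i))
    retained = [candidates[i] for i in order[:keep_best]]
    return retained[int(rng.integers(len(retained)))]


def constrained_randomize(
    clusters: Sequence[ClinicCluster],
    seed: int,
    n_candidates: int = 10_000,
    keep_best: int = 1_000,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    assign: bool = True,
) -> AllocationPlan:
    """The full procedure: candidates -> scores -> retained set -> one draw.

    Defaults follow the trial design: 10 000 candidate sequences, the 1000
    best-balanced retained, one selected at random.  With ``assign`` the
    chosen arms are written back onto the cluster objects.
    """
    rng = np.random.default_rng(seed)
    cands = generate_candidates(clusters, n_candidates, rng)
    plan = select_allocation(cands, keep_best, rng, clusters, covariates)
    plan.seed = seed
    if assign:
        for c in clusters:
            c.arm = plan.assignment[c.cluster_id]
    return plan
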