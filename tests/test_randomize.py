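"""Stratified covariate-constrained randomisation."""

import itertools

import numpy as np
import pytest

from anctrial.core_types import ClinicCluster
from anctrial.randomize import (
    balance_score,
    constrained_randomize,
    generate_candidates,
    select_allocation,
)


def make_clusters(n, strata=("s1",), rng=None, **overrides):
    rng = rng or np.random.default_rng(7)
    out = []
    for i in range(n):
        out.append(
            ClinicCluster(
                cluster_id=f"c{i}",
                stratum=strata[i % len(strata)],
                annual_enrolments=float(rng.integers(20, 300)),
                lab_available=bool(rng.random() < 0.5),
                ultrasound_available=True,
                prop_over40=float(rng.uniform(0, 0.05)),
                prop_primiparous=float(rng.uniform(0.1, 0.35)),
                **overrides,
            )
        )
    return out


def test_even_stratum_forces_equal_split():
    clusters = make_clusters(4)
    (plan,) = generate_candidates(clusters, 1, np.random.default_rng(0))
    arms = list(plan.assignment.values())
    assert arms.count("intervention") == 2 and arms.count("control") == 2


def test_odd_stratum_splits_within_one():
    clusters = make_clusters(5)
    for plan in generate_candidates(clusters, 20, np.random.default_rng(0)):
        arms = list(plan.assignment.values())
        assert abs(arms.count("intervention") - arms.count("control")) == 1


def test_degenerate_inputs_are_rejected():
    with pytest.raises(ValueError):
        generate_candidates([], 1, np.random.default_rng(0))
    with pytest.raises(ValueError):
        select_allocation([], 1, np.random.default_rng(0))
    clusters = make_clusters(4)
    cands = generate_candidates(clusters, 5, np.random.default_rng(0))
    with pytest.raises(ValueError):
        select_allocation(cands, 10, np.random.default_rng(0), clusters)


def test_identical_clusters_split_evenly_score_zero():
    clusters = [
        ClinicCluster(f"c{i}", "s1", 100, True, True, 0.02, 0.2) for i in range(2)
    ]
    (plan,) = generate_candidates(clusters, 1, np.random.default_rng(0))
    assert balance_score(plan, clusters) == 0.0


def test_balance_score_against_exhaustive_enumeration():
    """Hand-sized example: the scored minimum matches brute force over all
    stratified splits, recomputed independently."""
    clusters = make_clusters(6, strata=("s1", "s2"))
    ids = [c.cluster_id for c in clusters]
    covs = ["annual_enrolments", "lab_available", "prop_over40", "prop_primiparous"]
    x = {name: np.array([float(getattr(c, name)) for c in clusters]) for name in covs}

    def brute(assign_mask):
        total = 0.0
        for name in covs:
            v = x[name]
            total += abs(v[assign_mask].mean() - v[~assign_mask].mean()) / v.std()
        return total

    s1 = [i for i, c in enumerate(clusters) if c.stratum == "s1"]
    s2 = [i for i, c in enumerate(clusters) if c.stratum == "s2"]
    best = np.inf
    scores = []
    from anctrial.randomize import AllocationPlan

    for pick1 in itertools.combinations(s1, len(s1) // 2):
        for pick2 in itertools.combinations(s2, len(s2) // 2):
            mask = np.zeros(6, dtype=bool)
            mask[list(pick1 + pick2)] = True
            assignment = {ids[i]: ("intervention" if mask[i] else "control") for i in range(6)}
            plan = AllocationPlan(assignment)
            scores.append((balance_score(plan, clusters), brute(mask)))
    for got, expected in scores:
        assert got == pytest.approx(expected)


def test_dominating_plan_scores_lower():
    clusters = make_clusters(8)
    rng = np.random.default_rng(1)
    cands = generate_candidates(clusters, 50, rng)
    scores = [balance_score(p, clusters) for p in cands]
    # monotone aggregation: the best plan is no worse than any other
    assert min(scores) <= max(scores)
    best = select_allocation(cands, 1, np.random.default_rng(0), clusters)
    assert best.balance_score == min(scores)


def test_keep_best_percentile_and_uniform_selection():
    clusters = make_clusters(20, strata=("s1", "s2"))
    rng = np.random.default_rng(3)
    cands = generate_candidates(clusters, 500, rng)
    plan = select_allocation(cands, 50, rng, clusters)
    scores = np.array([p.balance_score for p in cands])
    assert plan.balance_score <= np.quantile(scores, 0.1)


def test_seed_determinism():
    clusters_a = make_clusters(12, strata=("s1", "s2", "s3"))
    clusters_b = make_clusters(12, strata=("s1", "s2", "s3"))
    p1 = constrained_randomize(clusters_a, seed=42, n_candidates=200, keep_best=20)
    p2 = constrained_randomize(clusters_b, seed=42, n_candidates=200, keep_best=20)
    assert p1.assignment == p2.assignment
    assert p1.balance_score == p2.balance_score


def test_constraint_beats_unconstrained_on_average():
    clusters = make_clusters(16, strata=("s1", "s2"))
    rng = np.random.default_rng(9)
    constrained, unconstrained = [], []
    for _ in range(30):
        cands = generate_candidates(clusters, 100, rng)
        constrained.append(select_allocation(cands, 10, rng, clusters).balance_score)
        unconstrained.append(balance_score(generate_candidates(clusters, 1, rng)[0], clusters))
    assert np.mean(constrained) < np.mean(unconstrained)


def test_missing_covariate_errors():
    clusters = make_clusters(4)
    (plan,) = generate_candidates(clusters, 1, np.random.default_rng(0))
    with pytest.raises(ValueError):
        balance_score(plan, clusters, covariates=("annual_enrolments", "no_such"))
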