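"""Synthetic cohort generator: determinism, calibration, no-leakage."""

import numpy as np
import pandas as pd
import pytest

from anctrial.core_types import validate_pregnancy
from anctrial.schedule import attendance_opportunities, attended_full_schedule
from anctrial.simulate import SimConfig, inject_missingness, simulate_trial, validate_config


def _cfg(**kw):
    defaults = dict(n_clusters=20, cluster_size_mean=15, n_candidates=100, keep_best=10)
    defaults.update(kw)
    return SimConfig(**defaults)


def test_seed_determinism():
    a = simulate_trial(_cfg(), seed=5)
    b = simulate_trial(_cfg(), seed=5)
    assert a.ground_truth == b.ground_truth
    assert a.pregnancies == b.pregnancies
    c = simulate_trial(_cfg(), seed=6)
    assert c.pregnancies != a.pregnancies


def test_generated_records_are_valid(small_trial):
    for p in small_trial.pregnancies:
        assert validate_pregnancy(p) == []


def test_cluster_sizes_match_mean_and_cv():
    cfg = SimConfig(n_clusters=400, cluster_size_mean=44, cluster_size_cv=0.85,
                    n_candidates=50, keep_best=5)
    sim = simulate_trial(cfg, seed=9)
    sizes = pd.Series([p.cluster_id for p in sim.pregnancies]).value_counts()
    assert sizes.mean() == pytest.approx(44, rel=0.12)
    assert sizes.std() / sizes.mean() == pytest.approx(0.85, abs=0.12)


def test_invalid_config_names_field():
    with pytest.raises(ValueError, match="attendance_mean"):
        validate_config(_cfg(attendance_mean=1.4))
    with pytest.raises(ValueError, match="icc_process"):
        validate_config(_cfg(icc_process=1.0))
    with pytest.raises(ValueError, match="missing_mechanism"):
        validate_config(_cfg(missing_mechanism="sometimes"))
    with pytest.raises(ValueError, match="doc_screen.anaemia"):
        validate_config(_cfg(doc_screen={"anaemia": 1.2}))


def test_null_arm_effect_gives_exchangeable_arms():
    from anctrial.adjudicate import adjudicate_all_processes

    cfg = _cfg(n_clusters=60, cluster_size_mean=25, arm_effect_logor=0.0)
    sim = simulate_trial(cfg, seed=31)
    proc = adjudicate_all_processes(sim.pregnancies, conditions=("anaemia",))
    cl = {p.pregnancy_id: p.cluster_id for p in sim.pregnancies}
    arm = {cid: a for cid, a in sim.allocation.assignment.items()}
    proc["arm"] = proc["pregnancy_id"].map(cl).map(arm)
    p0 = proc.loc[proc.arm == "control", "success"].mean()
    p1 = proc.loc[proc.arm == "intervention", "success"].mean()
    assert abs(p1 - p0) < 0.08  # Monte-Carlo margin incl. clustering


def test_no_leakage_into_physiology():
    """The arm affects documentation only: measured physiology and delivery
    outcomes have the same distribution in both arms."""
    cfg = _cfg(n_clusters=80, cluster_size_mean=30, arm_effect_logor=np.log(3.0))
    sim = simulate_trial(cfg, seed=17)
    arm_of = sim.allocation.assignment
    rows = []
    for p in sim.pregnancies:
        if p.delivery and p.delivery.birthweight is not None:
            rows.append((arm_of[p.cluster_id], p.delivery.birthweight))
    df = pd.DataFrame(rows, columns=["arm", "bw"])
    means = df.groupby("arm")["bw"].mean()
    assert abs(means["intervention"] - means["control"]) < 30  # g, MC margin
    # documented haemoglobin values (not their presence) also match
    hbs = {"control": [], "intervention": []}
    for p in sim.pregnancies:
        for c in p.contacts:
            if c.hb is not None:
                hbs[arm_of[p.cluster_id]].append(c.hb)
    assert abs(np.mean(hbs["control"]) - np.mean(hbs["intervention"])) < 0.15
    # ... while documentation frequency itself differs strongly
    n_c = sum(1 for p in sim.pregnancies if arm_of[p.cluster_id] == "control" for c in p.contacts)
    n_i = sum(1 for p in sim.pregnancies if arm_of[p.cluster_id] == "intervention" for c in p.contacts)
    assert len(hbs["intervention"]) / n_i > len(hbs["control"]) / n_c + 0.1


def test_attendance_calibration(small_trial):
    full = np.mean([attended_full_schedule(p) for p in small_trial.pregnancies])
    opp = [
        (o.attended, o.in_denominator)
        for p in small_trial.pregnancies
        for o in attendance_opportunities(p)
    ]
    att = sum(a for a, d in opp if d) / sum(d for _, d in opp)
    assert full == pytest.approx(0.094, abs=0.04)
    assert att == pytest.approx(0.43, abs=0.06)


def test_delivery_missingness_rates(small_trial):
    cfg_rates = SimConfig().missing_delivery
    deliveries = [p.delivery for p in small_trial.pregnancies if p.delivery is not None]
    n = len(deliveries)
    hb_missing = sum(d.admission_hb is None for d in deliveries) / n
    bp_missing = sum(d.admission_sbp is None for d in deliveries) / n
    assert hb_missing == pytest.approx(cfg_rates["admission_hb"], abs=0.05)
    assert bp_missing == pytest.approx(cfg_rates["admission_bp"], abs=0.05)
    # BP is documented (or not) as a pair
    assert all((d.admission_sbp is None) == (d.admission_dbp is None) for d in deliveries)


# --- inject_missingness ----------------------------------------------------


def _table(n=2000, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)}), rng


def test_inject_zero_rate_leaves_table_unchanged():
    df, rng = _table()
    out = inject_missingness(df, "mcar", {"a": 0.0}, rng)
    pd.testing.assert_frame_equal(out, df)


def test_inject_mcar_rate_matches():
    df, rng = _table()
    out = inject_missingness(df, "mcar", {"a": 0.3}, rng)
    assert out["a"].isna().mean() == pytest.approx(0.3, abs=0.025)


def test_inject_mar_and_mnar_marginal_rates_match():
    df, rng = _table()
    cov = df["b"]
    mar = inject_missingness(df, "mar_covariate", {"a": 0.25}, rng, covariate=cov)
    assert mar["a"].isna().mean() == pytest.approx(0.25, abs=0.03)
    mnar = inject_missingness(df, "mnar_outcome", {"a": 0.25}, rng)
    assert mnar["a"].isna().mean() == pytest.approx(0.25, abs=0.03)
    # MNAR missingness depends on the value: observed mean is shifted
    assert mnar["a"].mean() < df["a"].mean() - 0.1


def test_inject_unknown_mechanism_errors():
    df, rng = _table(50)
    with pytest.raises(ValueError):
        inject_missingness(df, "sometimes", {"a": 0.2}, rng)


def test_mnar_raises_little_power_over_mcar():
    from anctrial.analysis import little_mcar_test

    rng = np.random.default_rng(4)
    rej = {"mcar": 0, "mnar_outcome": 0}
    for mech in rej:
        for _ in range(15):
            z = rng.normal(size=800)
            df = pd.DataFrame({
                "a": z + rng.normal(0, 0.5, 800),
                "b": z + rng.normal(0, 0.5, 800),
            })
            out = inject_missingness(df, mech, {"a": 0.3}, rng, slope=2.5)
            rej[mech] += little_mcar_test(out).p_value < 0.05
    assert rej["mnar_outcome"] > rej["mcar"]
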