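"""Inference pipeline: GLMM bridge, re-expression, missing-data tools, pooling."""

import math

import numpy as np
import pandas as pd
import pytest

from anctrial.analysis import (
    ModelSpec,
    estimate_icc,
    fit_adherence_model,
    fit_glmm_logit,
    fit_logit_random_intercept_gh,
    little_mcar_test,
    mice_impute,
    or_to_per_1000,
    rubin_pool,
)


# --- OR re-expression ------------------------------------------------------


def test_or_one_maps_to_zero_for_any_baseline():
    for p0 in (0.05, 0.288, 0.7):
        assert or_to_per_1000(1.0, p0) == pytest.approx(0.0)


def test_or_to_per_1000_limit_and_closed_form():
    assert or_to_per_1000(1e9, 0.5) == pytest.approx(500.0, abs=0.01)
    # closed-form arithmetic: odds 0.288/0.712 * 1.88 -> p1 = 0.4319...
    assert or_to_per_1000(1.88, 0.288) == pytest.approx(143.96, abs=0.05)


def test_or_to_per_1000_rejects_bad_inputs():
    with pytest.raises(ValueError):
        or_to_per_1000(1.5, 0.0)
    with pytest.raises(ValueError):
        or_to_per_1000(-1.0, 0.3)


# --- Rubin's rules ---------------------------------------------------------


def test_rubin_two_imputation_hand_example():
    pooled = rubin_pool([0.0, 1.0], [0.0, 0.0])
    assert pooled.estimate == pytest.approx(0.5)
    assert pooled.between_var == pytest.approx(0.5)
    assert pooled.within_var == pytest.approx(0.0)
    assert pooled.total_var == pytest.approx(0.75)  # W + (1 + 1/2) B
    assert pooled.m == 2


def test_rubin_identical_estimates_have_no_between_variance():
    pooled = rubin_pool([0.3] * 5, [0.04] * 5)
    assert pooled.between_var == 0.0
    assert pooled.total_var == pytest.approx(0.04)
    assert math.isinf(pooled.df)


def test_rubin_ci_widens_with_between_variance():
    narrow = rubin_pool([0.3, 0.31, 0.29], [0.01] * 3)
    wide = rubin_pool([0.1, 0.5, 0.3], [0.01] * 3)
    assert (wide.ci[1] - wide.ci[0]) > (narrow.ci[1] - narrow.ci[0])


def test_rubin_total_variance_identity_holds():
    rng = np.random.default_rng(0)
    q = rng.normal(size=8)
    w = rng.uniform(0.01, 0.1, size=8)
    pooled = rubin_pool(q, w)
    assert pooled.total_var == pytest.approx(pooled.within_var + (1 + 1 / 8) * pooled.between_var)


def test_rubin_rejects_mismatched_lengths():
    with pytest.raises(ValueError):
        rubin_pool([0.1, 0.2], [0.01])


# --- Little's MCAR test ----------------------------------------------------


def test_little_degenerate_without_missingness():
    df = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 3)))
    with pytest.warns(UserWarning):
        res = little_mcar_test(df)
    assert res.p_value == 1.0


def test_little_type_one_error_under_mcar():
    rng = np.random.default_rng(42)
    rej = 0
    reps = 150
    for _ in range(reps):
        X = rng.normal(size=(200, 3))
        X[rng.random((200, 3)) < 0.25] = np.nan
        rej += little_mcar_test(pd.DataFrame(X)).p_value < 0.05
    assert 0.02 <= rej / reps <= 0.09


def test_little_detects_value_dependent_missingness():
    rng = np.random.default_rng(7)
    rej = 0
    for _ in range(20):
        z = rng.normal(size=1500)
        X = np.column_stack([z + rng.normal(0, 0.6, 1500) for _ in range(3)])
        p = 1 / (1 + np.exp(-(-1.2 + 1.5 * X[:, 0])))
        X[rng.random(1500) < p, 0] = np.nan
        X[rng.random(1500) < 0.2, 1] = np.nan
        rej += little_mcar_test(pd.DataFrame(X)).p_value < 0.05
    assert rej / 20 > 0.5


# --- MICE ------------------------------------------------------------------


def test_mice_no_missingness_returns_identical_copies():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 0.0]})
    for imp in mice_impute(df, 3, np.random.default_rng(0)):
        pd.testing.assert_frame_equal(imp, df)


def test_mice_never_alters_observed_values_and_is_deterministic():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({"y": (rng.random(200) < 0.3).astype(float), "x": rng.normal(size=200)})
    df.loc[rng.random(200) < 0.3, "y"] = np.nan
    obs = df["y"].notna()
    a = mice_impute(df, 3, np.random.default_rng(11), n_cycles=3)
    b = mice_impute(df, 3, np.random.default_rng(11), n_cycles=3)
    for ia, ib in zip(a, b):
        pd.testing.assert_frame_equal(ia, ib)  # bit-identical under a fixed seed
        assert (ia.loc[obs, "y"] == df.loc[obs, "y"]).all()
        assert ia["y"].notna().all()


def test_mice_recovers_prevalence_under_mcar():
    rng = np.random.default_rng(5)
    y = (rng.random(1500) < 0.2).astype(float)
    x = y + rng.normal(0, 1, 1500)
    df = pd.DataFrame({"y": y, "x": x})
    df.loc[rng.random(1500) < 0.3, "y"] = np.nan
    imps = mice_impute(df, 8, np.random.default_rng(6), n_cycles=4)
    prev = np.mean([im["y"].mean() for im in imps])
    assert prev == pytest.approx(0.2, abs=0.03)


def test_mice_rejects_all_missing_variable():
    df = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
    with pytest.raises(ValueError):
        mice_impute(df, 2, np.random.default_rng(0))


# --- GLMM bridge and ICC ---------------------------------------------------


def _sim_cluster_logit(rng, n_clusters=40, m=25, beta_arm=0.0, sigma=0.4):
    g = np.repeat(np.arange(n_clusters), m)
    arm = (g % 2 == 0).astype(int)
    u = rng.normal(0, sigma, n_clusters)[g]
    eta = -0.4 + beta_arm * arm + u
    y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    return pd.DataFrame({"y": y, "arm": arm, "cluster_id": g, "pregnancy_id": np.arange(len(g))})


def test_glmm_bridge_matches_quadrature_oracle():
    """lme4 route and the in-package Gauss-Hermite ML fitter agree."""
    rng = np.random.default_rng(21)
    df = _sim_cluster_logit(rng, n_clusters=30, m=20, beta_arm=0.6)
    fits = fit_glmm_logit(df, ["arm"], ["cluster_id"])
    coef = fits[(fits["kind"] == "coef") & (fits["term"] == "arm")].iloc[0]
    X = np.column_stack([np.ones(len(df)), df["arm"].to_numpy()])
    gh = fit_logit_random_intercept_gh(df["y"].to_numpy(), X, df["cluster_id"].to_numpy())
    assert coef["estimate"] == pytest.approx(gh["beta"][1], abs=0.01)
    assert coef["se"] == pytest.approx(gh["se"][1], abs=0.02)


def test_adherence_model_requires_two_arms():
    rng = np.random.default_rng(0)
    df = _sim_cluster_logit(rng)
    df["arm"] = 1
    with pytest.raises(ValueError):
        fit_adherence_model(df, ModelSpec(outcome="y"))


def test_contact_level_spec_requires_pregnancy_effect():
    with pytest.raises(ValueError):
        ModelSpec(outcome="y", unit="contact", random_effects=("cluster_id",))


def test_estimate_icc_recovers_simulated_value():
    rng = np.random.default_rng(13)
    icc_true = 0.05
    sigma = math.sqrt(icc_true / (1 - icc_true) * math.pi**2 / 3)
    df = _sim_cluster_logit(rng, n_clusters=100, m=40, sigma=sigma)
    est = estimate_icc(df)
    assert est.icc == pytest.approx(icc_true, abs=0.03)


def test_estimate_icc_rejects_single_cluster():
    df = pd.DataFrame({"y": [0, 1, 1], "cluster_id": ["a"] * 3})
    with pytest.raises(ValueError):
        estimate_icc(df)
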