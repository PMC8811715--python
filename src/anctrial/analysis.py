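"""The trial's inference pipeline.

Covers the statistical procedures applied to the adjudicated outcomes:

* mixed-effects logistic regression for process (contact-level, random
  intercepts for clinic and pregnancy) and delivery (pregnancy-level, clinic
  random intercept) outcomes, reporting cluster-specific adjusted odds
  ratios;
* re-expression of an OR as additional successes per 1000 women at a given
  control-group baseline risk;
* Little's chi-square test that missing constituent-outcome values are
  jointly missing completely at random;
* multiple imputation by chained equations (logistic models for binary
  variables, Bayesian linear models for continuous ones) and Rubin's rules
  for pooling;
* latent-scale intracluster correlation from a random-intercept logistic
  fit.

The generalised-linear-mixed-model optimisation itself is delegated to
lme4::glmer, driven through ``Rscript``; this module owns data assembly,
adjustment sets, nesting structure, imputation orchestration, pooling, and
re-expression.  A pure-Python Gauss-Hermite-quadrature fitter for the
single-random-intercept model is included as an independent numerical
cross-check.
"""

from __future__ import annotations

import logging
import math
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger("anctrial")

_R_SCRIPT = Path(__file__).parent / "data" / "glmm_logit.R"


# ---------------------------------------------------------------------------
# GLMM bridge
# ---------------------------------------------------------------------------


def fit_glmm_logit(
    df: pd.DataFrame,
    fixed: Sequence[str],
    groups: Sequence[str],
    outcome: str = "y",
    rep_col: Optional[str] = None,
    ci: str = "none",
) -> pd.DataFrame:
    """Fit ``outcome ~ fixed + (1|g) for g in groups`` by Laplace ML (lme4).

    When ``rep_col`` is given, each distinct value is fitted independently in
    a single R invocation (used to batch simulation replicates and multiple
    imputations).  Returns a tidy frame with columns
    rep/kind/term/estimate/se/lo/hi/fallback; ``kind`` is "coef" for fixed
    effects, "vc" for random-intercept standard deviations and "meta" for the
    convergence flag.
    """
    cols = [outcome, *fixed, *groups] + ([rep_col] if rep_col else [])
    sub = df[list(dict.fromkeys(cols))].copy()
    sub = sub.rename(columns={outcome: "y"})
    if rep_col:
        sub = sub.rename(columns={rep_col: ".rep"})
    sub["y"] = sub["y"].astype(int)
    rhs = " + ".join(fixed) if fixed else "1"
    with tempfile.TemporaryDirectory() as tmp:
        dat = Path(tmp) / "dat.csv"
        out = Path(tmp) / "fit.csv"
        sub.to_csv(dat, index=False)
        cmd = ["Rscript", "--vanilla", str(_R_SCRIPT), str(dat), str(out), rhs, ",".join(groups), ci]
        res = subprocess.run(cmd, capture_output=True, text=True)
        if res.returncode != 0 or not out.exists():
            raise RuntimeError(f"glmm fit failed: {res.stderr[-2000:]}")
        fits = pd.read_csv(out)
    if (fits.loc[fits["kind"] == "meta", "fallback"] == 1).any():
        logger.warning("glmm: pregnancy-level random effect dropped on non-convergence for some fits")
    return fits


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, unit of analysis, nesting, and adjustment set.

    Contact-level outcomes include a pregnancy random effect nested in the
    clinic effect; the stratification variable is excluded from the
    adjustment set for the severe-hypertension constituent (it can separate
    that rare outcome perfectly).
    """

    outcome: str
    unit: str = "contact"  # "contact" | "pregnancy"
    random_effects: tuple = ("cluster_id", "pregnancy_id")
    fixed_adjustments: tuple = ()
    alpha: float = 0.05

    def __post_init__(self):
        if self.unit == "contact" and "pregnancy_id" not in self.random_effects:
            raise ValueError("contact-level models must include the pregnancy random effect")


@dataclass
class OrEstimate:
    """A fitted (or pooled) arm effect on the odds-ratio scale."""

    logor: float
    se: float
    or_: float
    ci: tuple
    converged: bool = True
    fallback: bool = False
    n: int = 0
    vc: dict = field(default_factory=dict)


def _arm_row(fits: pd.DataFrame, term: str = "arm") -> pd.Series:
    coefs = fits[(fits["kind"] == "coef") & (fits["term"] == term)]
    if coefs.empty:
        raise RuntimeError(f"term {term!r} not found in fitted model")
    return coefs.iloc[0]


def fit_adherence_model(
    adjudications: pd.DataFrame,
    spec: ModelSpec,
    arm_col: str = "arm",
) -> OrEstimate:
    """Cluster-specific adjusted OR for intervention vs control.

    ``adjudications`` needs one row per unit with the binary outcome column
    named by ``spec.outcome``, an ``arm`` column coded 0 (control) / 1
    (intervention), the grouping columns, and any adjustment columns.
    """
    arms = set(pd.unique(adjudications[arm_col]))
    if len(arms) < 2:
        raise ValueError("both trial arms are required to estimate an arm effect")
    fixed = [arm_col, *spec.fixed_adjustments]
    fits = fit_glmm_logit(adjudications, fixed, list(spec.random_effects), outcome=spec.outcome)
    row = _arm_row(fits, arm_col)
    z = stats.norm.ppf(1 - spec.alpha / 2)
    est, se = float(row["estimate"]), float(row["se"])
    vc = {
        r["term"]: float(r["estimate"]) for _, r in fits[fits["kind"] == "vc"].iterrows()
    }
    conv = bool(fits.loc[fits["kind"] == "meta", "estimate"].iloc[0])
    fb = bool(fits["fallback"].iloc[0])
    return OrEstimate(
        logor=est, se=se, or_=math.exp(est),
        ci=(math.exp(est - z * se), math.exp(est + z * se)),
        converged=conv, fallback=fb, n=len(adjudications), vc=vc,
    )


# ---------------------------------------------------------------------------
# OR re-expression
# ---------------------------------------------------------------------------


def or_to_per_1000(or_: float, p0: float) -> float:
    """Additional successes per 1000 women implied by an OR at baseline risk p0.

    The baseline odds are taken from the control proportion; the intervention
    proportion is the OR applied to those odds, and the result is 1000 times
    the risk difference.  This is the standard conditional-OR-to-risk
    conversion; with cluster-specific ORs it is an approximation whose
    baseline (marginal vs raw control proportion) is the caller's choice.
    """
    if not (0 < p0 < 1):
        raise ValueError("p0 must lie strictly in (0, 1)")
    if or_ <= 0:
        raise ValueError("or_ must be positive")
    odds0 = p0 / (1 - p0)
    p1 = or_ * odds0 / (1 + or_ * odds0)
    return 1000.0 * (p1 - p0)


# ---------------------------------------------------------------------------
# Little's MCAR test
# ---------------------------------------------------------------------------


def _em_mvnorm(Y: np.ndarray, max_iter: int = 200, tol: float = 1e-7):
    """ML mean and covariance of an incomplete multivariate-normal sample (EM)."""
    n, p = Y.shape
    mu = np.nanmean(Y, axis=0)
    var = np.nanvar(Y, axis=0)
    var[var <= 0] = 1e-6
    sigma = np.diag(var)
    miss = np.isnan(Y)
    patterns = {}
    for i in range(n):
        patterns.setdefault(miss[i].tobytes(), []).append(i)
    for _ in range(max_iter):
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for key, rows in patterns.items():
            mask = np.frombuffer(key, dtype=bool)
            o, m = ~mask, mask
            Yo = Y[np.ix_(rows, np.where(o)[0])]
            if not m.any():
                sum_x += Yo.sum(axis=0)
                sum_xx += Yo.T @ Yo
                continue
            Soo = sigma[np.ix_(o, o)]
            Smo = sigma[np.ix_(m, o)]
            reg = np.linalg.solve(Soo + 1e-10 * np.eye(o.sum()), Smo.T).T
            cond_mean = mu[m] + (Yo - mu[o]) @ reg.T
            cond_cov = sigma[np.ix_(m, m)] - reg @ Smo.T
            X = np.empty((len(rows), p))
            X[:, o] = Yo
            X[:, m] = cond_mean
            sum_x += X.sum(axis=0)
            xx = X.T @ X
            mm = np.ix_(np.where(m)[0], np.where(m)[0])
            xx[mm] += len(rows) * cond_cov
            sum_xx += xx
        mu_new = sum_x / n
        sigma_new = sum_xx / n - np.outer(mu_new, mu_new)
        sigma_new += 1e-10 * np.eye(p)
        if np.max(np.abs(mu_new - mu)) < tol and np.max(np.abs(sigma_new - sigma)) < tol:
            mu, sigma = mu_new, sigma_new
            break
        mu, sigma = mu_new, sigma_new
    return mu, sigma, patterns


@dataclass(frozen=True)
class LittleResult:
    statistic: float
    df: int
    p_value: float
    n_patterns: int


def little_mcar_test(df: pd.DataFrame) -> LittleResult:
    """Little's chi-square test of missing completely at random.

    Compares pattern-wise observed means with the EM maximum-likelihood
    estimates; the statistic is the sum of Mahalanobis distances weighted by
    pattern size and is chi-square with (sum of per-pattern observed-variable
    counts minus the variable count) degrees of freedom under MCAR.  With a
    single missingness pattern (e.g. no missing data) the test is degenerate
    and returns p = 1 with a warning.
    """
    Y = df.to_numpy(dtype=float)
    Y = Y[~np.all(np.isnan(Y), axis=1)]
    n, p = Y.shape
    mu, sigma, patterns = _em_mvnorm(Y)
    if len(patterns) < 2:
        warnings.warn("single missingness pattern: Little's test is degenerate, p = 1")
        return LittleResult(0.0, 0, 1.0, len(patterns))
    d2 = 0.0
    df_total = 0
    for key, rows in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        o = np.where(~mask)[0]
        if len(o) == 0:
            continue
        ybar = Y[np.ix_(rows, o)].mean(axis=0)
        diff = ybar - mu[o]
        Soo = sigma[np.ix_(o, o)]
        d2 += len(rows) * float(diff @ np.linalg.solve(Soo, diff))
        df_total += len(o)
    dof = df_total - p
    if dof <= 0:
        warnings.warn("degenerate degrees of freedom in Little's test, p = 1")
        return LittleResult(float(d2), max(dof, 0), 1.0, len(patterns))
    return LittleResult(float(d2), dof, float(stats.chi2.sf(d2, dof)), len(patterns))


# ---------------------------------------------------------------------------
# Multiple imputation by chained equations
# ---------------------------------------------------------------------------


def _ridge_logit(X: np.ndarray, y: np.ndarray, lam: float = 1e-3, max_iter: int = 50):
    """IRLS logistic regression with a small ridge; returns (beta, cov)."""
    k = X.shape[1]
    beta = np.zeros(k)
    I = lam * np.eye(k)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = special.expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        H = (X * w[:, None]).T @ X + I
        g = X.T @ (y - mu) - lam * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = special.expit(eta)
    w = np.maximum(mu * (1 - mu), 1e-10)
    cov = np.linalg.inv((X * w[:, None]).T @ X + I)
    return beta, cov


def mice_impute(
    df: pd.DataFrame,
    m: int,
    rng: np.random.Generator,
    n_cycles: int = 10,
    binary: Optional[Sequence[str]] = None,
) -> list[pd.DataFrame]:
    """Chained-equations multiple imputation: ``m`` completed copies of ``df``.

    Binary variables (auto-detected as {0,1}-valued unless listed) are
    imputed from Bayesian logistic regressions, continuous variables from
    Bayesian linear regressions, each conditional on all other variables,
    cycling ``n_cycles`` times per imputation.  Observed values are never
    altered; with no missing data the copies are identical to the input.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    num = df.astype(float)
    cols = list(num.columns)
    miss = num.isna()
    if (miss.all(axis=0)).any():
        bad = list(num.columns[miss.all(axis=0)])
        raise ValueError(f"variables with no observed values cannot be imputed: {bad}")
    if binary is None:
        binary = [c for c in cols if set(num[c].dropna().unique()) <= {0.0, 1.0}]
    targets = [c for c in cols if miss[c].any()]
    targets.sort(key=lambda c: miss[c].sum())
    if not targets:
        return [df.copy() for _ in range(m)]

    out = []
    X_all = num.to_numpy()
    for _ in range(m):
        work = X_all.copy()
        # initial fill: bootstrap draws from each variable's observed values
        for j, c in enumerate(cols):
            idx = np.where(miss[c].to_numpy())[0]
            if idx.size:
                obs = work[~miss[c].to_numpy(), j]
                work[idx, j] = rng.choice(obs, size=idx.size, replace=True)
        for _cycle in range(n_cycles):
            for c in targets:
                j = cols.index(c)
                mis_rows = miss[c].to_numpy()
                others = [k for k in range(len(cols)) if k != j]
                X = np.column_stack([np.ones(len(work)), work[:, others]])
                y = work[:, j]
                Xo, yo = X[~mis_rows], y[~mis_rows]
                Xm = X[mis_rows]
                if c in binary:
                    beta, cov = _ridge_logit(Xo, yo)
                    bstar = rng.multivariate_normal(beta, cov, method="cholesky")
                    pmis = special.expit(np.clip(Xm @ bstar, -30, 30))
                    work[mis_rows, j] = (rng.random(mis_rows.sum()) < pmis).astype(float)
                else:
                    XtX = Xo.T @ Xo + 1e-8 * np.eye(Xo.shape[1])
                    beta = np.linalg.solve(XtX, Xo.T @ yo)
                    resid = yo - Xo @ beta
                    dof = max(len(yo) - Xo.shape[1], 1)
                    s2 = float(resid @ resid) / dof
                    sigma2 = s2 * dof / rng.chisquare(dof)
                    cov = sigma2 * np.linalg.inv(XtX)
                    bstar = rng.multivariate_normal(beta, cov, method="cholesky")
                    work[mis_rows, j] = Xm @ bstar + rng.normal(0, math.sqrt(sigma2), mis_rows.sum())
        filled = pd.DataFrame(work, columns=cols, index=df.index)
        out.append(filled)
    return out


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin-pooled estimate on the log-odds scale, with its OR re-expression."""

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    m: int
    df: float
    or_: float
    ci: tuple


def rubin_pool(
    estimates: Sequence[float],
    variances: Sequence[float],
    alpha: float = 0.05,
    df_com: float = math.inf,
) -> PooledEstimate:
    """Pool per-imputation estimates and variances by Rubin's rules.

    T = W + (1 + 1/m) B; the CI uses a t quantile with Barnard-Rubin
    degrees of freedom (which reduce to the classic large-sample formula
    when ``df_com`` is infinite, the default).
    """
    q = np.asarray(estimates, dtype=float)
    w = np.asarray(variances, dtype=float)
    if q.shape != w.shape:
        raise ValueError("estimates and variances must have the same length")
    m = len(q)
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 imputations")
    qbar = float(q.mean())
    W = float(w.mean())
    B = float(q.var(ddof=1))
    T = W + (1 + 1 / m) * B
    if B == 0:
        df = math.inf
    else:
        lam = (1 + 1 / m) * B / T
        df_classic = (m - 1) / lam**2
        if math.isinf(df_com):
            df = df_classic
        else:
            df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
            df = 1.0 / (1.0 / df_classic + 1.0 / df_obs)
    tq = stats.t.ppf(1 - alpha / 2, df) if math.isfinite(df) else stats.norm.ppf(1 - alpha / 2)
    half = tq * math.sqrt(T)
    return PooledEstimate(
        estimate=qbar, within_var=W, between_var=B, total_var=T, m=m, df=df,
        or_=math.exp(qbar), ci=(math.exp(qbar - half), math.exp(qbar + half)),
    )


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IccEstimate:
    icc: float
    ci: Optional[tuple]
    sigma_cluster: float


def estimate_icc(
    df: pd.DataFrame, outcome: str = "y", cluster: str = "cluster_id", ci: bool = False
) -> IccEstimate:
    """Latent-scale ICC from a random-intercept logistic fit.

    ICC = sigma_c^2 / (sigma_c^2 + pi^2/3).  With ``ci`` the cluster
    standard deviation's profile-likelihood interval is transformed to the
    ICC scale.
    """
    if df[cluster].nunique() < 2:
        raise ValueError("at least two clusters are required to estimate an ICC")
    fits = fit_glmm_logit(df, [], [cluster], outcome=outcome, ci="profile" if ci else "none")
    vc = fits[fits["kind"] == "vc"].iloc[0]
    sd = float(vc["estimate"])

    def to_icc(s):
        return s**2 / (s**2 + math.pi**2 / 3)

    interval = None
    if ci and not pd.isna(vc["lo"]):
        interval = (to_icc(float(vc["lo"])), to_icc(float(vc["hi"])))
    return IccEstimate(icc=to_icc(sd), ci=interval, sigma_cluster=sd)


# ---------------------------------------------------------------------------
# MI-based analysis of the composite outcome
# ---------------------------------------------------------------------------


def analyze_binary_mi(
    df: pd.DataFrame,
    outcome: str,
    m: int,
    rng: np.random.Generator,
    impute_cols: Sequence[str],
    fixed: Sequence[str] = ("arm",),
    groups: Sequence[str] = ("cluster_id",),
    composite_from: Optional[Sequence[str]] = None,
    n_cycles: int = 5,
    alpha: float = 0.05,
) -> dict:
    """Impute, fit per imputation (one batched GLMM call), pool, and compare
    with the complete-case fit.

    ``impute_cols`` are the variables entering the chained equations
    (constituent outcomes and any auxiliaries).  When ``composite_from`` is
    given, the outcome is recomputed in each completed dataset as "any
    constituent occurred".  Returns pooled and complete-case estimates plus
    Little's MCAR diagnostic on the imputed variables.
    """
    little = little_mcar_test(df[list(impute_cols)])
    completed = mice_impute(df[list(impute_cols)], m, rng, n_cycles=n_cycles)
    stacked = []
    for i, comp in enumerate(completed):
        full = df.copy()
        full[list(impute_cols)] = comp
        if composite_from:
            full[outcome] = (full[list(composite_from)].max(axis=1) > 0).astype(int)
        full[".imp"] = i
        stacked.append(full)
    big = pd.concat(stacked, ignore_index=True)
    fits = fit_glmm_logit(big, list(fixed), list(groups), outcome=outcome, rep_col=".imp")
    ests, ses = [], []
    for _, grp in fits.groupby("rep"):
        coefs = grp[(grp["kind"] == "coef") & (grp["term"] == fixed[0])]
        if not coefs.empty:
            ests.append(float(coefs["estimate"].iloc[0]))
            ses.append(float(coefs["se"].iloc[0]))
    pooled = rubin_pool(ests, [s**2 for s in ses], alpha=alpha)

    cc = df.dropna(subset=[c for c in impute_cols]).copy()
    cc_fit = None
    if composite_from:
        cc[outcome] = (cc[list(composite_from)].max(axis=1) > 0).astype(int)
    if cc[fixed[0]].nunique() > 1 and len(cc) > 0:
        spec_fixed = list(fixed)
        f = fit_glmm_logit(cc, spec_fixed, list(groups), outcome=outcome)
        row = _arm_row(f, fixed[0])
        z = stats.norm.ppf(1 - alpha / 2)
        est, se = float(row["estimate"]), float(row["se"])
        cc_fit = OrEstimate(
            est, se, math.exp(est), (math.exp(est - z * se), math.exp(est + z * se)), n=len(cc)
        )
    return {"pooled": pooled, "complete_case": cc_fit, "little": little, "m": len(ests)}


# ---------------------------------------------------------------------------
# Independent cross-check: Gauss-Hermite quadrature random-intercept logit
# ---------------------------------------------------------------------------


def fit_logit_random_intercept_gh(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, n_nodes: int = 25
) -> dict:
    """ML fit of a single-random-intercept logistic model by adaptive-free
    Gauss-Hermite quadrature.

    Small-data numerical oracle used to validate the external GLMM backend;
    returns betas, their SEs (inverse observed information) and the
    random-intercept standard deviation.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, _ = pd.factorize(groups)
    order = np.argsort(codes, kind="stable")
    y, X, codes = y[order], X[order], codes[order]
    starts = np.r_[0, 1 + np.where(np.diff(codes) != 0)[0], len(codes)]
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    logw = np.log(weights / math.sqrt(math.pi))

    def negll(theta):
        beta, logsig = theta[:-1], theta[-1]
        sig = math.exp(logsig)
        eta0 = X @ beta
        # obs x node log-likelihood contributions
        eta = eta0[:, None] + math.sqrt(2) * sig * nodes[None, :]
        ll_obs = y[:, None] * eta - np.logaddexp(0, eta)
        per_group = np.add.reduceat(ll_obs, starts[:-1], axis=0)
        return -float(special.logsumexp(per_group + logw[None, :], axis=1).sum())

    k = X.shape[1]
    res = optimize.minimize(negll, np.zeros(k + 1), method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 500})
    from statsmodels.tools.numdiff import approx_hess1

    H = approx_hess1(res.x, negll)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return {
        "beta": res.x[:-1],
        "se": se[:-1],
        "sigma": math.exp(res.x[-1]),
        "converged": bool(res.success),
        "loglik": -res.fun,
    }
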