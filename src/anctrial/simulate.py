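"""Synthetic pregnancy-cohort generator with known ground truth.

Emulates the data-generating setting of a two-arm cluster-randomised trial
of antenatal clinical decision support: stratified clinic clusters with
gamma-distributed sizes (mean 44 pregnancies over the recruitment period,
coefficient of variation 0.85), five-visit guideline schedules with
heterogeneous attendance (calibrated so roughly 9% of women complete the
full schedule and about 43% of visit opportunities are attended),
physiological measurement distributions tuned so condition prevalences are
of the order seen in routine antenatal care, an intervention effect that
acts only on documentation/management propensities (never on underlying
physiology), and configurable outcome missingness (MCAR, covariate-dependent
MAR, or MNAR).

Every latent parameter (true arm effect, true ICC, true propensities) is
recorded in the ground-truth record so each downstream stage can be tested
for recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special

from .core_types import (
    AntenatalContact,
    ClinicCluster,
    DeliveryOutcome,
    Pregnancy,
    episodes_to_frames,
    clusters_to_frame,
)
from .randomize import AllocationPlan, constrained_randomize
from .schedule import DEFAULT_WINDOWS


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


@dataclass
class SimConfig:
    """Generator configuration; defaults are the trial's design conditions
    where stated, and declared calibration conventions elsewhere."""

    n_clusters: int = 120
    strata_weights: dict = field(
        default_factory=lambda: {"gov_a": 0.25, "gov_b": 0.25, "gov_c": 0.20, "gov_d": 0.17, "gov_e": 0.13}
    )
    cluster_size_mean: float = 44.0
    cluster_size_cv: float = 0.85
    months_recruiting: float = 8.0
    lab_prob: float = 0.5
    ultrasound_prob: float = 0.66

    # Intervention effect: log-odds shift applied to every documentation and
    # management propensity in the intervention arm (and nowhere else).
    arm_effect_logor: float = math.log(1.9)

    # Clustering: latent-scale ICC of process outcomes -> clinic random
    # intercept SD; plus a pregnancy-level intercept for within-woman
    # correlation across contacts.
    icc_process: float = 0.04
    sigma_pregnancy: float = 0.6

    # Control-arm documentation propensities per condition.
    doc_screen: dict = field(
        default_factory=lambda: {
            "anaemia": 0.32, "hypertension": 0.95, "diabetes": 0.40,
            "growth": 0.80, "malpresentation": 0.78,
        }
    )
    doc_manage: dict = field(
        default_factory=lambda: {
            "anaemia": 0.13, "hypertension": 0.20, "diabetes": 0.40,
            "growth": 0.24, "malpresentation": 0.75,
        }
    )
    late_manage_prob: float = 0.3  # managed, but outside the guideline deadline

    # Attendance: per-woman visit-attendance propensity ~ Beta(mean, conc).
    # The concentration is calibrated so that, jointly with early-booking and
    # risk-referral rates, roughly 9% of women complete the full five-visit
    # schedule while ~43% of visit opportunities are attended.
    attendance_mean: float = 0.43
    attendance_concentration: float = 1.65

    booking_ga_median: float = 9.5
    booking_ga_log_sd: float = 0.45
    risk_referred_rate: float = 0.15
    chronic_htn_rate: float = 0.01
    primiparous_rate: float = 0.21
    age_over40_rate: float = 0.012

    # Measurement distributions (units per the data model).
    hb_mean: float = 11.9
    hb_sd: float = 1.0
    sbp_mean: float = 110.0
    sbp_sd: float = 13.0
    dbp_mean: float = 70.0
    dbp_sd: float = 9.0
    bp_corr: float = 0.6
    rbs_mean: float = 95.0
    rbs_sd: float = 20.0
    sfh_sd: float = 1.2
    noncephalic_late_rate: float = 0.045
    noncephalic_persist: float = 0.7

    # Delivery outcomes.
    ga_delivery_mean: float = 39.0
    ga_delivery_sd: float = 1.6
    bw_mean_at39: float = 2850.0
    bw_sd: float = 330.0
    bw_slope_per_week: float = 80.0
    stillbirth_rate: float = 0.0065
    adm_hb_mean: float = 12.1
    adm_hb_sd: float = 0.95
    adm_sbp_mean: float = 118.0
    adm_sbp_sd: float = 16.0
    adm_dbp_mean: float = 76.0
    adm_dbp_sd: float = 10.0

    # Missingness of delivery data (field-level rates + whole-record rate).
    # Admission blood pressure is documented (or not) as a pair, and field
    # missingness is correlated within a woman (record quality), which keeps
    # the composite-outcome missing fraction near the sum's lower envelope.
    missing_record_rate: float = 0.034
    missing_delivery: dict = field(
        default_factory=lambda: {
            "ga_at_delivery": 0.072, "birthweight": 0.098, "admission_hb": 0.244,
            "admission_bp": 0.33, "presentation_at_delivery": 0.03, "stillbirth": 0.0,
        }
    )
    missing_correlation: float = 0.7
    missing_mechanism: str = "mcar"  # mcar | mar_covariate | mnar_outcome

    # Randomisation settings used when the generator allocates arms itself.
    n_candidates: int = 10_000
    keep_best: int = 1_000

    def sigma_cluster(self) -> float:
        return math.sqrt(self.icc_process / (1 - self.icc_process) * math.pi**2 / 3)


def validate_config(cfg: SimConfig) -> None:
    """Raise ValueError naming the offending field for an invalid config."""
    probs = {
        "attendance_mean": cfg.attendance_mean,
        "risk_referred_rate": cfg.risk_referred_rate,
        "chronic_htn_rate": cfg.chronic_htn_rate,
        "lab_prob": cfg.lab_prob,
        "ultrasound_prob": cfg.ultrasound_prob,
        "stillbirth_rate": cfg.stillbirth_rate,
        "missing_record_rate": cfg.missing_record_rate,
        "late_manage_prob": cfg.late_manage_prob,
        "primiparous_rate": cfg.primiparous_rate,
        "age_over40_rate": cfg.age_over40_rate,
    }
    for cond, p in cfg.doc_screen.items():
        probs[f"doc_screen.{cond}"] = p
    for cond, p in cfg.doc_manage.items():
        probs[f"doc_manage.{cond}"] = p
    for f, p in cfg.missing_delivery.items():
        probs[f"missing_delivery.{f}"] = p
    for name, p in probs.items():
        if not (0 <= p <= 1):
            raise ValueError(f"{name}={p} outside [0, 1]")
    if not (0 < cfg.attendance_mean < 1):
        raise ValueError("attendance_mean must lie strictly in (0, 1)")
    if cfg.cluster_size_cv < 0:
        raise ValueError(f"cluster_size_cv={cfg.cluster_size_cv} negative")
    if not (0 <= cfg.icc_process < 1):
        raise ValueError(f"icc_process={cfg.icc_process} outside [0, 1)")
    if cfg.n_clusters < 4:
        raise ValueError(f"n_clusters={cfg.n_clusters} too small for a two-arm design")
    if abs(sum(cfg.strata_weights.values()) - 1.0) > 1e-6:
        raise ValueError("strata_weights must sum to 1")
    if cfg.missing_mechanism not in ("mcar", "mar_covariate", "mnar_outcome"):
        raise ValueError(f"missing_mechanism={cfg.missing_mechanism!r} unknown")


@dataclass
class SimResult:
    clusters: list
    pregnancies: list
    allocation: AllocationPlan
    ground_truth: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"clusters": clusters_to_frame(self.clusters), **episodes_to_frames(self.pregnancies)}


def _make_clusters(cfg: SimConfig, rng: np.random.Generator) -> list[ClinicCluster]:
    names = list(cfg.strata_weights)
    weights = np.array([cfg.strata_weights[s] for s in names])
    counts = np.floor(weights * cfg.n_clusters).astype(int)
    while counts.sum() < cfg.n_clusters:
        counts[int(np.argmax(weights * cfg.n_clusters - counts))] += 1
    shape = 1.0 / cfg.cluster_size_cv**2 if cfg.cluster_size_cv > 0 else None
    clusters = []
    i = 0
    for stratum, k in zip(names, counts):
        for _ in range(k):
            if shape is None:
                size = cfg.cluster_size_mean
            else:
                size = rng.gamma(shape, cfg.cluster_size_mean / shape)
            size = max(1, int(round(size)))
            clusters.append(
                ClinicCluster(
                    cluster_id=f"c{i:03d}",
                    stratum=stratum,
                    annual_enrolments=round(size * 12.0 / cfg.months_recruiting),
                    lab_available=bool(rng.random() < cfg.lab_prob),
                    ultrasound_available=bool(rng.random() < cfg.ultrasound_prob),
                    prop_over40=round(float(np.clip(rng.normal(cfg.age_over40_rate, 0.008), 0, 1)), 4),
                    prop_primiparous=round(float(np.clip(rng.normal(cfg.primiparous_rate, 0.05), 0, 1)), 4),
                    n_clinics=int(rng.integers(1, 4)),
                )
            )
            i += 1
    return clusters


_CONDS = ("anaemia", "hypertension", "diabetes", "growth", "malpresentation")


def _simulate_pregnancy(
    cfg: SimConfig,
    rng: np.random.Generator,
    pid: str,
    cluster: ClinicCluster,
    cluster_effects: np.ndarray,
    base_date: date,
) -> Pregnancy:
    arm_shift = cfg.arm_effect_logor if cluster.arm == "intervention" else 0.0
    preg_effects = rng.normal(0, cfg.sigma_pregnancy, len(_CONDS))
    q = rng.beta(
        cfg.attendance_mean * cfg.attendance_concentration,
        (1 - cfg.attendance_mean) * cfg.attendance_concentration,
    )
    booking_ga = int(np.clip(rng.lognormal(math.log(cfg.booking_ga_median), cfg.booking_ga_log_sd), 4, 42))
    anchor = base_date + timedelta(days=int(rng.integers(0, int(30.4 * cfg.months_recruiting))))
    risk_referred = rng.random() < cfg.risk_referred_rate
    chronic = rng.random() < cfg.chronic_htn_rate
    primi = rng.random() < cfg.primiparous_rate
    age = float(np.clip(rng.normal(26, 5.5), 16, 48))

    # attended gestational ages: booking, then each later scheduled window w.p. q
    gas = [booking_ga]
    if not risk_referred:
        for w in DEFAULT_WINDOWS:
            if w.ga_high <= booking_ga or w.contains(booking_ga):
                continue
            if rng.random() < q:
                lo = max(w.ga_low, booking_ga + 1)
                gas.append(int(rng.integers(lo, w.ga_high)))
    gas = sorted(set(gas))

    noncephalic_late = rng.random() < cfg.noncephalic_late_rate

    def documented(kind: int, base_p: float) -> bool:
        eta = _logit(base_p) + arm_shift + cluster_effects[kind] + preg_effects[kind]
        return rng.random() < special.expit(eta)

    contacts: list[AntenatalContact] = []
    referred = False
    for ga in gas:
        if referred:
            break
        cdate = anchor + timedelta(days=int(ga * 7 + rng.integers(0, 7)))
        c = AntenatalContact(date=cdate, ga_weeks=ga)

        # anaemia screening + management
        if documented(0, cfg.doc_screen["anaemia"]):
            c.hb = round(float(rng.normal(cfg.hb_mean, cfg.hb_sd)), 1)
            if c.hb < 7.0:
                if documented(0, cfg.doc_manage["anaemia"]):
                    c.referral = "hospital"
            elif c.hb < 11.0:
                if documented(0, cfg.doc_manage["anaemia"]):
                    c.repeat_hb_date = cdate + timedelta(days=int(rng.integers(7, 29)))
                elif rng.random() < cfg.late_manage_prob:
                    c.repeat_hb_date = cdate + timedelta(days=int(rng.integers(29, 60)))

        # blood pressure
        if documented(1, cfg.doc_screen["hypertension"]):
            z1, z2 = rng.normal(size=2)
            c.sbp = round(float(cfg.sbp_mean + cfg.sbp_sd * z1), 0)
            c.dbp = round(
                float(cfg.dbp_mean + cfg.dbp_sd * (cfg.bp_corr * z1 + math.sqrt(1 - cfg.bp_corr**2) * z2)), 0
            )
            severe = c.sbp >= 160 or c.dbp >= 110
            moderate = c.sbp >= 150 or c.dbp >= 100
            mild = c.sbp >= 140 or c.dbp >= 90
            if chronic or severe or moderate:
                if documented(1, cfg.doc_manage["hypertension"]):
                    c.referral = "high_risk_clinic" if c.referral == "none" else c.referral
            elif mild:
                if documented(1, cfg.doc_manage["hypertension"]):
                    c.repeat_bp_date = cdate + timedelta(days=int(rng.integers(1, 5)))
                elif rng.random() < cfg.late_manage_prob:
                    c.repeat_bp_date = cdate + timedelta(days=int(rng.integers(5, 15)))

        # glucose: blood test where a laboratory exists, urine dip otherwise
        if documented(2, cfg.doc_screen["diabetes"]):
            if cluster.lab_available or ga >= 23:
                c.rbs = round(float(rng.normal(cfg.rbs_mean, cfg.rbs_sd)), 0)
                if c.rbs >= 140 and documented(2, cfg.doc_manage["diabetes"]):
                    c.referral = "high_risk_clinic" if c.referral == "none" else c.referral
            else:
                c.urine_sugar = "positive" if rng.random() < 0.01 else "negative"

        # fundal growth (measurable from mid-pregnancy)
        if ga >= 20 and documented(3, cfg.doc_screen["growth"]):
            c.sfh = round(float(ga + rng.normal(0, cfg.sfh_sd)), 1)
            if abs(c.sfh - ga) > 2:
                if documented(3, cfg.doc_manage["growth"]):
                    if rng.random() < 0.5:
                        c.followup_us_date = cdate + timedelta(days=int(rng.integers(1, 8)))
                    else:
                        c.referral = "high_risk_clinic" if c.referral == "none" else c.referral

        # presentation (late pregnancy)
        if ga >= 30 and documented(4, cfg.doc_screen["malpresentation"]):
            c.presentation = "non_cephalic" if noncephalic_late and ga >= 34 else "cephalic"
            if c.presentation == "non_cephalic" and documented(4, cfg.doc_manage["malpresentation"]):
                c.referral = "hospital"

        if risk_referred and not contacts:
            c.referral = "high_risk_clinic"
        if c.referral != "none":
            referred = True
        contacts.append(c)

    # Delivery (physiology independent of arm by construction).
    ga_del = int(np.clip(round(rng.normal(cfg.ga_delivery_mean, cfg.ga_delivery_sd)), 28, 43))
    bw = float(max(500, rng.normal(cfg.bw_mean_at39 + cfg.bw_slope_per_week * (ga_del - 39), cfg.bw_sd)))
    z1, z2 = rng.normal(size=2)
    delivery = DeliveryOutcome(
        ga_at_delivery=ga_del,
        birthweight=round(bw, 0),
        admission_hb=round(float(rng.normal(cfg.adm_hb_mean, cfg.adm_hb_sd)), 1),
        admission_sbp=round(float(cfg.adm_sbp_mean + cfg.adm_sbp_sd * z1), 0),
        admission_dbp=round(
            float(cfg.adm_dbp_mean + cfg.adm_dbp_sd * (cfg.bp_corr * z1 + math.sqrt(1 - cfg.bp_corr**2) * z2)), 0
        ),
        presentation_at_delivery=(
            "non_cephalic"
            if (noncephalic_late and rng.random() < cfg.noncephalic_persist) or rng.random() < 0.005
            else "cephalic"
        ),
        stillbirth=bool(rng.random() < cfg.stillbirth_rate),
    )

    return Pregnancy(
        pregnancy_id=pid,
        cluster_id=cluster.cluster_id,
        anchor_date=anchor,
        booking_ga=booking_ga,
        maternal_age=round(age, 1),
        parity=0 if primi else int(rng.integers(1, 7)),
        risk_referred=risk_referred,
        chronic_htn=chronic,
        covariates={"attendance_propensity": round(float(q), 3)},
        contacts=contacts,
        delivery=delivery,
    )


def simulate_trial(
    cfg: SimConfig,
    seed: int,
    allocation: Optional[AllocationPlan] = None,
    base_date: date = date(2017, 1, 15),
) -> SimResult:
    """Generate a full four-table synthetic trial with ground truth.

    Clusters are created, allocated 1:1 by the covariate-constrained
    randomiser (unless an allocation is supplied), and populated with
    pregnancies whose documentation propensities carry the arm effect, the
    clinic random effects and the pregnancy random effects on the logit
    scale.  Identical config + seed give an identical dataset.
    """
    validate_config(cfg)
    rng = np.random.default_rng(seed)
    clusters = _make_clusters(cfg, rng)
    if allocation is None:
        allocation = constrained_randomize(
            clusters, seed=int(rng.integers(2**31)), n_candidates=cfg.n_candidates,
            keep_best=min(cfg.keep_best, cfg.n_candidates),
        )
    else:
        for c in clusters:
            c.arm = allocation.assignment[c.cluster_id]

    sig_c = cfg.sigma_cluster()
    pregnancies = []
    for cluster in clusters:
        n_preg = max(1, int(round(cluster.annual_enrolments * cfg.months_recruiting / 12.0)))
        cluster_effects = rng.normal(0, sig_c, len(_CONDS))
        for k in range(n_preg):
            pid = f"{cluster.cluster_id}_p{k:04d}"
            pregnancies.append(
                _simulate_pregnancy(cfg, rng, pid, cluster, cluster_effects, base_date)
            )

    _apply_delivery_missingness(cfg, rng, pregnancies)

    truth = {
        "seed": seed,
        "arm_effect_logor": cfg.arm_effect_logor,
        "arm_effect_or": math.exp(cfg.arm_effect_logor),
        "icc_process": cfg.icc_process,
        "sigma_cluster": sig_c,
        "sigma_pregnancy": cfg.sigma_pregnancy,
        "doc_screen": dict(cfg.doc_screen),
        "doc_manage": dict(cfg.doc_manage),
        "attendance_mean": cfg.attendance_mean,
        "n_pregnancies": len(pregnancies),
        "allocation": dict(allocation.assignment),
        "missing_mechanism": cfg.missing_mechanism,
    }
    return SimResult(clusters, pregnancies, allocation, truth)


#: Pseudo-fields in the missingness config that blank several record fields.
_FIELD_GROUPS = {"admission_bp": ("admission_sbp", "admission_dbp")}


def _shadow_value(v) -> float:
    """Numeric stand-in for MNAR thresholds (categoricals contribute 0)."""
    if isinstance(v, bool):
        return float(v)
    if isinstance(v, (int, float)):
        return float(v)
    return 0.0


def _apply_delivery_missingness(cfg, rng, pregnancies) -> None:
    for p in pregnancies:
        if rng.random() < cfg.missing_record_rate:
            p.delivery = None
    alive = [p for p in pregnancies if p.delivery is not None]
    if not alive or not cfg.missing_delivery:
        return
    keys = list(cfg.missing_delivery)
    shadow = pd.DataFrame(
        {
            k: [_shadow_value(getattr(p.delivery, _FIELD_GROUPS.get(k, (k,))[0])) for p in alive]
            for k in keys
        }
    )
    parity = pd.Series([float(p.parity or 0) for p in alive])
    masked = inject_missingness(
        shadow, cfg.missing_mechanism, cfg.missing_delivery, rng,
        covariate=parity, correlation=cfg.missing_correlation,
    )
    for k in keys:
        nulls = masked[k].isna().to_numpy()
        for col in _FIELD_GROUPS.get(k, (k,)):
            for p, is_null in zip(alive, nulls):
                if is_null:
                    setattr(p.delivery, col, None)


def inject_missingness(
    df: pd.DataFrame,
    mechanism: str,
    rates: dict,
    rng: np.random.Generator,
    covariate: Optional[pd.Series] = None,
    slope: float = 1.5,
    correlation: float = 0.0,
) -> pd.DataFrame:
    """Blank fields of a delivery table at the configured rates.

    ``mcar`` masks uniformly at random; ``mar_covariate`` makes missingness
    a logistic function of the supplied covariate; ``mnar_outcome`` makes it
    a logistic function of the (standardised) value being blanked.  In the
    latter two the intercept is solved so the marginal missing fraction
    matches the requested rate.  ``correlation`` induces a Gaussian-copula
    dependence of missingness across fields within a row (record quality)
    while leaving each field's marginal rate unchanged.
    """
    out = df.copy()
    n = len(out)
    if n == 0:
        return out
    if not (0 <= correlation < 1):
        raise ValueError("correlation must lie in [0, 1)")
    row_latent = rng.normal(size=n)

    def uniforms() -> np.ndarray:
        if correlation == 0:
            return rng.random(n)
        e = rng.normal(size=n)
        from scipy.stats import norm

        return norm.cdf(correlation * row_latent + math.sqrt(1 - correlation**2) * e)

    for col, rate in rates.items():
        if not (0 <= rate <= 1):
            raise ValueError(f"rate for {col!r} outside [0, 1]")
        if col not in out.columns or rate == 0:
            continue
        if mechanism == "mcar":
            mask = uniforms() < rate
        elif mechanism in ("mar_covariate", "mnar_outcome"):
            if mechanism == "mar_covariate":
                if covariate is None:
                    raise ValueError("mar_covariate needs a covariate series")
                z = covariate.to_numpy(dtype=float)
            else:
                z = out[col].to_numpy(dtype=float)
            if np.all(np.isnan(z)):
                z = np.zeros(n)
            else:
                mu, sd = np.nanmean(z), np.nanstd(z)
                z = np.where(np.isnan(z), 0.0, (z - mu) / (sd if sd > 0 else 1.0))

            def mean_p(a):
                return special.expit(a + slope * z).mean() - rate

            a = optimize.brentq(mean_p, -30, 30)
            mask = uniforms() < special.expit(a + slope * z)
        else:
            raise ValueError(f"unknown missingness mechanism {mechanism!r}")
        out.loc[mask, col] = np.nan
    return out
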