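"""Trial outcome adjudication.

Process (guideline-adherence) outcomes are scored per eligible antenatal
contact: success means the screening was documented AND the finding was
either normal or correctly managed within the guideline deadline.  Lack of
documentation is scored as non-performance, so process outcomes are never
missing.

The health outcome at delivery is a composite of five constituents, each
{occurred, absent, missing}: moderate/severe anaemia at admission (Hb < 10
g/dL); severe hypertension at admission (SBP >= 160 or DBP >= 110 mm Hg);
term large-for-gestational-age baby (birthweight >= 3258 g, the 90th
percentile at 37 weeks); term small-for-gestational-age baby (<= 2394 g, the
10th percentile) undetected antenatally; and malpresentation at delivery
(non-cephalic at or after 36 weeks) undetected antenatally.  The composite
occurred if at least one constituent occurred, is absent if all five are
absent, and is missing otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import cdss, schedule as _sched
from .core_types import AntenatalContact, Pregnancy

#: Default composite-outcome thresholds ("term" = >= 37 completed weeks; the
#: LGA/SGA birthweight cutoffs are the printed 37-week percentile values,
#: applied to all term births unless a per-GA percentile table is supplied).
COMPOSITE_DEFAULTS = {
    "anaemia_hb_below": 10.0,
    "severe_htn_sbp": 160.0,
    "severe_htn_dbp": 110.0,
    "term_ga": 37,
    "lga_cutoff": 3258.0,
    "sga_cutoff": 2394.0,
    "malpresentation_ga": 36,
    "malpresentation_detect_ga": 34,  # start of the 36-week visit window
    "stillbirth_ga": 28,
}

CONSTITUENTS = ("anaemia", "severe_htn", "lga", "sga_undetected", "malpresentation_undetected")


@dataclass(frozen=True)
class ContactAdjudication:
    """Adjudication of one eligible contact for one condition."""

    pregnancy_id: str
    contact_index: int
    ga_weeks: Optional[int]
    condition: str
    screened: bool
    finding: Optional[str]
    managed_correctly: Optional[bool]  # None = not applicable (normal finding)
    success: bool


_NORMAL = {"none", "negative", "normal", "cephalic"}


def _managed_correctly(
    p: Pregnancy, contact: AntenatalContact, condition: str, finding: str,
    accept_monitoring: bool = False,
) -> bool:
    """Guideline-deadline check for the management of a detected condition.

    ``accept_monitoring`` widens hypertension management (moderate/severe/
    chronic) to also accept a documented repeat BP measurement, reflecting
    in-clinic monitoring; the default requires a referral.
    """
    referred_any = contact.referral in ("high_risk_clinic", "hospital")
    referred_hosp = contact.referral == "hospital"
    if condition == "anaemia":
        if finding == "severe":
            return referred_hosp
        ok = (
            contact.repeat_hb_date is not None
            and contact.date < contact.repeat_hb_date <= contact.date + timedelta(days=28)
        )
        return ok
    if condition == "hypertension":
        if finding == "mild_gest":
            return (
                contact.repeat_bp_date is not None
                and contact.date < contact.repeat_bp_date <= contact.date + timedelta(days=4)
            )
        ok = referred_any
        if accept_monitoring:
            ok = ok or contact.repeat_bp_date is not None
        return ok
    if condition == "diabetes":
        return referred_any
    if condition == "growth":
        us_ok = (
            contact.followup_us_date is not None
            and contact.date < contact.followup_us_date <= contact.date + timedelta(days=7)
        )
        return us_ok or referred_any
    if condition == "malpresentation":
        return referred_hosp
    raise ValueError(f"unknown condition {condition!r}")


def adjudicate_process(
    p: Pregnancy,
    condition: str,
    windows=_sched.DEFAULT_WINDOWS,
    thresholds: dict = cdss.DEFAULT_THRESHOLDS,
    accept_monitoring: bool = False,
) -> list[ContactAdjudication]:
    """Score every eligible contact of a pregnancy for one condition."""
    index_of = {id(c): i for i, c in enumerate(p.contacts)}
    out = []
    for c in _sched.eligible_contacts(p, condition, windows):
        screened = cdss.screened_for(c, condition, thresholds)
        finding = cdss.classify(c, condition, p, thresholds) if screened else None
        if not screened:
            managed: Optional[bool] = None
            success = False
        elif finding in _NORMAL:
            managed = None
            success = True
        else:
            managed = _managed_correctly(p, c, condition, finding, accept_monitoring)
            success = managed
        out.append(
            ContactAdjudication(
                p.pregnancy_id, index_of[id(c)], c.ga_weeks, condition, screened, finding, managed, success
            )
        )
    return out


def adjudicate_all_processes(
    pregnancies: Sequence[Pregnancy], conditions=_sched.CONDITIONS, **kw
) -> pd.DataFrame:
    """One row per eligible contact per condition, over a cohort."""
    rows = []
    for p in pregnancies:
        for cond in conditions:
            rows.extend(vars(a) for a in adjudicate_process(p, cond, **kw))
    cols = list(ContactAdjudication.__dataclass_fields__)
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Composite health outcome at delivery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompositeOutcome:
    pregnancy_id: str
    constituents: dict  # name -> {"occurred", "absent", "missing"}
    composite: str


def combine_constituents(states: Mapping[str, str] | Sequence[str]) -> str:
    """Definitional truth table: occurred if any occurred; absent if all absent;
    missing otherwise."""
    values = list(states.values()) if isinstance(states, Mapping) else list(states)
    for v in values:
        if v not in ("occurred", "absent", "missing"):
            raise ValueError(f"unknown constituent state {v!r}")
    if any(v == "occurred" for v in values):
        return "occurred"
    if all(v == "absent" for v in values):
        return "absent"
    return "missing"


def growth_detected_antenatally(p: Pregnancy, thresholds=cdss.DEFAULT_THRESHOLDS) -> bool:
    """Any abnormal foetal-growth finding at any routine contact."""
    for c in _sched.routine_contacts(p):
        if c.ga_weeks is None:
            continue
        if cdss.classify_growth(c.sfh, c.ga_weeks, c.ultrasound_growth, thresholds) == "abnormal":
            return True
    return False


def malpresentation_detected_antenatally(p: Pregnancy, params=COMPOSITE_DEFAULTS) -> bool:
    """Non-cephalic finding documented at a late (36-week window) contact."""
    for c in _sched.routine_contacts(p):
        if c.ga_weeks is None or c.ga_weeks < params["malpresentation_detect_ga"]:
            continue
        if c.presentation == "non_cephalic":
            return True
    return False


def adjudicate_composite(p: Pregnancy, params: dict = COMPOSITE_DEFAULTS) -> CompositeOutcome:
    """Constituent flags from the delivery record, then the composite.

    A missing delivery field makes its constituent missing; a pregnancy with
    no delivery record has a missing composite.  "Undetected" constituents
    additionally require absence of the corresponding antenatal detection.
    """
    d = p.delivery
    states: dict[str, str] = {}
    if d is None:
        states = {k: "missing" for k in CONSTITUENTS}
        return CompositeOutcome(p.pregnancy_id, states, "missing")

    # Moderate or severe anaemia at admission.
    if d.admission_hb is None:
        states["anaemia"] = "missing"
    else:
        states["anaemia"] = "occurred" if d.admission_hb < params["anaemia_hb_below"] else "absent"

    # Severe hypertension at admission: either pressure can establish it.
    sbp, dbp = d.admission_sbp, d.admission_dbp
    if (sbp is not None and sbp >= params["severe_htn_sbp"]) or (
        dbp is not None and dbp >= params["severe_htn_dbp"]
    ):
        states["severe_htn"] = "occurred"
    elif sbp is not None and dbp is not None:
        states["severe_htn"] = "absent"
    else:
        states["severe_htn"] = "missing"

    # Term LGA / undetected term SGA.
    ga, bw = d.ga_at_delivery, d.birthweight
    if ga is not None and ga < params["term_ga"]:
        states["lga"] = "absent"
        states["sga_undetected"] = "absent"
    elif ga is None or bw is None:
        states["lga"] = "missing"
        states["sga_undetected"] = "missing"
    else:
        states["lga"] = "occurred" if bw >= params["lga_cutoff"] else "absent"
        if bw <= params["sga_cutoff"] and not growth_detected_antenatally(p):
            states["sga_undetected"] = "occurred"
        else:
            states["sga_undetected"] = "absent"

    # Undetected malpresentation at delivery (non-cephalic at/after 36 weeks).
    pres = d.presentation_at_delivery
    if ga is not None and ga < params["malpresentation_ga"]:
        states["malpresentation_undetected"] = "absent"
    elif pres is None or ga is None:
        states["malpresentation_undetected"] = "missing"
    elif pres == "non_cephalic" and not malpresentation_detected_antenatally(p, params):
        states["malpresentation_undetected"] = "occurred"
    else:
        states["malpresentation_undetected"] = "absent"

    return CompositeOutcome(p.pregnancy_id, states, combine_constituents(states))


def adjudicate_stillbirth(p: Pregnancy, params: dict = COMPOSITE_DEFAULTS) -> str:
    """Stillbirth = born with no signs of life at or after 28 completed weeks."""
    d = p.delivery
    if d is None or d.stillbirth is None:
        return "missing"
    if not d.stillbirth:
        return "livebirth"
    if d.ga_at_delivery is None:
        return "missing"
    return "stillbirth" if d.ga_at_delivery >= params["stillbirth_ga"] else "livebirth"


def adjudicate_deliveries(
    pregnancies: Sequence[Pregnancy], params: dict = COMPOSITE_DEFAULTS
) -> pd.DataFrame:
    """One row per pregnancy: constituent states, composite, stillbirth."""
    rows = []
    for p in pregnancies:
        comp = adjudicate_composite(p, params)
        rows.append(
            dict(
                pregnancy_id=p.pregnancy_id,
                cluster_id=p.cluster_id,
                **comp.constituents,
                composite=comp.composite,
                stillbirth=adjudicate_stillbirth(p, params),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Arm-level summary table
# ---------------------------------------------------------------------------


def tabulate(
    adjudications: pd.DataFrame, arm_of_cluster: Mapping[str, str],
    pregnancy_cluster: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Condition x arm table of successes / eligible contacts.

    ``adjudications`` is the frame from :func:`adjudicate_all_processes`;
    cluster membership comes either from a ``cluster_id`` column or from the
    ``pregnancy_cluster`` map.
    """
    if adjudications.empty:
        return pd.DataFrame(columns=["condition", "arm", "successes", "eligible", "proportion"])
    df = adjudications.copy()
    if "cluster_id" not in df.columns:
        if pregnancy_cluster is None:
            raise ValueError("need a cluster_id column or a pregnancy->cluster map")
        df["cluster_id"] = df["pregnancy_id"].map(pregnancy_cluster)
    df["arm"] = df["cluster_id"].map(arm_of_cluster)
    g = df.groupby(["condition", "arm"], sort=True)["success"].agg(successes="sum", eligible="count")
    g = g.reset_index()
    g["successes"] = g["successes"].astype(int)
    g["proportion"] = g["successes"] / g["eligible"]
    return g


def format_tabulation(table: pd.DataFrame) -> str:
    lines = [f"{'condition':<18}{'arm':<14}{'n/N':>12}  {'%':>6}"]
    for _, r in table.iterrows():
        lines.append(
            f"{r['condition']:<18}{r['arm']:<14}{int(r['successes'])}/{int(r['eligible']):<6}"
            f"  {100 * r['proportion']:6.1f}"
        )
    return "\n".join(lines)
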