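"""Clinical decision support rules engine.

Classifies each documented measurement against guideline thresholds and emits
prompts with deadlines: screening-due prompts for eligible but unperformed
screenings, and management actions for detected conditions (repeat tests,
ultrasound follow-up, referrals).  The thresholds and the condition-to-action
mapping are data (a declarative table, serialisable to YAML), not code
branches, so the production engine's much larger rule set can be approximated
by extending configuration.

Boundary conventions, chosen for internal consistency with the
delivery-outcome definitions:

* anaemia: severe < 7.0 <= moderate < 10.0 <= mild < 11.0 <= none (g/dL);
* gestational hypertension: mild 140-149 / 90-99, moderate 150-159 /
  100-109, severe >= 160 / >= 110 mm Hg (the severe band closes the printed
  gap at exactly 160/110, matching the at-delivery definition of severe
  hypertension);
* glucose: positive at random blood sugar >= 140 mg/dL; before 24 weeks a
  urine sugar test alone counts as screening, from 24 weeks a blood test is
  required;
* growth: abnormal when |fundal height - GA| discrepancy exceeds 2 (strict)
  or ultrasound suspects a growth abnormality.

Deadlines are calendar days, inclusive of the final day: "within 4 weeks" is
28 days, "within 1 week" 7 days, "within 4 days" 4 days.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Optional, Sequence

import yaml

from .core_types import AntenatalContact, Pregnancy
from . import schedule as _sched

# Management action vocabulary.
ACTIONS = (
    "repeat_hb_4wk",
    "repeat_bp_4d",
    "refer_high_risk_or_hospital",
    "refer_hospital",
    "ultrasound_1wk",
    "screening_due",
)

#: Default thresholds; YAML-overridable alongside the rule table.
DEFAULT_THRESHOLDS = {
    "anaemia": {"severe_below": 7.0, "moderate_below": 10.0, "mild_below": 11.0},
    "hypertension": {
        "mild": {"sbp": 140.0, "dbp": 90.0},
        "moderate": {"sbp": 150.0, "dbp": 100.0},
        "severe": {"sbp": 160.0, "dbp": 110.0},
    },
    "glucose": {"rbs_positive_at": 140.0, "urine_acceptable_below_ga": 24},
    "growth": {"discrepancy": 2.0},
}

#: Declarative management rules: finding class -> action(s) with deadlines.
DEFAULT_RULES = [
    {"id": "anaemia_mild_moderate", "condition": "anaemia", "classes": ["mild", "moderate"],
     "actions": [{"action": "repeat_hb_4wk", "deadline_days": 28}]},
    {"id": "anaemia_severe", "condition": "anaemia", "classes": ["severe"],
     "actions": [{"action": "refer_hospital", "deadline_days": None}]},
    {"id": "htn_mild_gest", "condition": "hypertension", "classes": ["mild_gest"],
     "actions": [{"action": "repeat_bp_4d", "deadline_days": 4}]},
    {"id": "htn_moderate_severe_chronic", "condition": "hypertension",
     "classes": ["moderate_gest", "severe_gest", "chronic"],
     "actions": [{"action": "refer_high_risk_or_hospital", "deadline_days": None}]},
    {"id": "glucose_positive", "condition": "diabetes", "classes": ["positive"],
     "actions": [{"action": "refer_high_risk_or_hospital", "deadline_days": None}]},
    {"id": "growth_abnormal", "condition": "growth", "classes": ["abnormal"],
     "actions": [{"action": "ultrasound_1wk", "deadline_days": 7},
                 {"action": "refer_high_risk_or_hospital", "deadline_days": None}]},
    {"id": "malpresentation", "condition": "malpresentation", "classes": ["non_cephalic"],
     "actions": [{"action": "refer_hospital", "deadline_days": None}]},
]


def load_rule_table(path) -> dict:
    """Load ``{thresholds: ..., rules: ...}`` from YAML, filling defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    table = {"thresholds": copy.deepcopy(DEFAULT_THRESHOLDS), "rules": copy.deepcopy(DEFAULT_RULES)}
    if "thresholds" in raw:
        for k, v in raw["thresholds"].items():
            table["thresholds"][k] = v
    if "rules" in raw:
        table["rules"] = raw["rules"]
    return table


def dump_rule_table(path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"thresholds": DEFAULT_THRESHOLDS, "rules": DEFAULT_RULES}, fh, sort_keys=False)


@dataclass(frozen=True)
class CdssAction:
    """A prompt emitted by the engine for one contact."""

    rule_id: str
    condition: str
    action: str
    due_by: Optional[date]  # contact date + deadline; None for immediate referrals
    triggering_value: Optional[object] = None


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------


def classify_anaemia(hb: float, thresholds: dict = DEFAULT_THRESHOLDS) -> str:
    """Anaemia severity from haemoglobin (g/dL): none / mild / moderate / severe."""
    if hb is None or hb <= 0:
        raise ValueError(f"haemoglobin must be positive, got {hb!r}")
    t = thresholds["anaemia"]
    if hb < t["severe_below"]:
        return "severe"
    if hb < t["moderate_below"]:
        return "moderate"
    if hb < t["mild_below"]:
        return "mild"
    return "none"


def classify_hypertension(
    sbp: float, dbp: float, known_chronic: bool = False, thresholds: dict = DEFAULT_THRESHOLDS
) -> str:
    """Hypertension class from one BP reading (mm Hg).

    A known chronic hypertensive is classified ``chronic`` regardless of the
    reading; otherwise the most severe band triggered by either pressure.
    """
    if sbp is None or dbp is None or sbp <= 0 or dbp <= 0:
        raise ValueError(f"both pressures must be positive, got sbp={sbp!r} dbp={dbp!r}")
    if known_chronic:
        return "chronic"
    t = thresholds["hypertension"]
    if sbp >= t["severe"]["sbp"] or dbp >= t["severe"]["dbp"]:
        return "severe_gest"
    if sbp >= t["moderate"]["sbp"] or dbp >= t["moderate"]["dbp"]:
        return "moderate_gest"
    if sbp >= t["mild"]["sbp"] or dbp >= t["mild"]["dbp"]:
        return "mild_gest"
    return "none"


def classify_glucose(
    rbs: Optional[float],
    urine: Optional[str],
    ga_weeks: int,
    thresholds: dict = DEFAULT_THRESHOLDS,
) -> str:
    """Diabetes screening status: positive / negative / unscreened.

    Positive iff random blood sugar >= the threshold.  Before 24 weeks a
    urine sugar test alone counts as screening; from 24 weeks the guideline
    row requires a blood test, so a urine result alone leaves the contact
    unscreened.
    """
    t = thresholds["glucose"]
    if rbs is not None:
        return "positive" if rbs >= t["rbs_positive_at"] else "negative"
    if urine is not None and ga_weeks < t["urine_acceptable_below_ga"]:
        return "positive" if urine == "positive" else "negative"
    return "unscreened"


def classify_growth(
    sfh: Optional[float],
    ga_weeks: int,
    ultrasound_growth: Optional[str],
    thresholds: dict = DEFAULT_THRESHOLDS,
) -> str:
    """Foetal growth screening: abnormal / normal / unscreened.

    Abnormal when the fundal-height-minus-GA discrepancy is strictly greater
    than +2 or strictly less than -2, or when ultrasound suspects a growth
    abnormality.
    """
    if ga_weeks is None:
        raise ValueError("gestational age required to assess fundal height")
    lim = thresholds["growth"]["discrepancy"]
    abnormal = False
    screened = False
    if sfh is not None:
        screened = True
        d = sfh - ga_weeks
        abnormal = d > lim or d < -lim
    if ultrasound_growth is not None:
        screened = True
        abnormal = abnormal or ultrasound_growth == "abnormal"
    if not screened:
        return "unscreened"
    return "abnormal" if abnormal else "normal"


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------


def screened_for(contact: AntenatalContact, condition: str, thresholds=DEFAULT_THRESHOLDS) -> bool:
    """Whether the condition's screening is documented at this contact."""
    if condition == "anaemia":
        return contact.hb is not None
    if condition == "hypertension":
        return contact.sbp is not None and contact.dbp is not None
    if condition == "diabetes":
        return classify_glucose(contact.rbs, contact.urine_sugar, contact.ga_weeks, thresholds) != "unscreened"
    if condition == "growth":
        return contact.sfh is not None or contact.ultrasound_growth is not None
    if condition == "malpresentation":
        return contact.presentation is not None
    raise ValueError(f"unknown condition {condition!r}")


def classify(contact: AntenatalContact, condition: str, pregnancy: Pregnancy,
             thresholds=DEFAULT_THRESHOLDS) -> Optional[str]:
    """Finding class for a screened condition; None when unscreened."""
    if not screened_for(contact, condition, thresholds):
        return None
    if condition == "anaemia":
        return classify_anaemia(contact.hb, thresholds)
    if condition == "hypertension":
        return classify_hypertension(contact.sbp, contact.dbp, pregnancy.chronic_htn, thresholds)
    if condition == "diabetes":
        return classify_glucose(contact.rbs, contact.urine_sugar, contact.ga_weeks, thresholds)
    if condition == "growth":
        return classify_growth(contact.sfh, contact.ga_weeks, contact.ultrasound_growth, thresholds)
    if condition == "malpresentation":
        return contact.presentation
    raise ValueError(f"unknown condition {condition!r}")


def evaluate_rules(
    contact: AntenatalContact,
    pregnancy: Pregnancy,
    rule_table: Optional[dict] = None,
    windows=_sched.DEFAULT_WINDOWS,
) -> list[CdssAction]:
    """Evaluate the engine for one contact: deterministic and idempotent.

    Emits a ``screening_due`` prompt for each condition eligible at this
    contact whose screening is undocumented, and the management action(s) for
    each detected condition, with ``due_by`` set to the contact date plus the
    action deadline.
    """
    table = rule_table or {"thresholds": DEFAULT_THRESHOLDS, "rules": DEFAULT_RULES}
    thresholds, rules = table["thresholds"], table["rules"]
    actions: list[CdssAction] = []
    for condition in _sched.CONDITIONS:
        eligible = any(c is contact for c in _sched.eligible_contacts(pregnancy, condition, windows))
        if not eligible:
            continue
        if not screened_for(contact, condition, thresholds):
            actions.append(CdssAction(f"{condition}_screening", condition, "screening_due", contact.date))
            continue
        finding = classify(contact, condition, pregnancy, thresholds)
        for rule in rules:
            if rule["condition"] != condition or finding not in rule["classes"]:
                continue
            for act in rule["actions"]:
                due = (
                    contact.date + timedelta(days=act["deadline_days"])
                    if act["deadline_days"] is not None
                    else None
                )
                actions.append(CdssAction(rule["id"], condition, act["action"], due, finding))
    return actions


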