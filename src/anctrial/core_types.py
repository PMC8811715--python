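"""Shared data model for clusters, pregnancies, antenatal contacts and deliveries.

The unit of randomisation is the primary-care clinic cluster; the unit of
observation is a pregnancy episode: a registration, an ordered series of
antenatal contacts, and (usually) a delivery record.  Measurement fields use
``None`` for *undocumented*: absence of documentation is meaningful (it is
scored as non-performance by the process-outcome adjudicator) and is never
conflated with a zero value.

Units are fixed throughout the package: haemoglobin in g/dL, blood pressure
in mm Hg, random blood sugar in mg/dL, birthweight in g, gestational age in
completed weeks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

# Categorical domains (kept as plain strings for painless CSV round-trips).
ARMS = ("control", "intervention", "unassigned")
REFERRALS = ("none", "high_risk_clinic", "hospital")
PRESENTATIONS = ("cephalic", "non_cephalic")
URINE_RESULTS = ("positive", "negative")
US_GROWTH = ("normal", "abnormal")


def ga_completed_weeks(anchor: date, on: date) -> int:
    """Completed gestational weeks at ``on`` for an episode anchored at ``anchor``.

    The anchor is the gestational-age reference date (last menstrual period or
    an ultrasound-derived equivalent); which one is used is an input choice
    recorded on the pregnancy, not something this function decides.
    """
    return (on - anchor).days // 7


@dataclass
class ClinicCluster:
    """A randomisation unit: one clinic, or 2-3 small clinics grouped together.

    Carries the four covariates used to constrain randomisation: annual
    enrolment volume, laboratory availability, proportion of enrolled women
    over 40, and proportion primiparous.
    """

    cluster_id: str
    stratum: str
    annual_enrolments: float
    lab_available: bool
    ultrasound_available: bool
    prop_over40: float
    prop_primiparous: float
    arm: str = "unassigned"
    n_clinics: int = 1


@dataclass
class AntenatalContact:
    """One documented clinic visit during pregnancy.

    ``None`` in any measurement field means the measurement was not
    documented at this contact.  ``repeat_hb_date``, ``repeat_bp_date`` and
    ``followup_us_date`` record follow-up management actions (when
    documented), which the adjudicator checks against guideline deadlines.
    """

    date: date
    ga_weeks: Optional[int] = None
    hb: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    rbs: Optional[float] = None
    urine_sugar: Optional[str] = None
    sfh: Optional[float] = None
    ultrasound_growth: Optional[str] = None
    presentation: Optional[str] = None
    referral: str = "none"
    repeat_hb_date: Optional[date] = None
    repeat_bp_date: Optional[date] = None
    followup_us_date: Optional[date] = None


@dataclass
class DeliveryOutcome:
    """Delivery-admission record; every field is independently missable."""

    ga_at_delivery: Optional[int] = None
    birthweight: Optional[float] = None
    admission_hb: Optional[float] = None
    admission_sbp: Optional[float] = None
    admission_dbp: Optional[float] = None
    presentation_at_delivery: Optional[str] = None
    stillbirth: Optional[bool] = None


@dataclass
class Pregnancy:
    """A pregnancy episode within a cluster."""

    pregnancy_id: str
    cluster_id: str
    anchor_date: date
    anchor_kind: str = "lmp"  # "lmp" or "ultrasound"; configurable input, not inferred
    booking_ga: int = 0
    maternal_age: Optional[float] = None
    parity: Optional[int] = None
    risk_referred: bool = False
    chronic_htn: bool = False
    covariates: dict = field(default_factory=dict)
    contacts: list = field(default_factory=list)
    delivery: Optional[DeliveryOutcome] = None


# ---------------------------------------------------------------------------
# Validation (report-only; never raises, never mutates)
# ---------------------------------------------------------------------------

_POSITIVE_FIELDS = ("hb", "sbp", "dbp", "rbs", "sfh")


def validate_cluster(c: ClinicCluster) -> list[str]:
    issues = []
    for name in ("prop_over40", "prop_primiparous"):
        v = getattr(c, name)
        if not (0.0 <= v <= 1.0):
            issues.append(f"{c.cluster_id}: {name}={v} outside [0, 1]")
    if c.annual_enrolments < 0:
        issues.append(f"{c.cluster_id}: annual_enrolments={c.annual_enrolments} negative")
    if not (1 <= c.n_clinics <= 3):
        issues.append(f"{c.cluster_id}: n_clinics={c.n_clinics} outside 1-3")
    if c.arm not in ARMS:
        issues.append(f"{c.cluster_id}: unknown arm {c.arm!r}")
    return issues


def validate_pregnancy(p: Pregnancy) -> list[str]:
    """Return a list of invariant violations (empty when well-formed).

    Validation is total: any structurally constructed record yields a
    report, never an exception.
    """
    issues: list[str] = []
    if not (0 <= p.booking_ga < 45):
        issues.append(f"booking_ga={p.booking_ga} outside [0, 45)")
    dates = [c.date for c in p.contacts]
    if any(b < a for a, b in zip(dates, dates[1:])):
        issues.append("contacts not ordered by date")
    for i, c in enumerate(p.contacts):
        for name in _POSITIVE_FIELDS:
            v = getattr(c, name)
            if v is not None and v <= 0:
                issues.append(f"contact {i}: nonpositive {name}={v}")
        if c.ga_weeks is not None and c.ga_weeks < 0:
            issues.append(f"contact {i}: negative ga_weeks={c.ga_weeks}")
        if c.referral not in REFERRALS:
            issues.append(f"contact {i}: unknown referral {c.referral!r}")
        if c.urine_sugar is not None and c.urine_sugar not in URINE_RESULTS:
            issues.append(f"contact {i}: unknown urine_sugar {c.urine_sugar!r}")
        if c.presentation is not None and c.presentation not in PRESENTATIONS:
            issues.append(f"contact {i}: unknown presentation {c.presentation!r}")
        if c.ultrasound_growth is not None and c.ultrasound_growth not in US_GROWTH:
            issues.append(f"contact {i}: unknown ultrasound_growth {c.ultrasound_growth!r}")
    d = p.delivery
    if d is not None:
        if d.birthweight is not None and d.birthweight <= 0:
            issues.append(f"delivery: nonpositive birthweight={d.birthweight}")
        if d.ga_at_delivery is not None and not (0 < d.ga_at_delivery < 45):
            issues.append(f"delivery: ga_at_delivery={d.ga_at_delivery} outside (0, 45)")
        if d.presentation_at_delivery is not None and d.presentation_at_delivery not in PRESENTATIONS:
            issues.append(f"delivery: unknown presentation {d.presentation_at_delivery!r}")
    return issues


# ---------------------------------------------------------------------------
# JSON round-trip of a full episode
# ---------------------------------------------------------------------------

_DATE_FIELDS_CONTACT = ("date", "repeat_hb_date", "repeat_bp_date", "followup_us_date")


def _iso(d: Optional[date]) -> Optional[str]:
    return None if d is None else d.isoformat()


def pregnancy_to_dict(p: Pregnancy) -> dict:
    out = dataclasses.asdict(p)
    out["anchor_date"] = _iso(p.anchor_date)
    for cd in out["contacts"]:
        for f in _DATE_FIELDS_CONTACT:
            cd[f] = _iso(cd[f])
    return out


def pregnancy_from_dict(d: dict) -> Pregnancy:
    d = dict(d)
    d["anchor_date"] = date.fromisoformat(d["anchor_date"])
    contacts = []
    for cd in d.pop("contacts", []):
        cd = dict(cd)
        for f in _DATE_FIELDS_CONTACT:
            cd[f] = date.fromisoformat(cd[f]) if cd.get(f) else None
        contacts.append(AntenatalContact(**cd))
    delivery = d.pop("delivery", None)
    p = Pregnancy(contacts=contacts, delivery=DeliveryOutcome(**delivery) if delivery else None, **d)
    return p


def pregnancy_to_json(p: Pregnancy) -> str:
    return json.dumps(pregnancy_to_dict(p))


def pregnancy_from_json(s: str) -> Pregnancy:
    return pregnancy_from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# Four-table CSV interchange
# ---------------------------------------------------------------------------
# clusters.csv:    cluster_id, stratum, annual_enrolments, lab_available,
#                  ultrasound_available, prop_over40, prop_primiparous, arm, n_clinics
# pregnancies.csv: pregnancy_id, cluster_id, anchor_date, anchor_kind, booking_ga,
#                  maternal_age, parity, risk_referred, chronic_htn
# contacts.csv:    pregnancy_id, date, ga_weeks, hb, sbp, dbp, rbs, urine_sugar,
#                  sfh, ultrasound_growth, presentation, referral,
#                  repeat_hb_date, repeat_bp_date, followup_us_date
# deliveries.csv:  pregnancy_id, ga_at_delivery, birthweight, admission_hb,
#                  admission_sbp, admission_dbp, presentation_at_delivery, stillbirth


def clusters_to_frame(clusters: Iterable[ClinicCluster]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(c) for c in clusters])


def clusters_from_frame(df: pd.DataFrame) -> list[ClinicCluster]:
    out = []
    for row in df.to_dict("records"):
        row["lab_available"] = bool(row["lab_available"])
        row["ultrasound_available"] = bool(row["ultrasound_available"])
        row["n_clinics"] = int(row.get("n_clinics", 1))
        out.append(ClinicCluster(**{k: row[k] for k in ClinicCluster.__dataclass_fields__ if k in row}))
    return out


def episodes_to_frames(pregnancies: Sequence[Pregnancy]) -> dict[str, pd.DataFrame]:
    """Flatten episodes into the pregnancies/contacts/deliveries tables."""
    preg_rows, contact_rows, delivery_rows = [], [], []
    for p in pregnancies:
        preg_rows.append(
            dict(
                pregnancy_id=p.pregnancy_id,
                cluster_id=p.cluster_id,
                anchor_date=_iso(p.anchor_date),
                anchor_kind=p.anchor_kind,
                booking_ga=p.booking_ga,
                maternal_age=p.maternal_age,
                parity=p.parity,
                risk_referred=p.risk_referred,
                chronic_htn=p.chronic_htn,
                covariates=json.dumps(p.covariates, sort_keys=True) if p.covariates else "",
            )
        )
        for c in p.contacts:
            row = dataclasses.asdict(c)
            for f in _DATE_FIELDS_CONTACT:
                row[f] = _iso(row[f])
            contact_rows.append(dict(pregnancy_id=p.pregnancy_id, **row))
        if p.delivery is not None:
            delivery_rows.append(dict(pregnancy_id=p.pregnancy_id, **dataclasses.asdict(p.delivery)))
    cols_c = ["pregnancy_id"] + list(AntenatalContact.__dataclass_fields__)
    cols_d = ["pregnancy_id"] + list(DeliveryOutcome.__dataclass_fields__)
    return {
        "pregnancies": pd.DataFrame(preg_rows),
        "contacts": pd.DataFrame(contact_rows, columns=cols_c),
        "deliveries": pd.DataFrame(delivery_rows, columns=cols_d),
    }


def _opt(v, cast=float):
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return cast(v)


def episodes_from_frames(
    pregnancies: pd.DataFrame, contacts: pd.DataFrame, deliveries: pd.DataFrame
) -> list[Pregnancy]:
    """Rebuild Pregnancy episodes from the three individual-level tables.

    Gestational age at each contact is taken from the table when present and
    otherwise derived once here from the anchor date (single source of truth).
    """
    by_preg_contacts: dict[str, list[AntenatalContact]] = {}
    for row in contacts.to_dict("records"):
        c = AntenatalContact(
            date=date.fromisoformat(str(row["date"])),
            ga_weeks=_opt(row.get("ga_weeks"), int),
            hb=_opt(row.get("hb")),
            sbp=_opt(row.get("sbp")),
            dbp=_opt(row.get("dbp")),
            rbs=_opt(row.get("rbs")),
            urine_sugar=_opt(row.get("urine_sugar"), str),
            sfh=_opt(row.get("sfh")),
            ultrasound_growth=_opt(row.get("ultrasound_growth"), str),
            presentation=_opt(row.get("presentation"), str),
            referral=row.get("referral") if isinstance(row.get("referral"), str) else "none",
            repeat_hb_date=_opt(row.get("repeat_hb_date"), date.fromisoformat),
            repeat_bp_date=_opt(row.get("repeat_bp_date"), date.fromisoformat),
            followup_us_date=_opt(row.get("followup_us_date"), date.fromisoformat),
        )
        by_preg_contacts.setdefault(str(row["pregnancy_id"]), []).append(c)

    by_preg_delivery: dict[str, DeliveryOutcome] = {}
    for row in deliveries.to_dict("records"):
        sb = row.get("stillbirth")
        if sb is None or (isinstance(sb, float) and pd.isna(sb)) or sb == "":
            sb = None
        else:
            sb = str(sb).lower() in ("true", "1", "1.0")
        by_preg_delivery[str(row["pregnancy_id"])] = DeliveryOutcome(
            ga_at_delivery=_opt(row.get("ga_at_delivery"), lambda v: int(float(v))),
            birthweight=_opt(row.get("birthweight")),
            admission_hb=_opt(row.get("admission_hb")),
            admission_sbp=_opt(row.get("admission_sbp")),
            admission_dbp=_opt(row.get("admission_dbp")),
            presentation_at_delivery=_opt(row.get("presentation_at_delivery"), str),
            stillbirth=sb,
        )

    out = []
    for row in pregnancies.to_dict("records"):
        pid = str(row["pregnancy_id"])
        anchor = date.fromisoformat(str(row["anchor_date"]))
        clist = sorted(by_preg_contacts.get(pid, []), key=lambda c: c.date)
        for c in clist:
            if c.ga_weeks is None:
                c.ga_weeks = ga_completed_weeks(anchor, c.date)
        out.append(
            Pregnancy(
                pregnancy_id=pid,
                cluster_id=str(row["cluster_id"]),
                anchor_date=anchor,
                anchor_kind=str(row.get("anchor_kind", "lmp")),
                booking_ga=int(row["booking_ga"]),
                maternal_age=_opt(row.get("maternal_age")),
                parity=_opt(row.get("parity"), lambda v: int(float(v))),
                risk_referred=str(row.get("risk_referred")).lower() in ("true", "1", "1.0"),
                chronic_htn=str(row.get("chronic_htn")).lower() in ("true", "1", "1.0"),
                covariates=json.loads(row["covariates"]) if isinstance(row.get("covariates"), str) and row["covariates"] else {},
                contacts=clist,
                delivery=by_preg_delivery.get(pid),
            )
        )
    return out


def write_tables(
    clusters: Sequence[ClinicCluster], pregnancies: Sequence[Pregnancy], out_dir: str | Path,
    header_lines: Sequence[str] = (),
) -> dict[str, Path]:
    """Write the four-table CSV bundle; optional ``# ``-prefixed provenance lines."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = {"clusters": clusters_to_frame(clusters), **episodes_to_frames(pregnancies)}
    paths = {}
    for name, df in frames.items():
        path = out_dir / f"{name}.csv"
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df.to_csv(fh, index=False)
        paths[name] = path
    return paths


def read_tables(in_dir: str | Path) -> tuple[list[ClinicCluster], list[Pregnancy]]:
    in_dir = Path(in_dir)
    frames = {
        name: pd.read_csv(in_dir / f"{name}.csv", comment="#")
        for name in ("clusters", "pregnancies", "contacts", "deliveries")
    }
    clusters = clusters_from_frame(frames["clusters"])
    episodes = episodes_from_frames(frames["pregnancies"], frames["contacts"], frames["deliveries"])
    return clusters, episodes
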