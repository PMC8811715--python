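"""Guideline visit schedule: mapping contacts to scheduled visits, condition
eligibility, and attendance opportunities.

The national guideline for low-risk antenatal care requires five visits after
the booking (first) contact, nominally at 16, 18-22, 24-28, 32 and 36 weeks.
The guideline names the visits, not gestational-age intervals for the
single-week labels, so this module ships a declared default window table
(configurable via YAML): a contiguous, non-overlapping cover of mid-to-late
pregnancy, ensuring every attended contact maps to at most one scheduled
visit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import yaml

from .core_types import AntenatalContact, Pregnancy

CONDITIONS = ("anaemia", "hypertension", "diabetes", "growth", "malpresentation")

SCHEDULED_VISITS = ("wk16", "wk18_22", "wk24_28", "wk32", "wk36")


@dataclass(frozen=True)
class VisitWindow:
    """Half-open gestational-age window [ga_low, ga_high) in completed weeks."""

    label: str
    ga_low: int
    ga_high: int

    def contains(self, ga: int) -> bool:
        return self.ga_low <= ga < self.ga_high


#: Default windows; a declared convention of this package, configurable.
DEFAULT_WINDOWS: tuple[VisitWindow, ...] = (
    VisitWindow("wk16", 14, 18),
    VisitWindow("wk18_22", 18, 23),
    VisitWindow("wk24_28", 23, 29),
    VisitWindow("wk32", 29, 34),
    VisitWindow("wk36", 34, 43),
)


def load_windows(path) -> tuple[VisitWindow, ...]:
    """Load a window table from YAML: ``{wk16: [14, 18], ...}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    windows = tuple(VisitWindow(label, int(lo), int(hi)) for label, (lo, hi) in raw.items())
    validate_windows(windows)
    return windows


def validate_windows(windows: Sequence[VisitWindow]) -> None:
    for w in windows:
        if w.ga_low >= w.ga_high:
            raise ValueError(f"window {w.label}: ga_low {w.ga_low} >= ga_high {w.ga_high}")
    ordered = sorted(windows, key=lambda w: w.ga_low)
    for a, b in zip(ordered, ordered[1:]):
        if b.ga_low < a.ga_high:
            raise ValueError(f"windows {a.label} and {b.label} overlap")


def assign_visit(
    contact: AntenatalContact,
    pregnancy: Pregnancy,
    windows: Sequence[VisitWindow] = DEFAULT_WINDOWS,
) -> Optional[str]:
    """Map a contact to its scheduled-visit label, or ``None`` if outside all windows.

    The first chronological contact is always the booking visit
    (``first_contact``), whatever its gestational age.  Later contacts map to
    the window containing their GA.

    Raises ``ValueError`` when the contact's gestational age is undocumented
    and cannot be derived (unassignable).
    """
    if pregnancy.contacts and contact is pregnancy.contacts[0]:
        return "first_contact"
    if contact.ga_weeks is None:
        raise ValueError("contact has no gestational age; cannot assign a visit")
    for w in windows:
        if w.contains(contact.ga_weeks):
            return w.label
    return None


def routine_contacts(p: Pregnancy) -> list[AntenatalContact]:
    """Contacts belonging to routine low-risk care in the trial clinics.

    Care moves to a referral clinic or hospital once a woman is referred, so
    contacts after a referral (including risk referral at registration) are
    excluded from routine-care denominators.  The referring contact itself is
    retained: the referral is the management performed at that contact.
    """
    out = []
    for i, c in enumerate(p.contacts):
        out.append(c)
        if c.referral != "none" or (p.risk_referred and i == 0):
            break
    return out


def referral_ga(p: Pregnancy) -> Optional[int]:
    """GA (completed weeks) at the first referral, or None if never referred."""
    for i, c in enumerate(p.contacts):
        if c.referral != "none" or (p.risk_referred and i == 0):
            return c.ga_weeks
    return None


# Eligible-contact rows per condition, from the guideline screening table.
# "first_lt24" etc. are predicates on the booking contact's GA.
_ELIGIBILITY = {
    "anaemia": {"visits": {"first_contact", "wk24_28", "wk36"}},
    "hypertension": {"visits": {"first_contact", *SCHEDULED_VISITS}},
    # Booking contact is diabetes-eligible when it falls before 24 weeks or
    # after the 24-28 week window; any contact in the 24-28 window qualifies.
    "diabetes": {"visits": {"wk24_28"}, "first_if": lambda ga, windows: ga < 24 or ga >= _high(windows, "wk24_28")},
    "growth": {"visits": set(), "first_if": lambda ga, windows: ga > 20},
    "malpresentation": {"visits": {"wk36"}},
}


def _high(windows: Sequence[VisitWindow], label: str) -> int:
    for w in windows:
        if w.label == label:
            return w.ga_high
    raise KeyError(label)


def eligible_contacts(
    p: Pregnancy,
    condition: str,
    windows: Sequence[VisitWindow] = DEFAULT_WINDOWS,
) -> list[AntenatalContact]:
    """Attended routine contacts at which ``condition`` should be screened.

    Follows the guideline's eligible-contact rows: anaemia at booking, 24-28
    and 36 weeks; blood pressure at booking and all five scheduled visits;
    blood sugar at booking (when before 24 or after 28 weeks) and at 24-28
    weeks; fundal growth at a booking contact after 20 weeks; presentation at
    the 36-week contact.
    """
    if condition not in _ELIGIBILITY:
        raise ValueError(f"unknown condition {condition!r}")
    rule = _ELIGIBILITY[condition]
    out = []
    for c in routine_contacts(p):
        label = assign_visit(c, p, windows) if c.ga_weeks is not None else None
        if label == "first_contact":
            ga = c.ga_weeks
            if "first_contact" in rule["visits"]:
                out.append(c)
                continue
            first_if = rule.get("first_if")
            if ga is None:
                continue
            # A booking contact inside one of the condition's scheduled
            # windows is still due that window's tests (e.g. a first visit at
            # 26 weeks gets the 24-28-week screenings).
            in_window = any(w.label in rule["visits"] and w.contains(ga) for w in windows)
            if in_window or (first_if is not None and first_if(ga, windows)):
                out.append(c)
        elif label is not None and label in rule["visits"]:
            out.append(c)
    return out


@dataclass(frozen=True)
class AttendanceOpportunity:
    visit_label: str
    in_denominator: bool
    attended: bool


def attendance_opportunities(
    p: Pregnancy, windows: Sequence[VisitWindow] = DEFAULT_WINDOWS
) -> list[AttendanceOpportunity]:
    """Per-scheduled-visit attendance, with the denominator rule.

    A woman counts in the denominator of a scheduled visit only if she was
    registered before that visit (booking GA below the window's end) and had
    not been sent to a referral clinic or hospital before the window opened.
    Attendance means a routine contact inside the window.  A woman booked
    after the last window contributes zero opportunities.
    """
    ref_ga = referral_ga(p)
    routine = routine_contacts(p)
    out = []
    for w in windows:
        in_denom = p.booking_ga < w.ga_high
        if ref_ga is not None and ref_ga < w.ga_low:
            in_denom = False
        attended = any(c.ga_weeks is not None and w.contains(c.ga_weeks) for c in routine)
        out.append(AttendanceOpportunity(w.label, in_denom, attended and in_denom))
    return out


def attendance_fraction(p: Pregnancy, windows=DEFAULT_WINDOWS) -> Optional[float]:
    opps = [o for o in attendance_opportunities(p, windows) if o.in_denominator]
    if not opps:
        return None
    return sum(o.attended for o in opps) / len(opps)


def attended_full_schedule(p: Pregnancy, windows=DEFAULT_WINDOWS) -> bool:
    """True when every scheduled visit with an opportunity was attended and
    the full five-visit schedule was available (booked before the first window)."""
    opps = attendance_opportunities(p, windows)
    return all(o.in_denominator and o.attended for o in opps)
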