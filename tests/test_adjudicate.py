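"""Process and delivery outcome adjudication."""

from datetime import timedelta

import pytest

from anctrial.adjudicate import (
    adjudicate_all_processes,
    adjudicate_composite,
    adjudicate_process,
    adjudicate_stillbirth,
    combine_constituents,
    tabulate,
)
from anctrial.core_types import DeliveryOutcome

from .conftest import make_pregnancy


def _one(p, condition="anaemia"):
    recs = adjudicate_process(p, condition)
    assert len(recs) >= 1
    return recs


def test_screened_normal_is_success():
    p = make_pregnancy(gas=(8,), contact_kw={8: {"hb": 12.1}})
    (rec,) = _one(p)
    assert rec.screened and rec.finding == "none" and rec.success
    assert rec.managed_correctly is None


def test_repeat_hb_within_28_days_is_success():
    p = make_pregnancy(gas=(8,), contact_kw={8: {"hb": 9.0}})
    p.contacts[0].repeat_hb_date = p.contacts[0].date + timedelta(days=20)
    (rec,) = _one(p)
    assert rec.success and rec.managed_correctly


def test_repeat_hb_after_deadline_fails():
    p = make_pregnancy(gas=(8,), contact_kw={8: {"hb": 9.0}})
    p.contacts[0].repeat_hb_date = p.contacts[0].date + timedelta(days=29)
    (rec,) = _one(p)
    assert not rec.success and rec.managed_correctly is False


def test_undocumented_screening_is_failure():
    p = make_pregnancy(gas=(8,))
    (rec,) = _one(p)
    assert not rec.screened and not rec.success and rec.finding is None


def test_mild_hypertension_management_deadline():
    p = make_pregnancy(gas=(8,), contact_kw={8: {"sbp": 145.0, "dbp": 92.0}})
    p.contacts[0].repeat_bp_date = p.contacts[0].date + timedelta(days=4)
    (rec,) = _one(p, "hypertension")
    assert rec.success
    p.contacts[0].repeat_bp_date = p.contacts[0].date + timedelta(days=5)
    (rec,) = _one(p, "hypertension")
    assert not rec.success


def test_monitoring_switch_for_hypertension_referral():
    p = make_pregnancy(gas=(8,), contact_kw={8: {"sbp": 152.0, "dbp": 96.0}})
    p.contacts[0].repeat_bp_date = p.contacts[0].date + timedelta(days=2)
    (strict,) = adjudicate_process(p, "hypertension")
    assert not strict.success  # default requires referral
    (lenient,) = adjudicate_process(p, "hypertension", accept_monitoring=True)
    assert lenient.success


def test_adding_ontime_management_never_flips_success_to_failure():
    base = make_pregnancy(gas=(8,), contact_kw={8: {"hb": 9.0}})
    (before,) = _one(base)
    base.contacts[0].repeat_hb_date = base.contacts[0].date + timedelta(days=10)
    (after,) = _one(base)
    assert after.success >= before.success


# --- composite -------------------------------------------------------------


def _delivered(p, **kw):
    defaults = dict(ga_at_delivery=39, birthweight=3000.0, admission_hb=11.8,
                    admission_sbp=120.0, admission_dbp=78.0,
                    presentation_at_delivery="cephalic", stillbirth=False)
    defaults.update(kw)
    p.delivery = DeliveryOutcome(**defaults)
    return p


def test_admission_anaemia_makes_composite_occur():
    p = _delivered(make_pregnancy(), admission_hb=9.8)
    out = adjudicate_composite(p)
    assert out.constituents["anaemia"] == "occurred"
    assert out.composite == "occurred"


def test_all_constituents_absent_gives_absent():
    p = _delivered(make_pregnancy())
    assert adjudicate_composite(p).composite == "absent"


def test_missing_field_without_event_gives_missing():
    p = _delivered(make_pregnancy(), admission_sbp=None, admission_dbp=None)
    out = adjudicate_composite(p)
    assert out.constituents["severe_htn"] == "missing"
    assert out.composite == "missing"


def test_no_delivery_record_is_missing():
    assert adjudicate_composite(make_pregnancy()).composite == "missing"


def test_detected_sga_is_not_a_constituent_event():
    p = make_pregnancy(gas=(8, 26), contact_kw={26: {"sfh": 22.0}})  # d = -4: abnormal
    _delivered(p, birthweight=2300.0)
    out = adjudicate_composite(p)
    assert out.constituents["sga_undetected"] == "absent"
    p2 = _delivered(make_pregnancy(gas=(8, 26)), birthweight=2300.0)
    assert adjudicate_composite(p2).constituents["sga_undetected"] == "occurred"


def test_lga_and_term_thresholds():
    p = _delivered(make_pregnancy(), birthweight=3258.0)
    assert adjudicate_composite(p).constituents["lga"] == "occurred"
    preterm = _delivered(make_pregnancy(), ga_at_delivery=36, birthweight=3400.0)
    assert adjudicate_composite(preterm).constituents["lga"] == "absent"


def test_undetected_malpresentation():
    p = _delivered(make_pregnancy(), presentation_at_delivery="non_cephalic")
    assert adjudicate_composite(p).constituents["malpresentation_undetected"] == "occurred"
    detected = make_pregnancy(gas=(8, 36), contact_kw={36: {"presentation": "non_cephalic"}})
    _delivered(detected, presentation_at_delivery="non_cephalic")
    assert adjudicate_composite(detected).constituents["malpresentation_undetected"] == "absent"


@pytest.mark.parametrize(
    "ga, flag, expected",
    [(30, True, "stillbirth"), (26, True, "livebirth"), (39, False, "livebirth")],
)
def test_stillbirth_requires_28_weeks(ga, flag, expected):
    p = _delivered(make_pregnancy(), ga_at_delivery=ga, stillbirth=flag)
    assert adjudicate_stillbirth(p) == expected


def test_stillbirth_missing_without_record():
    assert adjudicate_stillbirth(make_pregnancy()) == "missing"


def test_combine_constituents_examples():
    assert combine_constituents(["occurred", "missing", "absent", "absent", "absent"]) == "occurred"
    assert combine_constituents(["absent"] * 5) == "absent"
    assert combine_constituents(["absent", "missing", "absent", "absent", "absent"]) == "missing"
    with pytest.raises(ValueError):
        combine_constituents(["yes"])


# --- tabulation ------------------------------------------------------------


def test_tabulate_counts_and_proportions():
    pregs = []
    for i, hb in enumerate([12.0, 9.0, 12.5, 13.0]):
        p = make_pregnancy(gas=(8,), contact_kw={8: {"hb": hb}})
        p.pregnancy_id = f"p{i}"
        p.cluster_id = "cA" if i < 2 else "cB"
        pregs.append(p)
    df = adjudicate_all_processes(pregs, conditions=("anaemia",))
    table = tabulate(df, {"cA": "control", "cB": "intervention"},
                     {p.pregnancy_id: p.cluster_id for p in pregs})
    ctrl = table[(table.condition == "anaemia") & (table.arm == "control")].iloc[0]
    assert ctrl.successes == 1 and ctrl.eligible == 2 and ctrl.proportion == 0.5
    inter = table[(table.condition == "anaemia") & (table.arm == "intervention")].iloc[0]
    assert inter.successes == 2 and inter.eligible == 2


def test_tabulate_empty_input():
    import pandas as pd

    table = tabulate(pd.DataFrame(), {})
    assert table.empty
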