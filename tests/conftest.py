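from datetime import date, timedelta

import pytest
from hypothesis import settings

from anctrial.core_types import AntenatalContact, DeliveryOutcome, Pregnancy
from anctrial.simulate import SimConfig, simulate_trial

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

ANCHOR = date(2017, 2, 1)


def make_contact(ga, **kw):
    """Contact at a gestational age, dated consistently from the anchor."""
    return AntenatalContact(date=ANCHOR + timedelta(weeks=ga), ga_weeks=ga, **kw)


def make_pregnancy(gas=(8, 26, 36), contact_kw=None, **kw):
    """Pregnancy with contacts at the given gestational ages."""
    contact_kw = contact_kw or {}
    contacts = [make_contact(ga, **contact_kw.get(ga, {})) for ga in sorted(gas)]
    defaults = dict(
        pregnancy_id="p1", cluster_id="c1", anchor_date=ANCHOR,
        booking_ga=min(gas) if gas else 0, contacts=contacts,
    )
    defaults.update(kw)
    return Pregnancy(**defaults)


@pytest.fixture
def pregnancy_factory():
    return make_pregnancy


@pytest.fixture
def contact_factory():
    return make_contact


@pytest.fixture(scope="session")
def small_trial():
    """A small complete synthetic trial shared across read-only tests."""
    cfg = SimConfig(n_clusters=30, cluster_size_mean=12, n_candidates=200, keep_best=20)
    return simulate_trial(cfg, seed=20170115)
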