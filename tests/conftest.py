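import dataclasses
from datetime import date
from pathlib import Path

import pytest
from hypothesis import settings

from encounterdq import CohortConfig, generate_cohort, read_encounters

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"

#: Hand-derived flag table for the committed rule fixture
#: (record_id -> (same_day, complete, valid)).
RULE_FIXTURE_EXPECTED = {
    "r01": (True, True, True),    # all-good follow-up, same-day
    "r02": (False, True, True),   # entered the next day
    "r03": (True, False, True),   # visit reason "other"
    "r04": (True, True, True),    # all-good initial with referral
    "r05": (True, False, True),   # initial lacking referral source
    "r06": (True, False, True),   # unknown-referral sentinel
    "r07": (False, True, False),  # entry precedes appointment
    "r08": (True, True, False),   # appointment before 2008
    "r09": (False, True, True),   # entered one day inside the 4-month limit
    "r10": (False, True, False),  # entered exactly at the 4-month limit
    "r11": (True, True, True),    # referral exactly 6 months before appt
    "r12": (True, True, False),   # referral gap one day over 6 months
}


@pytest.fixture(scope="session")
def rule_fixture_path() -> Path:
    return DATA_DIR / "rule_fixture.csv"


@pytest.fixture(scope="session")
def rule_fixture(rule_fixture_path):
    return read_encounters(rule_fixture_path, strict=True)


def small_config(**overrides) -> CohortConfig:
    """A light cohort for fast structural tests."""
    base = dict(
        n_users=8,
        start_date=date(2016, 6, 1),
        end_date=date(2016, 12, 31),
        intervention_date=date(2016, 10, 3),
        entries_per_user_week=4.0,
        p_same_day_pre=0.6,
        p_same_day_post=0.8,
        delay_geom_p=0.4,
        p_initial=0.25,
        p_reason_other_pre=0.1,
        p_reason_other_post=0.1,
        p_referral_unknown_pre=0.2,
        p_referral_unknown_spike=0.5,
        spike_duration_days=60,
        p_validity_error=0.02,
        quarter_end_delay_boost=0.1,
        p_no_show=0.05,
        seed=7,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())
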