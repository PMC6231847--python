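"""The three quality predicates and their aggregation to percentage series."""

import random
from dataclasses import replace
from datetime import date

import pandas as pd
import pytest

from encounterdq import (
    ConfigurationError,
    Dataset,
    EncounterRecord,
    UNKNOWN_REFERRAL_SENTINEL,
    aggregate,
    classify_complete,
    classify_same_day,
    classify_valid,
    generate_cohort,
    score_dataset,
    score_frame,
)
from encounterdq.quality import Grouping, add_months, assign_window

from conftest import RULE_FIXTURE_EXPECTED, small_config


def _rec(**overrides) -> EncounterRecord:
    base = dict(
        record_id="r1",
        user_id="u1",
        encounter_type="follow_up",
        appointment_date=date(2016, 11, 1),
        entry_date=date(2016, 11, 1),
        visit_reason="counseling",
        no_show=False,
    )
    base.update(overrides)
    return EncounterRecord(**base)


class TestClassifiers:
    @pytest.mark.parametrize(
        "appt,entry,expected",
        [
            (date(2016, 11, 1), date(2016, 11, 1), True),
            (date(2016, 11, 1), date(2016, 11, 2), False),
            (date(2016, 11, 2), date(2016, 11, 1), False),
        ],
    )
    def test_same_day(self, appt, entry, expected):
        assert classify_same_day(
            _rec(appointment_date=appt, entry_date=entry)
        ) is expected

    def test_complete_followup_all_present(self):
        assert classify_complete(_rec()) is True

    def test_other_reason_is_incomplete(self):
        assert classify_complete(_rec(visit_reason="other")) is False

    def test_initial_needs_referral_details(self):
        good = _rec(encounter_type="initial", referral_source="physician",
                    referral_date=date(2016, 10, 1))
        assert classify_complete(good) is True
        assert classify_complete(replace(good, referral_source=None)) is False
        assert classify_complete(replace(good, referral_date=None)) is False
        # the sentinel means "unknown", which is missing for completeness
        assert classify_complete(
            replace(good, referral_date=UNKNOWN_REFERRAL_SENTINEL)
        ) is False

    def test_unknown_required_field_rejected(self):
        with pytest.raises(ConfigurationError, match="favourite_color"):
            classify_complete(_rec(), required_fields={"favourite_color"})

    @pytest.mark.parametrize(
        "appt,entry,expected",
        [
            (date(2016, 11, 1), date(2016, 11, 1), True),   # same-day is valid
            (date(2016, 11, 2), date(2016, 11, 1), False),  # entry precedes appt
            (date(2007, 6, 1), date(2016, 11, 1), False),   # pre-2008 appt
            (date(2008, 1, 1), date(2008, 1, 2), False),    # floor is strict
            (date(2008, 1, 2), date(2008, 1, 2), True),
            (date(2016, 6, 1), date(2016, 9, 30), True),    # inside 4 months
            (date(2016, 6, 1), date(2016, 10, 1), False),   # exactly 4 months
            (date(2016, 6, 1), date(2016, 11, 1), False),   # past 4 months
        ],
    )
    def test_valid_date_rules(self, appt, entry, expected):
        assert classify_valid(
            _rec(appointment_date=appt, entry_date=entry)
        ) is expected

    @pytest.mark.parametrize(
        "referral,expected",
        [
            (date(2016, 5, 1), True),    # exactly 6 months: still valid
            (date(2016, 4, 30), False),  # one day over
            (None, True),                # rule skipped without a referral
            (UNKNOWN_REFERRAL_SENTINEL, True),  # unknown date: cannot evaluate
        ],
    )
    def test_referral_gap_rule(self, referral, expected):
        rec = _rec(encounter_type="initial", referral_source="physician",
                   referral_date=referral,
                   appointment_date=date(2016, 11, 1),
                   entry_date=date(2016, 11, 1))
        assert classify_valid(rec) is expected

    def test_calendar_month_arithmetic_clamps(self):
        assert add_months(date(2016, 10, 31), 4) == date(2017, 2, 28)
        assert add_months(date(2016, 1, 31), 1) == date(2016, 2, 29)


class TestScoring:
    def test_rule_fixture_matches_hand_derivation(self, rule_fixture):
        flags = score_dataset(rule_fixture)
        got = {f.record_id: (f.same_day, f.complete, f.valid) for f in flags}
        assert got == RULE_FIXTURE_EXPECTED

    def test_vectorized_scoring_agrees_with_record_classifiers(self, small_cohort):
        scored = score_frame(small_cohort.frame)
        for row, rec in zip(scored.itertuples(index=False), small_cohort.records):
            assert row.same_day == classify_same_day(rec)
            assert row.complete == classify_complete(rec)
            assert row.valid == classify_valid(rec)

    def test_one_flag_row_per_record_in_order(self, rule_fixture):
        flags = score_dataset(rule_fixture)
        assert [f.record_id for f in flags] == [
            r.record_id for r in rule_fixture.records
        ]

    def test_permutation_equivariance(self, rule_fixture):
        records = rule_fixture.records
        shuffled = records[:]
        random.Random(3).shuffle(shuffled)
        by_id = {f.record_id: f for f in score_dataset(rule_fixture)}
        shuffled_flags = score_dataset(Dataset.from_records(shuffled))
        assert all(by_id[f.record_id] == f for f in shuffled_flags)

    def test_same_day_implies_date_order_subconditions(self, small_cohort):
        for rec in small_cohort.records:
            if classify_same_day(rec):
                assert rec.appointment_date <= rec.entry_date
                assert rec.entry_date < add_months(rec.appointment_date, 4)


class TestAggregate:
    def test_by_user_percentage(self):
        records = [
            _rec(record_id=f"r{i}", entry_date=date(2016, 11, 1 + (i == 3)))
            for i in range(4)
        ]
        d = Dataset.from_records(records)
        series = aggregate(score_dataset(d), d, "by_user")
        assert series.table.loc[0, "pct_same_day"] == 75.0
        assert series.table.loc[0, "n_records"] == 4

    def test_by_month_hand_computed(self, rule_fixture):
        series = aggregate(score_dataset(rule_fixture), rule_fixture, "by_month")
        t = series.table.set_index("month")
        assert list(t.index) == ["2007-06", "2016-06", "2016-11"]
        assert t.loc["2007-06", "n_records"] == 1
        assert t.loc["2007-06", "pct_valid"] == 0.0
        assert t.loc["2016-06", "pct_same_day"] == 0.0
        assert t.loc["2016-06", "pct_valid"] == 50.0
        assert t.loc["2016-11", "n_records"] == 9
        assert t.loc["2016-11", "pct_same_day"] == pytest.approx(100 * 7 / 9)
        assert t.loc["2016-11", "pct_complete"] == pytest.approx(100 * 6 / 9)
        assert t.loc["2016-11", "pct_valid"] == pytest.approx(100 * 7 / 9)

    def test_conservation_and_bounds(self, small_cohort):
        flags = score_frame(small_cohort.frame)
        for grouping in ("by_user", "by_month"):
            series = aggregate(flags, small_cohort, grouping)
            t = series.table
            assert (t["n_records"] > 0).all()
            for c in ("pct_same_day", "pct_complete", "pct_valid"):
                assert t[c].between(0.0, 100.0).all()
                # flagged + unflagged counts reconstruct n_records exactly
                flagged = (t[c] / 100.0 * t["n_records"]).round(6)
                assert (flagged == flagged.round()).all()

    def test_window_assignment_boundaries(self):
        iv = date(2016, 11, 28)
        appt = pd.Series(pd.to_datetime([
            "2016-10-02",  # 57 days before: outside
            "2016-10-03",  # first pre day
            "2016-11-27",  # last pre day
            "2016-11-28",  # intervention day: first post day
            "2017-01-22",  # last post day
            "2017-01-23",  # 56 days after: outside
        ]))
        got = assign_window(appt, iv).tolist()
        assert got[0] is pd.NA and got[5] is pd.NA
        assert got[1:5] == ["pre", "pre", "post", "post"]

    def test_window_grouping_requires_intervention_date(self, small_cohort):
        flags = score_frame(small_cohort.frame)
        with pytest.raises(ConfigurationError, match="intervention_date"):
            aggregate(flags, small_cohort, "by_user_and_window")

    def test_misaligned_flags_rejected(self, rule_fixture, small_cohort):
        flags = score_frame(small_cohort.frame)
        with pytest.raises(ConfigurationError, match="aligned"):
            aggregate(flags, rule_fixture, "by_month")

    def test_error_free_cohort_scores_100_everywhere(self):
        cfg = small_config(
            p_same_day_pre=1.0, p_same_day_post=1.0, p_validity_error=0.0,
            p_reason_other_pre=0.0, p_reason_other_post=0.0,
            p_referral_unknown_pre=0.0, p_referral_unknown_spike=0.0,
            quarter_end_delay_boost=0.0,
        )
        d = generate_cohort(cfg)
        flags = score_frame(d.frame)
        for grouping in ("by_user", "by_month"):
            t = aggregate(flags, d, grouping).table
            for c in ("pct_same_day", "pct_complete", "pct_valid"):
                assert (t[c] == 100.0).all()
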