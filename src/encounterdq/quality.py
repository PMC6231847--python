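"""Record-level quality classification and percentage aggregation.

Three boolean dimensions are scored per encounter record:

``same_day``
    The record was entered into the system on the day of the appointment
    (the timeliness proxy).

``complete``
    Every required form field is populated, the visit reason is not the
    catch-all ``"other"``, and — for initial encounters — the referral
    source and a *known* referral date are present.  The 1900-01-01
    sentinel ("I do not know the referral date") counts as missing here.

``valid``
    Logical date consistency: the appointment does not post-date the entry,
    falls after 2008-01-01 (strictly), was entered within four calendar
    months, and — when a known referral date exists — the referral-to-
    appointment gap is at most six calendar months.

Month arithmetic is calendar-month advancement (add N months, clamp the
day to the target month's length), so the 4- and 6-month rules are
deterministic and day-count free.

Aggregation turns record flags into percentage measures per user, per
calendar month (for control charting) or per (user, pre/post window)
around an intervention date (for paired comparison).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from enum import Enum
from typing import Iterable, Optional, Set

import numpy as np
import pandas as pd
from dateutil.relativedelta import relativedelta

from .errors import ConfigurationError
from .io import Dataset, EncounterRecord, UNKNOWN_REFERRAL_SENTINEL

#: Earliest plausible appointment date; on-or-before is a validity error.
VALIDITY_FLOOR = date(2008, 1, 1)

#: Default required-field set for the completeness rule.  The source form is
#: larger than this schema; the set is configurable for richer schemas.
DEFAULT_REQUIRED_FIELDS: frozenset = frozenset(
    {"user_id", "encounter_type", "appointment_date", "entry_date", "visit_reason"}
)

_KNOWN_FIELDS = frozenset(
    {"record_id", "user_id", "profession", "encounter_type", "appointment_date",
     "entry_date", "referral_date", "referral_source", "visit_reason", "no_show"}
)

#: Length of each pre/post comparison window around the intervention.
WINDOW_DAYS = 56  # 8 weeks


class Grouping(str, Enum):
    BY_USER = "by_user"
    BY_MONTH = "by_month"
    BY_USER_AND_WINDOW = "by_user_and_window"


@dataclass(frozen=True)
class QualityFlags:
    """The three quality classifications for one record."""

    record_id: str
    same_day: bool
    complete: bool
    valid: bool


# ---------------------------------------------------------------------------
# per-record classifiers (reference semantics; scoring is vectorized below)
# ---------------------------------------------------------------------------

def classify_same_day(record: EncounterRecord) -> bool:
    """True iff the record was entered on the appointment day."""
    return record.entry_date == record.appointment_date


def _missing(value) -> bool:
    return value is None or value == ""


def classify_complete(
    record: EncounterRecord,
    required_fields: Iterable[str] = DEFAULT_REQUIRED_FIELDS,
) -> bool:
    """Apply the completeness rule to one record.

    Raises :class:`ConfigurationError` for an unknown field name in
    ``required_fields``.
    """
    required = set(required_fields)
    unknown = required - _KNOWN_FIELDS
    if unknown:
        raise ConfigurationError(
            f"unknown required field(s): {sorted(unknown)}"
        )
    for name in required:
        if _missing(getattr(record, name)):
            return False
    if record.visit_reason == "other":
        return False
    if record.encounter_type == "initial":
        if _missing(record.referral_source):
            return False
        if record.referral_date is None or record.referral_unknown:
            return False
    return True


def add_months(d: date, months: int) -> date:
    """Calendar-month advancement with day clamped to the target month."""
    return d + relativedelta(months=months)


def classify_valid(record: EncounterRecord) -> bool:
    """Apply the date-consistency (validity) rule to one record.

    The appointment may equal the entry date (same-day entry is valid);
    an unknown (sentinel) referral date skips the referral-gap condition,
    since an unknown date cannot be evaluated.
    """
    appt, entry = record.appointment_date, record.entry_date
    if appt > entry:
        return False
    if appt <= VALIDITY_FLOOR:
        return False
    if entry >= add_months(appt, 4):
        return False
    ref = record.referral_date
    if ref is not None and not record.referral_unknown:
        if appt > add_months(ref, 6):
            return False
    return True


# ---------------------------------------------------------------------------
# vectorized scoring
# ---------------------------------------------------------------------------

def _add_months_vec(dates: pd.Series, months: int) -> pd.Series:
    return dates + pd.DateOffset(months=months)


def score_frame(
    frame: pd.DataFrame,
    required_fields: Iterable[str] = DEFAULT_REQUIRED_FIELDS,
) -> pd.DataFrame:
    """Vectorized scoring; returns a frame with record_id + 3 boolean columns."""
    required = set(required_fields)
    unknown = required - _KNOWN_FIELDS
    if unknown:
        raise ConfigurationError(f"unknown required field(s): {sorted(unknown)}")

    appt = frame["appointment_date"]
    entry = frame["entry_date"]
    ref = frame["referral_date"]
    sentinel = pd.Timestamp(UNKNOWN_REFERRAL_SENTINEL)

    same_day = (entry == appt).to_numpy()

    complete = np.ones(len(frame), dtype=bool)
    for name in required:
        col = frame[name]
        if pd.api.types.is_datetime64_any_dtype(col):
            complete &= col.notna().to_numpy()
        else:
            complete &= (col.notna() & (col != "")).to_numpy()
    complete &= (frame["visit_reason"] != "other").to_numpy()
    is_initial = (frame["encounter_type"] == "initial").to_numpy()
    src = frame["referral_source"]
    has_source = (src.notna() & (src != "")).to_numpy()
    known_ref = (ref.notna() & (ref != sentinel)).to_numpy()
    complete &= ~is_initial | (has_source & known_ref)

    valid = (appt <= entry).to_numpy()
    valid &= (appt > pd.Timestamp(VALIDITY_FLOOR)).to_numpy()
    valid &= (entry < _add_months_vec(appt, 4)).to_numpy()
    ref_limit = _add_months_vec(ref, 6)
    valid &= (~known_ref | (appt <= ref_limit)).to_numpy()

    return pd.DataFrame(
        {
            "record_id": frame["record_id"].to_numpy(),
            "same_day": same_day,
            "complete": complete,
            "valid": valid,
        }
    )


def score_dataset(
    dataset: Dataset,
    required_fields: Iterable[str] = DEFAULT_REQUIRED_FIELDS,
) -> list[QualityFlags]:
    """Score every record, order preserved; one :class:`QualityFlags` each."""
    scored = score_frame(dataset.frame, required_fields)
    return [
        QualityFlags(r.record_id, bool(r.same_day), bool(r.complete), bool(r.valid))
        for r in scored.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class MeasureSeries:
    """Aggregated percentage measures, one row per group.

    ``table`` columns: the group key column(s), ``n_records``,
    ``pct_same_day``, ``pct_complete``, ``pct_valid``.  Groups with zero
    records are never emitted; percentages are in [0, 100].
    """

    grouping: Grouping
    table: pd.DataFrame

    @property
    def labels(self) -> list:
        keys = [c for c in ("user_id", "month", "window") if c in self.table.columns]
        if len(keys) == 1:
            return self.table[keys[0]].tolist()
        return list(self.table[keys].itertuples(index=False, name=None))

    def restrict(self, first: Optional[str] = None,
                 last: Optional[str] = None) -> "MeasureSeries":
        """Restrict a by-month series to a label range (inclusive).

        Validity errors of the "implausibly old appointment" kind place
        records in calendar months far outside the study period; restrict
        the chart to the months under analysis before building limits.
        """
        if self.grouping is not Grouping.BY_MONTH:
            raise ConfigurationError("restrict() applies to by_month series")
        t = self.table
        if first is not None:
            t = t[t["month"] >= first]
        if last is not None:
            t = t[t["month"] <= last]
        return MeasureSeries(self.grouping, t.reset_index(drop=True))

    def measure(self, name: str) -> pd.Series:
        col = f"pct_{name}"
        if col not in self.table.columns:
            raise ConfigurationError(
                f"unknown measure {name!r}; expected same_day, complete or valid"
            )
        return self.table[col]


def assign_window(appointment: pd.Series, intervention_date: date) -> pd.Series:
    """Label each appointment 'pre'/'post' or NA outside the 8-week windows.

    Pre window is [intervention − 56 d, intervention); post window is
    [intervention, intervention + 56 d).  Assignment is by appointment
    date: the measures describe encounters, not entry events.
    """
    iv = pd.Timestamp(intervention_date)
    lo, hi = iv - pd.Timedelta(days=WINDOW_DAYS), iv + pd.Timedelta(days=WINDOW_DAYS)
    out = pd.Series(pd.NA, index=appointment.index, dtype=object)
    out[(appointment >= lo) & (appointment < iv)] = "pre"
    out[(appointment >= iv) & (appointment < hi)] = "post"
    return out


def aggregate(
    flags: Iterable[QualityFlags] | pd.DataFrame,
    dataset: Dataset,
    grouping: Grouping | str = Grouping.BY_MONTH,
    intervention_date: Optional[date] = None,
) -> MeasureSeries:
    """Aggregate record flags into percentage measures.

    Parameters
    ----------
    flags
        Output of :func:`score_dataset` (or :func:`score_frame`), aligned
        with ``dataset``.
    grouping
        ``by_user``, ``by_month`` (calendar month of the appointment date)
        or ``by_user_and_window`` (pre/post around ``intervention_date``).
    intervention_date
        Required for ``by_user_and_window``; records outside the two
        8-week windows are dropped from that aggregation.
    """
    grouping = Grouping(grouping)
    if isinstance(flags, pd.DataFrame):
        fl = flags
    else:
        fl = pd.DataFrame(
            [(f.record_id, f.same_day, f.complete, f.valid) for f in flags],
            columns=["record_id", "same_day", "complete", "valid"],
        )
    frame = dataset.frame
    if len(fl) != len(frame) or not (fl["record_id"].to_numpy()
                                     == frame["record_id"].to_numpy()).all():
        raise ConfigurationError("flags are not aligned with the dataset")

    work = fl.copy()
    work["user_id"] = frame["user_id"].to_numpy()
    appt = pd.Series(frame["appointment_date"].to_numpy(), index=work.index)

    if grouping is Grouping.BY_USER:
        keys = ["user_id"]
    elif grouping is Grouping.BY_MONTH:
        work["month"] = appt.dt.strftime("%Y-%m")
        keys = ["month"]
    else:
        if intervention_date is None:
            raise ConfigurationError(
                "by_user_and_window grouping requires intervention_date"
            )
        work["window"] = assign_window(appt, intervention_date)
        work = work.dropna(subset=["window"])
        keys = ["user_id", "window"]

    grouped = work.groupby(keys, sort=True, observed=True)
    table = grouped.agg(
        n_records=("record_id", "size"),
        pct_same_day=("same_day", "mean"),
        pct_complete=("complete", "mean"),
        pct_valid=("valid", "mean"),
    ).reset_index()
    for c in ("pct_same_day", "pct_complete", "pct_valid"):
        table[c] = 100.0 * table[c]
    return MeasureSeries(grouping=grouping, table=table)
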