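"""Encounter-record data model and CSV reading/writing.

A dataset is one row per clinical encounter, as entered by an allied
health professional into a reporting system: who entered it, what kind of
visit it was, when the appointment happened, when the record actually made
it into the system, and (for initial encounters) where the referral came
from.  Two conventions matter downstream:

* empty strings denote missing optional values;
* the literal referral date ``1900-01-01`` is NOT missing data — it is the
  sentinel the source system writes when a user picks the "I do not know
  the referral date" option, and it must survive read/write untouched.

Dates are ISO-8601 only; no locale-dependent parsing is attempted.
"""

from __future__ import annotations

import hashlib
import io as _stdio
from dataclasses import dataclass, field, fields as dc_fields
from datetime import date
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import pandas as pd

from .errors import RowParseError, SchemaError

#: Referral date written by the source system for "I do not know the referral
#: date".  Preserved verbatim on read/write; interpreted as *unknown* (and
#: therefore incomplete) by the quality rules.
UNKNOWN_REFERRAL_SENTINEL = date(1900, 1, 1)

#: Canonical CSV column order.
COLUMNS = [
    "record_id",
    "user_id",
    "profession",
    "encounter_type",
    "appointment_date",
    "entry_date",
    "referral_date",
    "referral_source",
    "visit_reason",
    "no_show",
]

REQUIRED_COLUMNS = [
    "record_id",
    "user_id",
    "encounter_type",
    "appointment_date",
    "entry_date",
    "visit_reason",
    "no_show",
]

_DATE_COLUMNS = ["appointment_date", "entry_date", "referral_date"]
_ENCOUNTER_TYPES = frozenset({"initial", "follow_up"})


@dataclass(frozen=True)
class EncounterRecord:
    """One clinical encounter's structured entry."""

    record_id: str
    user_id: str
    encounter_type: str  # "initial" | "follow_up"
    appointment_date: date
    entry_date: date
    visit_reason: str
    no_show: bool
    profession: Optional[str] = None
    referral_date: Optional[date] = None
    referral_source: Optional[str] = None

    def __post_init__(self) -> None:
        if self.encounter_type not in _ENCOUNTER_TYPES:
            raise ValueError(
                f"encounter_type must be one of {sorted(_ENCOUNTER_TYPES)}, "
                f"got {self.encounter_type!r}"
            )

    @property
    def referral_unknown(self) -> bool:
        """True when the referral date is the 1900-01-01 sentinel."""
        return self.referral_date == UNKNOWN_REFERRAL_SENTINEL


class Dataset:
    """An ordered collection of encounter records.

    Internally backed by a :class:`pandas.DataFrame` (dates as
    ``datetime64[ns]``) so that scoring and aggregation stay vectorized;
    records materialize on demand.  Input order is preserved — no implicit
    sorting anywhere.
    """

    def __init__(self, frame: pd.DataFrame, provenance: str = "",
                 n_dropped: int = 0) -> None:
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"dataset frame lacks columns: {missing}")
        frame = frame[COLUMNS].reset_index(drop=True)
        for c in _DATE_COLUMNS:  # normalize datetime resolution
            frame[c] = frame[c].astype("datetime64[ns]")
        self._frame = frame
        self.provenance = provenance
        #: rows discarded during lenient reading
        self.n_dropped = n_dropped

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: Sequence[EncounterRecord],
                     provenance: str = "") -> "Dataset":
        rows = {c: [] for c in COLUMNS}
        for r in records:
            for f in dc_fields(EncounterRecord):
                rows[f.name].append(getattr(r, f.name))
        frame = pd.DataFrame(rows, columns=COLUMNS)
        for c in _DATE_COLUMNS:
            frame[c] = pd.to_datetime(frame[c], errors="coerce")
        if len(records) == 0:
            frame = _empty_frame()
        return cls(frame, provenance=provenance)

    # -- access ------------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """The backing frame (treat as read-only)."""
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[EncounterRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> EncounterRecord:
        return self.records[i]

    @property
    def records(self) -> list[EncounterRecord]:
        """Materialize all rows as :class:`EncounterRecord` objects."""
        out = []
        for row in self._frame.itertuples(index=False):
            out.append(
                EncounterRecord(
                    record_id=row.record_id,
                    user_id=row.user_id,
                    profession=_none_if_missing(row.profession),
                    encounter_type=row.encounter_type,
                    appointment_date=row.appointment_date.date(),
                    entry_date=row.entry_date.date(),
                    referral_date=(None if pd.isna(row.referral_date)
                                   else row.referral_date.date()),
                    referral_source=_none_if_missing(row.referral_source),
                    visit_reason=row.visit_reason,
                    no_show=bool(row.no_show),
                )
            )
        return out

    def digest(self) -> str:
        """SHA-256 of the canonical CSV serialization (provenance aid)."""
        buf = _stdio.StringIO()
        _write_frame(self._frame, buf)
        return hashlib.sha256(buf.getvalue().encode()).hexdigest()


def _none_if_missing(v) -> Optional[str]:
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return v


def _empty_frame() -> pd.DataFrame:
    frame = pd.DataFrame({c: pd.Series(dtype=object) for c in COLUMNS})
    for c in _DATE_COLUMNS:
        frame[c] = pd.Series(dtype="datetime64[ns]")
    frame["no_show"] = pd.Series(dtype=bool)
    return frame


# -- reading ---------------------------------------------------------------

def read_encounters(path: Union[str, Path], strict: bool = True) -> Dataset:
    """Read an encounter CSV.

    Parameters
    ----------
    path
        CSV file with a header row naming every record field (the optional
        columns ``profession``, ``referral_date``, ``referral_source`` may
        be absent entirely).
    strict
        If True (default) any malformed row raises :class:`RowParseError`.
        If False malformed rows are dropped and counted in the returned
        dataset's ``n_dropped`` tally.

    Raises
    ------
    SchemaError
        If a required column is missing from the header.
    RowParseError
        Strict mode only: a date fails ISO-8601 parsing, ``no_show`` is not
        true/false, or ``encounter_type`` is not a known value.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    for c in COLUMNS:
        if c not in raw.columns:
            raw[c] = ""
    raw = raw[COLUMNS]

    bad = pd.Series(False, index=raw.index)
    parsed = {}
    for c in _DATE_COLUMNS:
        col = raw[c].str.strip()
        dt = pd.to_datetime(col, format="%Y-%m-%d", errors="coerce")
        invalid = dt.isna() & (col != "")
        if c in ("appointment_date", "entry_date"):
            invalid |= col == ""
        parsed[c] = dt
        bad |= invalid

    no_show = raw["no_show"].str.strip().str.lower()
    bad |= ~no_show.isin(["true", "false"])
    bad |= ~raw["encounter_type"].isin(list(_ENCOUNTER_TYPES))

    if strict and bad.any():
        i = int(bad.idxmax())
        raise RowParseError(i, f"malformed row (record_id={raw.at[i, 'record_id']!r}): "
                               "check dates, encounter_type and no_show")

    frame = raw.copy()
    for c in _DATE_COLUMNS:
        frame[c] = parsed[c]
    frame["no_show"] = no_show == "true"
    n_dropped = int(bad.sum())
    if n_dropped:
        frame = frame.loc[~bad].reset_index(drop=True)

    dup = frame["record_id"].duplicated()
    if dup.any():
        raise SchemaError(
            f"{path.name}: duplicate record_id(s): "
            f"{sorted(frame.loc[dup, 'record_id'].unique())[:5]}"
        )
    return Dataset(frame, provenance=str(path), n_dropped=n_dropped)


# -- writing ---------------------------------------------------------------

def _write_frame(frame: pd.DataFrame, handle) -> None:
    out = frame.copy()
    for c in _DATE_COLUMNS:
        out[c] = out[c].dt.strftime("%Y-%m-%d").fillna("")
    out["no_show"] = out["no_show"].map({True: "true", False: "false"})
    for c in ("profession", "referral_source"):
        out[c] = out[c].fillna("")
    out.to_csv(handle, index=False, lineterminator="\n")


def write_encounters(dataset: Dataset, path: Union[str, Path]) -> Path:
    """Write a dataset as CSV with ISO-8601 dates.

    ``read_encounters(write_encounters(d))`` reproduces ``d``
    field-for-field, including the 1900-01-01 sentinel.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        _write_frame(dataset.frame, fh)
    return path
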