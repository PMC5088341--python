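"""Domain types, validation and delimited-text I/O for EMA cohorts.

An ecological momentary assessment (EMA) cohort consists of a participant
roster (one row per smoker in a post-quit observation week) and an EMA table
(one row per completed momentary assessment).  Each assessment carries four
5-point ordinal items (urge to smoke, stress, cessation motivation, cigarette
availability), two binary items (interacting with a smoker, alcohol in the
past hour) and a momentary smoking report.

Ordinal coding is fixed as 1-5 with 1 = "strongly disagree" / "not at all
available" and 5 = "strongly agree" / "easily available".  Timestamps are
ISO-8601 at minute resolution in a single study timezone; booleans are
serialized as ``yes``/``no`` (case-insensitive on input).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pandas as pd

__all__ = [
    "Arm",
    "PromptType",
    "EmaRecord",
    "Participant",
    "CohortTable",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "EMA_COLUMNS",
    "ROSTER_COLUMNS",
    "ORDINAL_ITEMS",
    "TIMESTAMP_FORMAT",
]

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M"

#: EMA CSV schema, exact column order.
EMA_COLUMNS = (
    "participant_id",
    "timestamp",
    "prompt_type",
    "urge",
    "stress",
    "motivation",
    "availability",
    "interacting_smoker",
    "alcohol_past_hour",
    "smoked_since_last",
)

#: Roster CSV schema, exact column order.
ROSTER_COLUMNS = (
    "participant_id",
    "arm",
    "quit_time",
    "first_lapse_time",
    "consistent_reporting",
)

ORDINAL_ITEMS = ("urge", "stress", "motivation", "availability")
_BOOL_ITEMS = ("interacting_smoker", "alcohol_past_hour", "smoked_since_last")


class Arm(str, enum.Enum):
    """Parent-trial treatment arm: usual care or contingency management."""

    UC = "UC"
    CM = "CM"


class PromptType(str, enum.Enum):
    """How an EMA was triggered.

    ``daily_diary`` is the wake-anchored first prompt of the day, ``random``
    a signal-contingent prompt at a random waking time, and the two
    ``*_selfinit`` types are event-contingent assessments the participant
    initiated (urge episode; about to lapse).
    """

    DAILY_DIARY = "daily_diary"
    RANDOM = "random"
    URGE_SELFINIT = "urge_selfinit"
    LAPSE_SELFINIT = "lapse_selfinit"


class CohortValidationError(ValueError):
    """Raised for any malformed cohort input.

    Carries enough context (file, line, column) to locate the offending
    cell; validation never silently coerces.
    """

    def __init__(self, message: str, *, file: str | None = None,
                 line: int | None = None, column: str | None = None):
        self.file = file
        self.line = line
        self.column = column
        loc = []
        if file is not None:
            loc.append(f"file={file}")
        if line is not None:
            loc.append(f"line={line}")
        if column is not None:
            loc.append(f"column={column}")
        super().__init__(message + (f" [{', '.join(loc)}]" if loc else ""))


@dataclass(frozen=True)
class EmaRecord:
    """One completed momentary assessment."""

    participant_id: str
    timestamp: pd.Timestamp
    prompt_type: PromptType
    urge: int
    stress: int
    motivation: int
    availability: int
    interacting_smoker: bool
    alcohol_past_hour: bool
    smoked_since_last: bool

    def __post_init__(self):
        for item in ORDINAL_ITEMS:
            v = getattr(self, item)
            if v not in (1, 2, 3, 4, 5):
                raise CohortValidationError(
                    f"ordinal item {item!r} must be in 1-5, got {v!r}",
                    column=item)
        object.__setattr__(self, "timestamp",
                           pd.Timestamp(self.timestamp).floor("min"))
        object.__setattr__(self, "prompt_type", PromptType(self.prompt_type))


@dataclass(frozen=True)
class Participant:
    """Roster entry for one participant of the post-quit week."""

    participant_id: str
    arm: Arm
    quit_time: pd.Timestamp
    first_lapse_time: Optional[pd.Timestamp] = None
    consistent_reporting: bool = True

    def __post_init__(self):
        object.__setattr__(self, "arm", Arm(self.arm))
        object.__setattr__(self, "quit_time",
                           pd.Timestamp(self.quit_time).floor("min"))
        if self.first_lapse_time is not None:
            flt = pd.Timestamp(self.first_lapse_time).floor("min")
            if flt < self.quit_time:
                raise CohortValidationError(
                    f"first_lapse_time {flt} precedes quit_time "
                    f"{self.quit_time} for participant {self.participant_id}",
                    column="first_lapse_time")
            object.__setattr__(self, "first_lapse_time", flt)

    @property
    def lapsed(self) -> bool:
        """Whether a first lapse was observed (lapsed ⇔ lapse time present)."""
        return self.first_lapse_time is not None


@dataclass
class CohortTable:
    """A validated roster + EMA table pair.

    Canonical storage is two pandas DataFrames with the CSV schemas of
    :data:`ROSTER_COLUMNS` and :data:`EMA_COLUMNS` (timestamps as
    ``pd.Timestamp``, booleans as ``bool``).  ``meta`` carries optional
    generator bookkeeping (e.g. per-proximity-class record counts).
    """

    roster: pd.DataFrame
    ema: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.roster = self.roster.reset_index(drop=True)
        self.ema = self.ema.reset_index(drop=True)
        # canonical dtypes so vectorized time arithmetic and equality work
        self.roster["participant_id"] = self.roster["participant_id"].astype(str)
        self.roster["quit_time"] = pd.to_datetime(self.roster["quit_time"])
        self.roster["first_lapse_time"] = pd.to_datetime(
            self.roster["first_lapse_time"])
        self.roster["consistent_reporting"] = (
            self.roster["consistent_reporting"].astype(bool))
        self.ema["participant_id"] = self.ema["participant_id"].astype(str)
        self.ema["timestamp"] = pd.to_datetime(self.ema["timestamp"])
        for col in ORDINAL_ITEMS:
            self.ema[col] = self.ema[col].astype("int64")
        for col in _BOOL_ITEMS:
            self.ema[col] = self.ema[col].astype(bool)
        ids = set(self.roster["participant_id"])
        if len(ids) != len(self.roster):
            dup = self.roster["participant_id"][
                self.roster["participant_id"].duplicated()].iloc[0]
            raise CohortValidationError(
                f"duplicate participant_id {dup!r} in roster",
                column="participant_id")
        orphans = set(self.ema["participant_id"]) - ids
        if orphans:
            raise CohortValidationError(
                f"EMA rows reference unknown participant_id(s): "
                f"{sorted(orphans)[:5]}", column="participant_id")

    # -- record-level views -------------------------------------------------

    @classmethod
    def from_records(cls, participants: Sequence[Participant],
                     records: Sequence[EmaRecord],
                     meta: dict | None = None) -> "CohortTable":
        roster = pd.DataFrame(
            [(p.participant_id, p.arm.value, p.quit_time,
              p.first_lapse_time, p.consistent_reporting)
             for p in participants],
            columns=list(ROSTER_COLUMNS))
        ema = pd.DataFrame(
            [(r.participant_id, r.timestamp, r.prompt_type.value, r.urge,
              r.stress, r.motivation, r.availability, r.interacting_smoker,
              r.alcohol_past_hour, r.smoked_since_last)
             for r in records],
            columns=list(EMA_COLUMNS))
        if roster.empty:
            roster = pd.DataFrame(columns=list(ROSTER_COLUMNS))
        if ema.empty:
            ema = pd.DataFrame(columns=list(EMA_COLUMNS))
        return cls(roster=roster, ema=ema, meta=dict(meta or {}))

    @property
    def participants(self) -> Iterator[Participant]:
        for row in self.roster.itertuples(index=False):
            flt = row.first_lapse_time
            if pd.isna(flt):
                flt = None
            yield Participant(row.participant_id, Arm(row.arm),
                              row.quit_time, flt,
                              bool(row.consistent_reporting))

    @property
    def records(self) -> Iterator[EmaRecord]:
        for row in self.ema.itertuples(index=False):
            yield EmaRecord(row.participant_id, row.timestamp,
                            PromptType(row.prompt_type), int(row.urge),
                            int(row.stress), int(row.motivation),
                            int(row.availability),
                            bool(row.interacting_smoker),
                            bool(row.alcohol_past_hour),
                            bool(row.smoked_since_last))

    def participant(self, participant_id: str) -> Participant:
        sub = self.roster[self.roster["participant_id"] == participant_id]
        if sub.empty:
            raise KeyError(participant_id)
        flt = sub.iloc[0]["first_lapse_time"]
        return Participant(participant_id, Arm(sub.iloc[0]["arm"]),
                           sub.iloc[0]["quit_time"],
                           None if pd.isna(flt) else flt,
                           bool(sub.iloc[0]["consistent_reporting"]))

    def equals(self, other: "CohortTable") -> bool:
        """Field-for-field equality of roster and EMA tables."""
        return (self.roster.equals(other.roster)
                and self.ema.equals(other.ema))


# -- parsing helpers --------------------------------------------------------

def _parse_bool(raw: str, *, file: str, line: int, column: str) -> bool:
    s = str(raw).strip().lower()
    if s in ("yes", "true", "1"):
        return True
    if s in ("no", "false", "0"):
        return False
    raise CohortValidationError(
        f"expected yes/no, got {raw!r}", file=file, line=line, column=column)


def _parse_ts(raw: str, *, file: str, line: int, column: str) -> pd.Timestamp:
    try:
        return pd.Timestamp(str(raw).strip()).floor("min")
    except (ValueError, TypeError) as exc:
        raise CohortValidationError(
            f"unparseable timestamp {raw!r}: {exc}",
            file=file, line=line, column=column) from None


def _parse_ordinal(raw: str, *, file: str, line: int, column: str) -> int:
    try:
        v = int(str(raw).strip())
    except (ValueError, TypeError):
        raise CohortValidationError(
            f"expected integer 1-5, got {raw!r}",
            file=file, line=line, column=column) from None
    if v not in (1, 2, 3, 4, 5):
        raise CohortValidationError(
            f"ordinal item {column!r} out of range 1-5: {v}",
            file=file, line=line, column=column)
    return v


def _read_csv(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise CohortValidationError(f"no such file: {path}", file=str(path))
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != list(columns):
        raise CohortValidationError(
            f"expected columns {list(columns)}, got {list(df.columns)}",
            file=str(path), line=1)
    return df


def read_cohort(ema_path: str | Path, roster_path: str | Path) -> CohortTable:
    """Read and validate a cohort from its two CSV files.

    Row order is preserved.  Every malformed cell raises
    :class:`CohortValidationError` naming the file, line (1-based, header is
    line 1) and column; an EMA row whose participant_id is absent from the
    roster is an error.
    """
    ema_path, roster_path = Path(ema_path), Path(roster_path)
    raw_roster = _read_csv(roster_path, ROSTER_COLUMNS)
    raw_ema = _read_csv(ema_path, EMA_COLUMNS)

    rfile = str(roster_path)
    participants = []
    for i, row in enumerate(raw_roster.itertuples(index=False)):
        line = i + 2
        if row.arm not in (a.value for a in Arm):
            raise CohortValidationError(
                f"unknown arm {row.arm!r}", file=rfile, line=line,
                column="arm")
        flt = (None if str(row.first_lapse_time).strip() == ""
               else _parse_ts(row.first_lapse_time, file=rfile, line=line,
                              column="first_lapse_time"))
        try:
            participants.append(Participant(
                str(row.participant_id),
                Arm(row.arm),
                _parse_ts(row.quit_time, file=rfile, line=line,
                          column="quit_time"),
                flt,
                _parse_bool(row.consistent_reporting, file=rfile, line=line,
                            column="consistent_reporting")))
        except CohortValidationError as exc:
            raise CohortValidationError(
                str(exc), file=rfile, line=line, column=exc.column) from None

    efile = str(ema_path)
    records = []
    for i, row in enumerate(raw_ema.itertuples(index=False)):
        line = i + 2
        if row.prompt_type not in (p.value for p in PromptType):
            raise CohortValidationError(
                f"unknown prompt_type {row.prompt_type!r}",
                file=efile, line=line, column="prompt_type")
        records.append(EmaRecord(
            str(row.participant_id),
            _parse_ts(row.timestamp, file=efile, line=line,
                      column="timestamp"),
            PromptType(row.prompt_type),
            *(
                _parse_ordinal(getattr(row, item), file=efile, line=line,
                               column=item)
                for item in ORDINAL_ITEMS
            ),
            *(
                _parse_bool(getattr(row, item), file=efile, line=line,
                            column=item)
                for item in _BOOL_ITEMS
            )))

    return CohortTable.from_records(participants, records)


def _fmt_bool(v: bool) -> str:
    return "yes" if v else "no"


def write_cohort(cohort: CohortTable, ema_path: str | Path,
                 roster_path: str | Path) -> None:
    """Write a cohort to its two CSV files, readable back by
    :func:`read_cohort` with identical content."""
    roster = cohort.roster.copy()
    roster["quit_time"] = roster["quit_time"].map(
        lambda t: pd.Timestamp(t).strftime(TIMESTAMP_FORMAT))
    roster["first_lapse_time"] = roster["first_lapse_time"].map(
        lambda t: "" if pd.isna(t) else pd.Timestamp(t).strftime(
            TIMESTAMP_FORMAT))
    roster["consistent_reporting"] = roster["consistent_reporting"].map(
        _fmt_bool)
    roster.to_csv(roster_path, index=False, columns=list(ROSTER_COLUMNS))

    ema = cohort.ema.copy()
    if not ema.empty:
        ema["timestamp"] = ema["timestamp"].map(
            lambda t: pd.Timestamp(t).strftime(TIMESTAMP_FORMAT))
        for col in _BOOL_ITEMS:
            ema[col] = ema[col].map(_fmt_bool)
    ema.to_csv(ema_path, index=False, columns=list(EMA_COLUMNS))
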