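"""Participant records and cohort CSV serialization.

A cohort is a list of :class:`ParticipantRecord`, one per study participant.
The on-disk format is a plain UTF-8 comma-separated file with one row per
participant and the documented header (see :data:`CSV_COLUMNS`): identifier,
demographics, medication count, 17 chronic-disease flags, living situation,
the GP's three-level vulnerability rating, 23 screening-questionnaire problem
flags, 18 GARS item scores at baseline and, for participants seen again, the
18 GARS item scores at 12 months, plus an event code for everyone else
(died / nursing-home admission / lost to follow-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

N_ISCOPE_ITEMS = 23
N_GARS_ITEMS = 18
N_DISEASE_FLAGS = 17

SEXES = ("male", "female")
LIVING_SITUATIONS = ("independent", "home_for_older_persons")
GP_OPINIONS = ("not_vulnerable", "possibly_vulnerable", "vulnerable")
EVENTS = ("followed_up", "died", "nursing_home", "lost")

CSV_COLUMNS = (
    ["id", "age", "sex", "med_count"]
    + [f"disease_{i}" for i in range(1, N_DISEASE_FLAGS + 1)]
    + ["living", "gp_opinion"]
    + [f"item_{i}" for i in range(1, N_ISCOPE_ITEMS + 1)]
    + [f"g0_{i}" for i in range(1, N_GARS_ITEMS + 1)]
    + [f"g12_{i}" for i in range(1, N_GARS_ITEMS + 1)]
    + ["event"]
)


class RecordValidationError(ValueError):
    """A participant record violates a structural invariant."""


class CohortParseError(ValueError):
    """A cohort file row could not be parsed; carries row/column context."""

    def __init__(self, row: int, column: str, message: str):
        self.row = row
        self.column = column
        super().__init__(f"row {row}, column {column!r}: {message}")


@dataclass
class ParticipantRecord:
    """One participant's covariates, questionnaire and GARS measurements.

    ``gars_items_t12`` is present exactly when ``event == "followed_up"``;
    participants who died, were institutionalised or were lost have no
    12-month functional-status measurement.
    """

    id: str
    age: float
    sex: str
    medication_count: int
    disease_flags: list[bool]
    living_situation: str
    gp_opinion: str
    iscope_items: list[bool]
    gars_items_t0: list[int]
    gars_items_t12: list[int] | None = None
    event: str = "followed_up"

    def validate(self) -> None:
        if self.age < 75:
            raise RecordValidationError(f"{self.id}: age {self.age} < 75")
        if self.sex not in SEXES:
            raise RecordValidationError(f"{self.id}: sex {self.sex!r}")
        if self.medication_count < 0:
            raise RecordValidationError(f"{self.id}: negative medication count")
        if len(self.disease_flags) != N_DISEASE_FLAGS:
            raise RecordValidationError(
                f"{self.id}: expected {N_DISEASE_FLAGS} disease flags"
            )
        if self.living_situation not in LIVING_SITUATIONS:
            raise RecordValidationError(f"{self.id}: living {self.living_situation!r}")
        if self.gp_opinion not in GP_OPINIONS:
            raise RecordValidationError(f"{self.id}: gp_opinion {self.gp_opinion!r}")
        if len(self.iscope_items) != N_ISCOPE_ITEMS:
            raise RecordValidationError(
                f"{self.id}: expected {N_ISCOPE_ITEMS} questionnaire items"
            )
        if self.event not in EVENTS:
            raise RecordValidationError(f"{self.id}: event {self.event!r}")
        _check_gars_items(self.gars_items_t0, self.id, "baseline")
        if self.event == "followed_up":
            if self.gars_items_t12 is None:
                raise RecordValidationError(
                    f"{self.id}: followed-up participant lacks 12-month GARS items"
                )
            _check_gars_items(self.gars_items_t12, self.id, "12-month")
        elif self.gars_items_t12 is not None:
            raise RecordValidationError(
                f"{self.id}: event {self.event!r} but 12-month GARS items present"
            )


def _check_gars_items(items: Sequence[int], rid: str, when: str) -> None:
    if len(items) != N_GARS_ITEMS:
        raise RecordValidationError(
            f"{rid}: expected {N_GARS_ITEMS} {when} GARS items, got {len(items)}"
        )
    for i, v in enumerate(items, start=1):
        if not (1 <= int(v) <= 4):
            raise RecordValidationError(
                f"{rid}: {when} GARS item {i} = {v} outside 1..4"
            )


def records_to_frame(records: Iterable[ParticipantRecord]) -> pd.DataFrame:
    """Flatten records into the cohort CSV column layout."""
    rows = []
    for r in records:
        row: dict = {"id": r.id, "age": r.age, "sex": r.sex, "med_count": r.medication_count}
        for i, f in enumerate(r.disease_flags, start=1):
            row[f"disease_{i}"] = int(f)
        row["living"] = r.living_situation
        row["gp_opinion"] = r.gp_opinion
        for i, f in enumerate(r.iscope_items, start=1):
            row[f"item_{i}"] = int(f)
        for i, v in enumerate(r.gars_items_t0, start=1):
            row[f"g0_{i}"] = int(v)
        for i in range(1, N_GARS_ITEMS + 1):
            row[f"g12_{i}"] = (
                int(r.gars_items_t12[i - 1]) if r.gars_items_t12 is not None else ""
            )
        row["event"] = r.event
        rows.append(row)
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_cohort(records: Iterable[ParticipantRecord], path) -> None:
    """Write a cohort to ``path`` as UTF-8 CSV ("." decimal, blank = absent)."""
    records_to_frame(records).to_csv(path, index=False, encoding="utf-8")


def read_cohort(path) -> list[ParticipantRecord]:
    """Read a cohort CSV; malformed cells raise :class:`CohortParseError`
    naming the offending row and column."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CohortParseError(0, missing[0], "column missing from header")
    records: list[ParticipantRecord] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based, after header
        records.append(_parse_row(row, rownum))
    return records


def _parse_row(row: pd.Series, rownum: int) -> ParticipantRecord:
    def get_int(col: str, lo: int | None = None, hi: int | None = None) -> int:
        try:
            v = int(row[col])
        except ValueError:
            raise CohortParseError(rownum, col, f"not an integer: {row[col]!r}")
        if lo is not None and v < lo or hi is not None and v > hi:
            raise CohortParseError(rownum, col, f"value {v} outside [{lo}, {hi}]")
        return v

    def get_cat(col: str, allowed: tuple[str, ...]) -> str:
        v = row[col]
        if v not in allowed:
            raise CohortParseError(rownum, col, f"{v!r} not one of {allowed}")
        return v

    try:
        age = float(row["age"])
    except ValueError:
        raise CohortParseError(rownum, "age", f"not a number: {row['age']!r}")
    event = get_cat("event", EVENTS)
    t12: list[int] | None
    if event == "followed_up":
        t12 = [get_int(f"g12_{i}", 1, 4) for i in range(1, N_GARS_ITEMS + 1)]
    else:
        for i in range(1, N_GARS_ITEMS + 1):
            if row[f"g12_{i}"] != "":
                raise CohortParseError(
                    rownum, f"g12_{i}", f"present but event is {event!r}"
                )
        t12 = None
    rec = ParticipantRecord(
        id=row["id"],
        age=age,
        sex=get_cat("sex", SEXES),
        medication_count=get_int("med_count", 0),
        disease_flags=[bool(get_int(f"disease_{i}", 0, 1)) for i in range(1, N_DISEASE_FLAGS + 1)],
        living_situation=get_cat("living", LIVING_SITUATIONS),
        gp_opinion=get_cat("gp_opinion", GP_OPINIONS),
        iscope_items=[bool(get_int(f"item_{i}", 0, 1)) for i in range(1, N_ISCOPE_ITEMS + 1)],
        gars_items_t0=[get_int(f"g0_{i}", 1, 4) for i in range(1, N_GARS_ITEMS + 1)],
        gars_items_t12=t12,
        event=event,
    )
    try:
        rec.validate()
    except RecordValidationError as e:
        raise CohortParseError(rownum, "record", str(e))
    return rec
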