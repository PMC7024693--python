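"""Domain types, validation and CSV round-trip for the student cohort.

One row per student; SDQ subscale sums at baseline (T1) and one-year
follow-up (T2), socio-demographics, functioning/environment covariates and
three support-receipt flags.  Missing T2 (lost to follow-up) is encoded as
empty cells and yields a record that is present but not analysable.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

#: Subscale integer ranges: four problem subscales 0-10, impact supplement 0-15.
SUBSCALE_RANGES = {
    "emotional": (0, 10),
    "conduct": (0, 10),
    "hyperactivity": (0, 10),
    "peer": (0, 10),
    "impact": (0, 15),
}

#: The three outcome subscales entering reliable-change classification.
OUTCOME_SUBSCALES = ("emotional", "conduct", "hyperactivity")

ETHNICITY_LEVELS = ("White", "Asian", "Black", "Mixed", "Other")
DURATION_LEVELS = ("none", "<1mo", "1-5mo", "6-12mo", ">1yr")
GENDER_LEVELS = ("male", "female")

SCHOOL_CLIMATE_RANGE = (0, 14)  # 7 items scored 0-2
QUALITY_OF_LIFE_RANGE = (0, 36)  # 9 items scored 0-4

#: Canonical CSV column order.
CSV_COLUMNS = [
    "id",
    "school_id",
    "gender",
    "ethnicity",
    "fsm",
    "sen",
    "attainment",
    "school_climate",
    "quality_of_life",
    "duration",
    "support_counsellor",
    "support_peer_mentor",
    "support_other",
    "t1_emotional",
    "t1_conduct",
    "t1_hyperactivity",
    "t1_peer",
    "t1_impact",
    "t2_emotional",
    "t2_conduct",
    "t2_hyperactivity",
    "t2_peer",
    "t2_impact",
]


class CohortValidationError(ValueError):
    """A row violated a typed invariant; message cites row number and value."""


@dataclass(frozen=True)
class SubscaleScores:
    """SDQ subscale sums at one timepoint.

    Problem subscales are five items scored 0/1/2 (range 0-10); the impact
    supplement is five items scored 0-3 (range 0-15).
    """

    emotional: int
    conduct: int
    hyperactivity: int
    peer: int
    impact: int

    def __post_init__(self) -> None:
        for name, (lo, hi) in SUBSCALE_RANGES.items():
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise CohortValidationError(
                    f"{name} score must be an integer, got {value!r}"
                )
            if not lo <= value <= hi:
                raise CohortValidationError(
                    f"{name} score {value} outside range {lo}-{hi}"
                )

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in SUBSCALE_RANGES}


@dataclass(frozen=True)
class ThresholdConfig:
    """Clinical cutoffs identifying the most symptomatic population band.

    A baseline score greater than or equal to the cut counts as above
    threshold (the cuts label band membership, not a strict exceedance).
    """

    conduct_cut: int = 5
    emotional_cut: int = 6
    hyperactivity_cut: int = 7

    def __post_init__(self) -> None:
        for name, cut in (
            ("conduct", self.conduct_cut),
            ("emotional", self.emotional_cut),
            ("hyperactivity", self.hyperactivity_cut),
        ):
            lo, hi = SUBSCALE_RANGES[name]
            if not lo <= cut <= hi:
                raise CohortValidationError(
                    f"{name} threshold {cut} outside subscale range {lo}-{hi}"
                )


@dataclass(frozen=True)
class StudentRecord:
    """One adolescent: T1/T2 scores, demographics, context, support flags."""

    id: str
    school_id: str
    t1: SubscaleScores
    t2: Optional[SubscaleScores]
    gender: str
    ethnicity: str
    fsm: bool
    sen: bool
    attainment: float
    school_climate: int
    quality_of_life: int
    duration: str
    support_counsellor: bool
    support_peer_mentor: bool
    support_other: bool

    def __post_init__(self) -> None:
        if self.gender not in GENDER_LEVELS:
            raise CohortValidationError(f"unknown gender label {self.gender!r}")
        if self.ethnicity not in ETHNICITY_LEVELS:
            raise CohortValidationError(
                f"unknown ethnicity label {self.ethnicity!r}"
            )
        if self.duration not in DURATION_LEVELS:
            raise CohortValidationError(
                f"unknown duration label {self.duration!r}"
            )
        lo, hi = SCHOOL_CLIMATE_RANGE
        if not lo <= self.school_climate <= hi:
            raise CohortValidationError(
                f"school_climate {self.school_climate} outside range {lo}-{hi}"
            )
        lo, hi = QUALITY_OF_LIFE_RANGE
        if not lo <= self.quality_of_life <= hi:
            raise CohortValidationError(
                f"quality_of_life {self.quality_of_life} outside range {lo}-{hi}"
            )

    @property
    def analysable(self) -> bool:
        """True iff T2 is present (all key fields are typed non-optional)."""
        return self.t2 is not None

    def drop_t2(self) -> "StudentRecord":
        return replace(self, t2=None)


def records_to_frame(records: Sequence[StudentRecord]) -> pd.DataFrame:
    """Flatten records to a DataFrame in the canonical column order."""
    rows = []
    for r in records:
        row: dict = {
            "id": r.id,
            "school_id": r.school_id,
            "gender": r.gender,
            "ethnicity": r.ethnicity,
            "fsm": int(r.fsm),
            "sen": int(r.sen),
            "attainment": r.attainment,
            "school_climate": r.school_climate,
            "quality_of_life": r.quality_of_life,
            "duration": r.duration,
            "support_counsellor": int(r.support_counsellor),
            "support_peer_mentor": int(r.support_peer_mentor),
            "support_other": int(r.support_other),
        }
        for name in SUBSCALE_RANGES:
            row[f"t1_{name}"] = getattr(r.t1, name)
        for name in SUBSCALE_RANGES:
            row[f"t2_{name}"] = getattr(r.t2, name) if r.t2 is not None else pd.NA
        rows.append(row)
    frame = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return frame


def _parse_int(value, column: str, row: int) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise CohortValidationError(
            f"row {row}: {column} value {value!r} is not numeric"
        ) from None
    if f != int(f):
        raise CohortValidationError(
            f"row {row}: {column} value {value!r} is not an integer"
        )
    return int(f)


def _with_row(exc: CohortValidationError, row_number: int) -> CohortValidationError:
    message = str(exc)
    if message.startswith("row "):
        return exc
    return CohortValidationError(f"row {row_number}: {message}")


def _record_from_row(row: pd.Series, row_number: int) -> StudentRecord:
    t2_cols = [f"t2_{name}" for name in SUBSCALE_RANGES]
    t2_vals = [row[c] for c in t2_cols]
    if all(pd.isna(v) for v in t2_vals):
        t2 = None
    elif any(pd.isna(v) for v in t2_vals):
        raise CohortValidationError(
            f"row {row_number}: partially missing T2 scores "
            "(all five must be present or all empty)"
        )
    else:
        try:
            t2 = SubscaleScores(
                **{
                    name: _parse_int(row[f"t2_{name}"], f"t2_{name}", row_number)
                    for name in SUBSCALE_RANGES
                }
            )
        except CohortValidationError as exc:
            raise _with_row(exc, row_number) from None
    try:
        t1 = SubscaleScores(
            **{
                name: _parse_int(row[f"t1_{name}"], f"t1_{name}", row_number)
                for name in SUBSCALE_RANGES
            }
        )
    except CohortValidationError as exc:
        raise _with_row(exc, row_number) from None
    try:
        return StudentRecord(
            id=str(row["id"]),
            school_id=str(row["school_id"]),
            t1=t1,
            t2=t2,
            gender=str(row["gender"]),
            ethnicity=str(row["ethnicity"]),
            fsm=bool(_parse_int(row["fsm"], "fsm", row_number)),
            sen=bool(_parse_int(row["sen"], "sen", row_number)),
            attainment=float(row["attainment"]),
            school_climate=_parse_int(
                row["school_climate"], "school_climate", row_number
            ),
            quality_of_life=_parse_int(
                row["quality_of_life"], "quality_of_life", row_number
            ),
            duration=str(row["duration"]),
            support_counsellor=bool(
                _parse_int(row["support_counsellor"], "support_counsellor", row_number)
            ),
            support_peer_mentor=bool(
                _parse_int(row["support_peer_mentor"], "support_peer_mentor", row_number)
            ),
            support_other=bool(
                _parse_int(row["support_other"], "support_other", row_number)
            ),
        )
    except CohortValidationError as exc:
        raise _with_row(exc, row_number) from None


def read_cohort(path, **csv_options) -> list[StudentRecord]:
    """Read a cohort CSV; every row becomes a :class:`StudentRecord`.

    Rows with all-empty T2 columns become non-analysable records rather than
    errors; any typed-invariant violation raises
    :class:`CohortValidationError` naming the offending row (2 = first data
    row, matching a spreadsheet view with the header on line 1).
    """
    csv_options.setdefault("float_precision", "round_trip")
    frame = pd.read_csv(path, **csv_options)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortValidationError(f"missing columns: {missing}")
    records = []
    for i, (_, row) in enumerate(frame.iterrows()):
        records.append(_record_from_row(row, i + 2))
    return records


def write_cohort(records: Sequence[StudentRecord], path) -> None:
    """Write records as UTF-8 CSV, canonical column order, empty cells for
    missing T2; ``read_cohort`` of the result reproduces the input."""
    frame = records_to_frame(records)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, encoding="utf-8")


def analysable_subset(records: Iterable[StudentRecord]) -> list[StudentRecord]:
    """Listwise deletion: exactly the records with T2 present.

    All other key fields are non-optional by construction, so eligibility
    reduces to follow-up presence.  Idempotent.
    """
    return [r for r in records if r.analysable]
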