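"""Data model and scoring arithmetic for the 11-item Brief-HINE proforma.

The Brief-HINE is a short form of the Hammersmith Infant Neurological
Examination (HINE) used to screen infants at 3, 6, 9 and 12 months for early
signs of cerebral palsy.  Each of its 11 items is recorded in one of four
optimality columns mapping to a column score of 3 (optimal, seen in >75% of
typically developing infants), 2, 1 or 0 (seen in <10%).  Some items are
examined on each body side; when the two sides land in different columns the
item score is the mean of the two column scores, so item scores live on a
half-point grid and the global score ranges from 0 to 33.

This module holds the item table, the response/exam containers with
validation, the scoring arithmetic, and the CSV interchange format used by
the rest of the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ITEM_IDS",
    "PAIRED_ITEMS",
    "AGE_RELATED_ITEMS",
    "ASSESSMENT_AGES",
    "MAX_GLOBAL_SCORE",
    "ItemDefinition",
    "ITEM_DEFINITIONS",
    "ItemResponse",
    "ExamRecord",
    "OutcomeLabel",
    "CP_SUBTYPES",
    "ValidationError",
    "score_item",
    "is_asymmetric",
    "global_score",
    "count_asymmetries",
    "exam_csv_columns",
    "exams_to_frame",
    "frame_to_exams",
    "read_exam_csv",
    "write_exam_csv",
    "outcomes_to_frame",
    "frame_to_outcomes",
    "read_outcome_csv",
    "write_outcome_csv",
]

#: Canonical item order, as they appear on the proforma.
ITEM_IDS: tuple[str, ...] = (
    "visual_response",
    "trunk_posture",
    "movement_quantity",
    "movement_quality",
    "scarf_sign",
    "hip_adductors",
    "popliteal_angle",
    "pull_to_sit",
    "lateral_tilting",
    "forward_parachute",
    "tendon_reflexes",
)

#: Items examined separately on the left and right side (limb angles and
#: lateralised postural reactions).  Configurable in principle via
#: ``ITEM_DEFINITIONS``; this default is the set with lateral responses on
#: the full HINE.
PAIRED_ITEMS: frozenset[str] = frozenset(
    {
        "scarf_sign",
        "hip_adductors",
        "popliteal_angle",
        "tendon_reflexes",
        "lateral_tilting",
        "forward_parachute",
    }
)

#: Items whose optimal response matures with age: a column score of 0-1 is
#: still typical at 3-6 months and only becomes a warning sign at 9-12 months.
AGE_RELATED_ITEMS: frozenset[str] = frozenset(
    {"trunk_posture", "lateral_tilting", "forward_parachute"}
)

ASSESSMENT_AGES: tuple[int, ...] = (3, 6, 9, 12)
VALID_COLUMN_SCORES: tuple[int, ...] = (0, 1, 2, 3)
MAX_GLOBAL_SCORE: float = 33.0

CP_SUBTYPES: tuple[str, ...] = (
    "unilateral",
    "bilateral_diplegia",
    "bilateral_quadriplegia",
)


class ValidationError(ValueError):
    """Raised when an exam, response or file fails schema validation.

    ``errors`` carries one message per individual problem so callers can
    produce an itemized validation report.
    """

    def __init__(self, errors: Sequence[str] | str):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class ItemDefinition:
    item_id: str
    paired: bool
    age_related: bool


ITEM_DEFINITIONS: Mapping[str, ItemDefinition] = {
    item: ItemDefinition(
        item_id=item,
        paired=item in PAIRED_ITEMS,
        age_related=item in AGE_RELATED_ITEMS,
    )
    for item in ITEM_IDS
}


def _check_score(value: object, item_id: str, side: str) -> int:
    if not isinstance(value, (int,)) or isinstance(value, bool):
        if isinstance(value, float) and value.is_integer():
            value = int(value)
        else:
            raise ValidationError(
                f"{item_id}: {side} score must be an integer column score, got {value!r}"
            )
    if value not in VALID_COLUMN_SCORES:
        raise ValidationError(
            f"{item_id}: {side} score {value} outside the column-score domain {{0,1,2,3}}"
        )
    return int(value)


@dataclass(frozen=True)
class ItemResponse:
    """One item's recorded column score(s); ``right_score`` only for paired items."""

    item_id: str
    left_score: int
    right_score: int | None = None

    def __post_init__(self) -> None:
        if self.item_id not in ITEM_DEFINITIONS:
            raise ValidationError(f"unknown item_id {self.item_id!r}")
        object.__setattr__(
            self, "left_score", _check_score(self.left_score, self.item_id, "left")
        )
        definition = ITEM_DEFINITIONS[self.item_id]
        if definition.paired:
            if self.right_score is None:
                raise ValidationError(
                    f"{self.item_id}: paired item requires a right-side score"
                )
            object.__setattr__(
                self,
                "right_score",
                _check_score(self.right_score, self.item_id, "right"),
            )
        elif self.right_score is not None:
            raise ValidationError(
                f"{self.item_id}: unpaired item must not carry a right-side score"
            )

    @property
    def score(self) -> float:
        return score_item(self)

    @property
    def asymmetric(self) -> bool:
        return is_asymmetric(self)


def score_item(response: ItemResponse) -> float:
    """Item score: the single column score, or the mean of left and right.

    When a paired item has asymmetrical responses in different columns the
    item contributes the arithmetic mean of the two column scores (a
    half-point when the columns differ by an odd amount); same column on both
    sides contributes that score once.
    """
    if response.right_score is None:
        return float(response.left_score)
    return (response.left_score + response.right_score) / 2.0


def is_asymmetric(response: ItemResponse) -> bool:
    """True when a paired item's left and right column scores differ."""
    return response.right_score is not None and response.left_score != response.right_score


@dataclass(frozen=True)
class ExamRecord:
    """One subject x age assessment: the 11 item responses.

    ``global_score`` (0-33, half-point grid) and ``asymmetry_count`` are
    derived from the responses.
    """

    subject_id: str
    age_months: int
    responses: tuple[ItemResponse, ...]

    def __post_init__(self) -> None:
        errors: list[str] = []
        if self.age_months not in ASSESSMENT_AGES:
            errors.append(
                f"age_months {self.age_months!r} not an assessment age {ASSESSMENT_AGES}"
            )
        object.__setattr__(self, "responses", tuple(self.responses))
        seen = [r.item_id for r in self.responses]
        duplicates = sorted({i for i in seen if seen.count(i) > 1})
        missing = sorted(set(ITEM_IDS) - set(seen))
        if duplicates:
            errors.append(f"duplicate item responses: {duplicates}")
        if missing:
            errors.append(f"missing item responses: {missing}")
        if errors:
            raise ValidationError(errors)

    def response_for(self, item_id: str) -> ItemResponse:
        for response in self.responses:
            if response.item_id == item_id:
                return response
        raise KeyError(item_id)

    @property
    def global_score(self) -> float:
        return global_score(self)

    @property
    def asymmetry_count(self) -> int:
        return count_asymmetries(self)


def global_score(exam: ExamRecord) -> float:
    """Sum of the 11 item scores; a multiple of 0.5 in [0, 33]."""
    return float(sum(score_item(r) for r in exam.responses))


def count_asymmetries(exam: ExamRecord) -> int:
    """Number of paired items whose left and right column scores differ."""
    return sum(1 for r in exam.responses if is_asymmetric(r))


@dataclass(frozen=True)
class OutcomeLabel:
    """Two-year neurodevelopmental outcome: typical, or CP with a subtype."""

    subject_id: str
    outcome: str
    cp_subtype: str | None = None

    def __post_init__(self) -> None:
        if self.outcome not in ("typical", "cp"):
            raise ValidationError(
                f"{self.subject_id}: outcome must be 'typical' or 'cp', got {self.outcome!r}"
            )
        if self.outcome == "cp":
            if self.cp_subtype not in CP_SUBTYPES:
                raise ValidationError(
                    f"{self.subject_id}: cp outcome requires a subtype in {CP_SUBTYPES}"
                )
        elif self.cp_subtype is not None:
            raise ValidationError(
                f"{self.subject_id}: typical outcome must not carry a CP subtype"
            )

    @property
    def is_cp(self) -> bool:
        return self.outcome == "cp"


# ---------------------------------------------------------------------------
# CSV interchange


def exam_csv_columns() -> list[str]:
    """Column order of the exam CSV: id, age, then items (paired split L/R)."""
    columns = ["subject_id", "age_months"]
    for item in ITEM_IDS:
        if item in PAIRED_ITEMS:
            columns.extend([f"{item}_left", f"{item}_right"])
        else:
            columns.append(item)
    return columns


def _exam_to_row(exam: ExamRecord) -> dict[str, object]:
    row: dict[str, object] = {
        "subject_id": exam.subject_id,
        "age_months": exam.age_months,
    }
    for item in ITEM_IDS:
        response = exam.response_for(item)
        if item in PAIRED_ITEMS:
            row[f"{item}_left"] = response.left_score
            row[f"{item}_right"] = response.right_score
        else:
            row[item] = response.left_score
    return row


def _row_to_exam(row: Mapping[str, object]) -> ExamRecord:
    responses = []
    for item in ITEM_IDS:
        if item in PAIRED_ITEMS:
            responses.append(
                ItemResponse(
                    item,
                    int(row[f"{item}_left"]),  # type: ignore[arg-type]
                    int(row[f"{item}_right"]),  # type: ignore[arg-type]
                )
            )
        else:
            responses.append(ItemResponse(item, int(row[item])))  # type: ignore[arg-type]
    return ExamRecord(str(row["subject_id"]), int(row["age_months"]), tuple(responses))  # type: ignore[arg-type]


def exams_to_frame(exams: Iterable[ExamRecord]) -> pd.DataFrame:
    return pd.DataFrame([_exam_to_row(e) for e in exams], columns=exam_csv_columns())


def frame_to_exams(frame: pd.DataFrame) -> list[ExamRecord]:
    missing = [c for c in exam_csv_columns() if c not in frame.columns]
    if missing:
        raise ValidationError([f"exam table missing column {c!r}" for c in missing])
    return [_row_to_exam(row) for row in frame.to_dict(orient="records")]


def write_exam_csv(exams: Iterable[ExamRecord], path: str | Path) -> None:
    exams_to_frame(exams).to_csv(path, index=False)


def read_exam_csv(path: str | Path) -> list[ExamRecord]:
    return frame_to_exams(pd.read_csv(path))


def outcomes_to_frame(outcomes: Iterable[OutcomeLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": o.subject_id,
                "outcome": o.outcome,
                "cp_subtype": o.cp_subtype if o.cp_subtype is not None else "",
            }
            for o in outcomes
        ],
        columns=["subject_id", "outcome", "cp_subtype"],
    )


def frame_to_outcomes(frame: pd.DataFrame) -> list[OutcomeLabel]:
    missing = [c for c in ("subject_id", "outcome") if c not in frame.columns]
    if missing:
        raise ValidationError([f"outcome table missing column {c!r}" for c in missing])
    outcomes = []
    for row in frame.to_dict(orient="records"):
        subtype = row.get("cp_subtype")
        if subtype is None or (isinstance(subtype, float) and math.isnan(subtype)) or subtype == "":
            subtype = None
        outcomes.append(OutcomeLabel(str(row["subject_id"]), str(row["outcome"]), subtype))
    return outcomes


def write_outcome_csv(outcomes: Iterable[OutcomeLabel], path: str | Path) -> None:
    outcomes_to_frame(outcomes).to_csv(path, index=False)


def read_outcome_csv(path: str | Path) -> list[OutcomeLabel]:
    return frame_to_outcomes(pd.read_csv(path, keep_default_na=False))
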