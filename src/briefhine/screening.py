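"""Age-specific global-score cut-off classifier for cerebral-palsy risk.

An infant screens at risk when the global Brief-HINE score falls strictly
below the age-specific threshold.  The default thresholds are the published
values (< 22 at 3 months, < 25 at 6 months, < 27 at 9 and 12 months); the
table is carried explicitly so thresholds re-estimated on local data (see
:mod:`briefhine.accuracy`) can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .proforma import ASSESSMENT_AGES, ExamRecord, ValidationError, global_score, count_asymmetries, score_item
from .warning_signs import RuleTable, WarningProfile, count_warning_signs, needs_full_exam

__all__ = [
    "AT_RISK",
    "NOT_AT_RISK",
    "DEFAULT_CUTOFFS",
    "CutoffTable",
    "classify_risk",
    "ScreeningResult",
    "screen_exam",
    "screen_cohort",
]

AT_RISK = "at_risk"
NOT_AT_RISK = "not_at_risk"

#: Published age-specific thresholds (predicted at risk iff score < threshold).
DEFAULT_CUTOFFS: Mapping[int, float] = {3: 22.0, 6: 25.0, 9: 27.0, 12: 27.0}


@dataclass(frozen=True)
class CutoffTable:
    thresholds: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))

    def __post_init__(self) -> None:
        missing = [a for a in ASSESSMENT_AGES if a not in self.thresholds]
        if missing:
            raise ValidationError(f"cut-off table missing ages: {missing}")

    def threshold_for(self, age_months: int) -> float:
        if age_months not in self.thresholds:
            raise ValidationError(f"no cut-off defined for age {age_months}")
        return float(self.thresholds[age_months])

    @classmethod
    def default(cls) -> "CutoffTable":
        return cls()


def classify_risk(
    global_score_value: float,
    age_months: int,
    table: CutoffTable | None = None,
) -> str:
    """``at_risk`` iff the global score is strictly below the age's threshold.

    The comparison is numeric, so a half-point 21.5 at 3 months is at risk
    while 22 exactly is not.
    """
    if not 0 <= global_score_value <= 33:
        raise ValidationError(f"global score {global_score_value} outside [0, 33]")
    table = table or CutoffTable.default()
    return AT_RISK if global_score_value < table.threshold_for(age_months) else NOT_AT_RISK


@dataclass(frozen=True)
class ScreeningResult:
    subject_id: str
    age_months: int
    global_score: float
    asymmetry_count: int
    risk_class: str
    warnings: WarningProfile
    needs_full_exam: bool


def screen_exam(
    exam: ExamRecord,
    table: CutoffTable | None = None,
    rules: RuleTable | None = None,
    *,
    strict_referral: bool = False,
) -> ScreeningResult:
    """Full screen of one exam: risk class, warning profile, referral flag.

    With ``strict_referral`` any single sub-optimal item (score below 3)
    also triggers referral, reading the "items that are not optimal for the
    age" clause as an independent trigger; by default referral requires
    more than one warning sign.
    """
    score = global_score(exam)
    profile = count_warning_signs(exam, rules)
    refer = needs_full_exam(profile)
    if strict_referral and not refer:
        refer = any(score_item(r) < 3 for r in exam.responses)
    return ScreeningResult(
        subject_id=exam.subject_id,
        age_months=exam.age_months,
        global_score=score,
        asymmetry_count=count_asymmetries(exam),
        risk_class=classify_risk(score, exam.age_months, table),
        warnings=profile,
        needs_full_exam=refer,
    )


def screen_cohort(
    exams: Iterable[ExamRecord],
    table: CutoffTable | None = None,
    rules: RuleTable | None = None,
    *,
    strict_referral: bool = False,
) -> pd.DataFrame:
    """Screen every exam; one row per subject x age (the CLI `score` output)."""
    rows = []
    for exam in exams:
        result = screen_exam(exam, table, rules, strict_referral=strict_referral)
        rows.append(
            {
                "subject_id": result.subject_id,
                "age_months": result.age_months,
                "global_score": result.global_score,
                "asymmetry_count": result.asymmetry_count,
                "warning_count": result.warnings.warning_count,
                "risk_class": result.risk_class,
                "needs_full_exam": result.needs_full_exam,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "age_months",
            "global_score",
            "asymmetry_count",
            "warning_count",
            "risk_class",
            "needs_full_exam",
        ],
    )
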