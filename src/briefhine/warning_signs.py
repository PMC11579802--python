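"""Age-conditional warning-sign rules for Brief-HINE item scores.

A warning sign is an item column score of 0 or 1 — a finding seen in fewer
than 10% of infants with a typical two-year outcome (outside the 90th
centile of the typical-cohort score distribution).  Three items whose
optimal response matures with age (trunk posture, lateral tilting, forward
parachute) are exempt at 3 and 6 months, where low scores are still common
in typically developing infants; for those items scores of 0-1 count as
warning signs only at 9 and 12 months.

More than one warning sign on a screen triggers referral for the full
26-item examination.

Besides the fixed rule table this module provides the data-driven
re-derivation of the rule from a typical cohort (the 90th-centile
tabulation), so the default table can be checked against, or replaced by,
local normative data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .proforma import (
    AGE_RELATED_ITEMS,
    ASSESSMENT_AGES,
    ITEM_IDS,
    ExamRecord,
    ValidationError,
    score_item,
)

__all__ = [
    "WarningProfile",
    "DEFAULT_WARNING_RULES",
    "build_default_rules",
    "is_warning_sign",
    "count_warning_signs",
    "needs_full_exam",
    "derive_warning_scores",
    "rules_to_json",
    "rules_from_json",
]

#: item_id -> age_months -> frozenset of flagged column scores.
RuleTable = Mapping[str, Mapping[int, frozenset[int]]]


def build_default_rules() -> dict[str, dict[int, frozenset[int]]]:
    """The published rule: {0,1} flagged at all ages except the three
    age-related items, which are exempt at 3 and 6 months."""
    rules: dict[str, dict[int, frozenset[int]]] = {}
    for item in ITEM_IDS:
        rules[item] = {}
        for age in ASSESSMENT_AGES:
            if item in AGE_RELATED_ITEMS and age in (3, 6):
                rules[item][age] = frozenset()
            else:
                rules[item][age] = frozenset({0, 1})
    return rules


DEFAULT_WARNING_RULES: RuleTable = build_default_rules()


@dataclass(frozen=True)
class WarningProfile:
    subject_id: str
    age_months: int
    warning_count: int
    flagged_items: tuple[str, ...]


def is_warning_sign(
    item_id: str,
    score: float,
    age_months: int,
    rules: RuleTable | None = None,
    *,
    flag_half_scores: bool = False,
) -> bool:
    """Whether an (effective) item score is a warning sign at this age.

    Asymmetry averaging can yield half-point scores.  By default only
    scores of 0, 0.5 or 1 are flagged — an averaged 1.5 sits above the
    flagged columns and is not counted.  With ``flag_half_scores`` a 1.5 is
    flagged whenever column score 1 is flagged (the score's integer part is
    looked up instead).
    """
    if item_id not in DEFAULT_WARNING_RULES:
        raise ValidationError(f"unknown item_id {item_id!r}")
    if age_months not in ASSESSMENT_AGES:
        raise ValidationError(f"age_months {age_months!r} not in {ASSESSMENT_AGES}")
    if not 0 <= score <= 3:
        raise ValidationError(f"{item_id}: score {score} outside [0, 3]")
    table = DEFAULT_WARNING_RULES if rules is None else rules
    flagged = table[item_id][age_months]
    if not flagged:
        return False
    if flag_half_scores:
        return int(math.floor(score)) in flagged
    return score <= max(flagged) and int(math.floor(score)) in flagged


def count_warning_signs(
    exam: ExamRecord,
    rules: RuleTable | None = None,
    *,
    flag_half_scores: bool = False,
) -> WarningProfile:
    """Apply the warning rule to each item of an exam."""
    flagged = tuple(
        r.item_id
        for r in exam.responses
        if is_warning_sign(
            r.item_id,
            score_item(r),
            exam.age_months,
            rules,
            flag_half_scores=flag_half_scores,
        )
    )
    return WarningProfile(exam.subject_id, exam.age_months, len(flagged), flagged)


def needs_full_exam(profile: WarningProfile) -> bool:
    """Referral rule: more than one warning sign on the screen."""
    return profile.warning_count > 1


def derive_warning_scores(
    typical_cohort: Sequence[ExamRecord],
    age_months: int,
    *,
    centile: float = 0.10,
) -> dict[str, set[int]]:
    """Re-derive the flagged scores from a typical cohort at one age.

    For each item, column score ``s`` is flagged when the cumulative
    relative frequency of item scores at or below ``s`` in the cohort is
    strictly below ``centile`` — i.e. the score lies outside the 90th
    centile of the typical-outcome distribution.  Because the cumulative
    frequency is monotone the flagged set is always of the form {0..k}.
    """
    if not typical_cohort:
        raise ValidationError("derive_warning_scores requires a non-empty cohort")
    wrong_age = [e.subject_id for e in typical_cohort if e.age_months != age_months]
    if wrong_age:
        raise ValidationError(
            f"cohort contains exams not at {age_months} months: {sorted(set(wrong_age))[:5]}"
        )
    n = len(typical_cohort)
    flagged: dict[str, set[int]] = {}
    for item in ITEM_IDS:
        scores = [score_item(e.response_for(item)) for e in typical_cohort]
        flagged[item] = {
            s for s in (0, 1, 2, 3) if sum(x <= s for x in scores) / n < centile
        }
    return flagged


# ---------------------------------------------------------------------------
# JSON interchange (clinic override of the rule table)


def rules_to_json(rules: RuleTable, path: str | Path | None = None) -> str:
    payload = {
        item: {str(age): sorted(scores) for age, scores in by_age.items()}
        for item, by_age in rules.items()
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def rules_from_json(source: str | Path) -> dict[str, dict[int, frozenset[int]]]:
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and source.endswith(".json")):
        text = Path(source).read_text()
    else:
        text = str(source)
    payload = json.loads(text)
    rules: dict[str, dict[int, frozenset[int]]] = {}
    for item, by_age in payload.items():
        if item not in ITEM_IDS:
            raise ValidationError(f"unknown item_id {item!r} in rule table")
        rules[item] = {int(age): frozenset(int(s) for s in scores) for age, scores in by_age.items()}
    missing = sorted(set(ITEM_IDS) - set(rules))
    if missing:
        raise ValidationError(f"rule table missing items: {missing}")
    return rules
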