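"""Study pipeline: score a cohort, derive cut-offs, render summary tables.

``run_study`` reproduces the published analysis layout on any labeled
cohort (real-format CSVs or a simulated study): per-age global-score
summaries by outcome group, per-age Liu cut-offs with accuracy metrics and
bootstrap CIs, warning-sign prevalence tables, and asymmetry-count
summaries by CP subtype.  Ages are analysed independently, as in the
source analysis, even though the data are longitudinal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .accuracy import CutoffResult, LabeledScores, liu_cutpoint, round_half_up
from .proforma import (
    ASSESSMENT_AGES,
    ExamRecord,
    OutcomeLabel,
    ValidationError,
    count_asymmetries,
    global_score,
    read_exam_csv,
    read_outcome_csv,
)
from .screening import CutoffTable
from .warning_signs import RuleTable, count_warning_signs, rules_from_json

logger = logging.getLogger("briefhine")

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "warning_prevalence",
    "render_report",
    "format_summary",
]


@dataclass(frozen=True)
class StudyConfig:
    """Analysis configuration (a single JSON document on disk).

    ``integer_grid`` restricts candidate cut-offs to whole scores, matching
    the published integer thresholds; set it to False to search the
    empirical half-point grid.
    """

    seed: int = 0
    bootstrap_n: int = 1000
    integer_grid: bool = True
    ci_level: float = 0.95
    warning_ks: tuple[int, ...] = (1, 2, 3, 4)
    cutoff_table: Mapping[int, float] | None = None
    warning_rules: RuleTable | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        payload = json.loads(Path(path).read_text())
        rules = payload.pop("warning_rules", None)
        if rules is not None:
            rules = rules_from_json(json.dumps(rules))
        cutoffs = payload.pop("cutoff_table", None)
        if cutoffs is not None:
            cutoffs = {int(k): float(v) for k, v in cutoffs.items()}
        known = {"seed", "bootstrap_n", "integer_grid", "ci_level", "warning_ks"}
        unknown = set(payload) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "warning_ks" in payload:
            payload["warning_ks"] = tuple(int(k) for k in payload["warning_ks"])
        return cls(cutoff_table=cutoffs, warning_rules=rules, **payload)


@dataclass
class StudyReport:
    """All derived tables for one cohort."""

    score_summaries: pd.DataFrame  # group x age: n, mean, sd, min, max
    cutoffs: dict[int, CutoffResult | None]  # age -> result (None: not estimable)
    warning_prevalence: pd.DataFrame  # group x age x k: % with count > k
    asymmetry_summaries: pd.DataFrame  # subtype x age: median/quartiles/range
    n_subjects: int
    group_sizes: dict[str, int]


def _group_of(label: OutcomeLabel) -> str:
    if label.outcome == "typical":
        return "typical"
    return {
        "unilateral": "cp_unilateral",
        "bilateral_diplegia": "cp_diplegia",
        "bilateral_quadriplegia": "cp_quadriplegia",
    }[label.cp_subtype]  # type: ignore[index]


def _validate_cohort(
    exams: Sequence[ExamRecord], outcomes: Sequence[OutcomeLabel]
) -> dict[str, OutcomeLabel]:
    errors: list[str] = []
    by_subject: dict[str, OutcomeLabel] = {}
    for label in outcomes:
        if label.subject_id in by_subject:
            errors.append(f"duplicate outcome label for subject {label.subject_id}")
        by_subject[label.subject_id] = label
    seen: set[tuple[str, int]] = set()
    for exam in exams:
        key = (exam.subject_id, exam.age_months)
        if key in seen:
            errors.append(f"duplicate exam for subject {key[0]} at {key[1]} months")
        seen.add(key)
        if exam.subject_id not in by_subject:
            errors.append(f"exam subject {exam.subject_id} has no outcome label")
    if errors:
        raise ValidationError(errors)
    return by_subject


def warning_prevalence(
    profiles: pd.DataFrame, ks: Sequence[int] = (1, 2, 3, 4)
) -> pd.DataFrame:
    """Percent of each group x age with more than k warning signs.

    ``profiles`` needs columns group, age_months, warning_count.  Empty
    group x age cells yield NaN percentages (undefined, flagged rather than
    silently zero).  For a fixed group and age the percentage is
    non-increasing in k.
    """
    rows = []
    for (group, age), chunk in profiles.groupby(["group", "age_months"], sort=True):
        n = len(chunk)
        for k in ks:
            pct = float("nan") if n == 0 else 100.0 * (chunk["warning_count"] > k).mean()
            rows.append({"group": group, "age_months": age, "k": k, "pct_gt_k": pct, "n": n})
    return pd.DataFrame(rows, columns=["group", "age_months", "k", "pct_gt_k", "n"])


def run_study(
    exams: Sequence[ExamRecord] | str | Path,
    outcomes: Sequence[OutcomeLabel] | str | Path,
    config: StudyConfig | None = None,
) -> StudyReport:
    """Run the full per-age analysis on a labeled cohort.

    Deterministic: the same inputs and config (including the bootstrap
    seed) always produce the same report.  When the cohort contains only
    one outcome class the cut-off stage reports None ("not estimable") and
    the descriptive tables are still produced.
    """
    config = config or StudyConfig()
    if isinstance(exams, (str, Path)):
        exams = read_exam_csv(exams)
    if isinstance(outcomes, (str, Path)):
        outcomes = read_outcome_csv(outcomes)
    label_of = _validate_cohort(exams, outcomes)
    logger.info("validated cohort: %d exams, %d subjects", len(exams), len(label_of))

    records = pd.DataFrame(
        {
            "subject_id": [e.subject_id for e in exams],
            "age_months": [e.age_months for e in exams],
            "global_score": [global_score(e) for e in exams],
            "asymmetry_count": [count_asymmetries(e) for e in exams],
            "warning_count": [
                count_warning_signs(e, config.warning_rules).warning_count for e in exams
            ],
        }
    )
    records["group"] = [_group_of(label_of[s]) for s in records["subject_id"]]
    records["is_cp"] = [label_of[s].is_cp for s in records["subject_id"]]
    logger.info("scored %d exams", len(records))

    summaries = (
        records.groupby(["group", "age_months"])["global_score"]
        .agg(n="size", mean="mean", sd="std", min="min", max="max")
        .reset_index()
    )
    # whole-CP rows alongside the subtypes, as the published table prints both
    cp = records[records["is_cp"]]
    if len(cp):
        cp_rows = (
            cp.groupby("age_months")["global_score"]
            .agg(n="size", mean="mean", sd="std", min="min", max="max")
            .reset_index()
        )
        cp_rows.insert(0, "group", "cp_all")
        summaries = pd.concat([summaries, cp_rows], ignore_index=True)
    logger.info("score summaries: %d group x age cells", len(summaries))

    cutoffs: dict[int, CutoffResult | None] = {}
    ages = sorted(int(a) for a in records["age_months"].unique())
    for i, age in enumerate(ages):
        chunk = records[records["age_months"] == age]
        if chunk["is_cp"].nunique() < 2:
            cutoffs[age] = None
            logger.info("age %dm: cut-off not estimable (single-class cohort)", age)
            continue
        data = LabeledScores(
            chunk["global_score"].to_numpy(),
            chunk["is_cp"].to_numpy(),
            age_months=int(age),
        )
        cutoffs[age] = liu_cutpoint(
            data,
            integer_grid=config.integer_grid,
            ci_bootstrap=config.bootstrap_n,
            seed=config.seed + i,
            level=config.ci_level,
        )
        logger.info(
            "age %dm: cut-off %s (sens %.2f, spec %.2f)",
            age,
            cutoffs[age].threshold,
            cutoffs[age].sensitivity,
            cutoffs[age].specificity,
        )

    prevalence = warning_prevalence(records, config.warning_ks)

    asym = records[records["group"].str.startswith("cp_")]
    asym_summaries = (
        asym.groupby(["group", "age_months"])["asymmetry_count"]
        .agg(
            n="size",
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
            min="min",
            max="max",
        )
        .reset_index()
        if len(asym)
        else pd.DataFrame(
            columns=["group", "age_months", "n", "median", "q25", "q75", "min", "max"]
        )
    )

    group_sizes = (
        pd.Series({s: _group_of(l) for s, l in label_of.items()}).value_counts().to_dict()
    )
    return StudyReport(
        score_summaries=summaries,
        cutoffs=cutoffs,
        warning_prevalence=prevalence,
        asymmetry_summaries=asym_summaries,
        n_subjects=len(label_of),
        group_sizes={k: int(v) for k, v in group_sizes.items()},
    )


# ---------------------------------------------------------------------------
# Rendering


def _fmt(value: float) -> str:
    """Trim a display number: integers bare, otherwise one decimal (half-up)."""
    rounded = round_half_up(float(value), 1)
    if rounded == int(rounded):
        return str(int(rounded))
    return f"{rounded:.1f}"


def format_summary(mean: float, sd: float, lo: float, hi: float) -> str:
    """"mean (SD; min-max)" string in the published table style, e.g.
    ``23 (2.2; 18–30)``."""
    return f"{_fmt(mean)} ({_fmt(sd)}; {_fmt(lo)}–{_fmt(hi)})"


def _fmt2(value: float | None) -> str:
    if value is None:
        return "NA"
    rounded = round_half_up(float(value), 2)
    if rounded == int(rounded):
        return str(int(rounded))
    return f"{rounded:g}"


def _cutoff_rows(report: StudyReport) -> pd.DataFrame:
    rows = []
    for age, result in sorted(report.cutoffs.items()):
        if result is None:
            rows.append({"age_months": age, "cutoff": "not estimable"})
            continue
        row = {
            "age_months": age,
            "cutoff": result.threshold,
            "sensitivity": result.sensitivity,
            "specificity": result.specificity,
            "ppv": result.ppv,
            "npv": result.npv,
            "accuracy": result.accuracy,
            "auc": result.auc,
            "degenerate": result.degenerate,
        }
        if result.cis:
            for name, (low, high) in result.cis.items():
                row[f"{name}_ci_low"] = low
                row[f"{name}_ci_high"] = high
        rows.append(row)
    return pd.DataFrame(rows)


def render_report(
    report: StudyReport,
    out_dir: str | Path,
    formats: Sequence[str] = ("csv", "json", "markdown"),
) -> list[Path]:
    """Write the report tables; returns the paths written.

    CSV: one file per table.  JSON: a single document.  Markdown: a
    human-readable summary with published-style formatting (metrics to two
    decimals, summaries as "mean (SD; range)").
    """
    unknown = set(formats) - {"csv", "json", "markdown"}
    if unknown:
        raise ValidationError(f"unknown report format(s): {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    cutoff_frame = _cutoff_rows(report)

    if "csv" in formats:
        tables = {
            "score_summaries.csv": report.score_summaries,
            "cutoffs.csv": cutoff_frame,
            "warning_prevalence.csv": report.warning_prevalence,
            "asymmetry_summaries.csv": report.asymmetry_summaries,
        }
        for name, frame in tables.items():
            path = out / name
            frame.to_csv(path, index=False)
            written.append(path)

    if "json" in formats:
        payload = {
            "n_subjects": report.n_subjects,
            "group_sizes": report.group_sizes,
            "score_summaries": report.score_summaries.to_dict(orient="records"),
            "cutoffs": cutoff_frame.to_dict(orient="records"),
            "warning_prevalence": report.warning_prevalence.to_dict(orient="records"),
            "asymmetry_summaries": report.asymmetry_summaries.to_dict(orient="records"),
        }
        path = out / "report.json"
        path.write_text(json.dumps(payload, indent=2, allow_nan=True))
        written.append(path)

    if "markdown" in formats:
        written.append(_write_markdown(report, cutoff_frame, out / "report.md"))
    return written


def _write_markdown(
    report: StudyReport, cutoff_frame: pd.DataFrame, path: Path
) -> Path:
    lines = ["# Brief-HINE study report", ""]
    lines.append(f"Subjects: {report.n_subjects} ({report.group_sizes})")
    lines.append("")
    lines.append("## Global scores by group and age")
    lines.append("")
    lines.append("| group | age (months) | n | score, mean (SD; range) |")
    lines.append("|---|---|---|---|")
    for row in report.score_summaries.itertuples():
        sd = 0.0 if pd.isna(row.sd) else row.sd
        lines.append(
            f"| {row.group} | {row.age_months} | {row.n} | "
            f"{format_summary(row.mean, sd, row.min, row.max)} |"
        )
    lines.append("")
    lines.append("## Cut-off scores by age")
    lines.append("")
    lines.append("| age (months) | cut-off | sens–spec | PPV–NPV–ACC | AUC |")
    lines.append("|---|---|---|---|---|")
    for age, result in sorted(report.cutoffs.items()):
        if result is None:
            lines.append(f"| {age} | not estimable | | | |")
            continue
        lines.append(
            f"| {age} | {_fmt(result.threshold)} "
            f"| {_fmt2(result.sensitivity)}–{_fmt2(result.specificity)} "
            f"| {_fmt2(result.ppv)}–{_fmt2(result.npv)}–{_fmt2(result.accuracy)} "
            f"| {_fmt2(result.auc)} |"
        )
    lines.append("")
    lines.append("## Warning-sign prevalence (% with more than k signs)")
    lines.append("")
    lines.append("| group | age (months) | k | % | n |")
    lines.append("|---|---|---|---|---|")
    for row in report.warning_prevalence.itertuples():
        pct = "NA" if pd.isna(row.pct_gt_k) else _fmt2(row.pct_gt_k)
        lines.append(f"| {row.group} | {row.age_months} | {row.k} | {pct} | {row.n} |")
    lines.append("")
    path.write_text("\n".join(lines))
    return path
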