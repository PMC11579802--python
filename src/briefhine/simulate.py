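"""Synthetic longitudinal cohorts with the published score structure.

No patient-level Brief-HINE data are deposited, so validation of the
analysis pipeline runs on simulated cohorts whose *global-score* marginals
(mean, SD, range per outcome group and age) and *asymmetry-count* profiles
(median/range per CP subtype) are calibrated to the published summary
statistics, and whose composition matches the study cohort: 228 infants
with a typical two-year outcome and 82 who developed cerebral palsy
(40 unilateral, 17 bilateral diplegia, 25 bilateral quadriplegia), each
examined at 3, 6, 9 and 12 months.

Model choices (summary statistics under-determine the data):

* Global scores are truncated normal on the published [min, max] with the
  published mean/SD, rounded to the half-point grid.  Subtype rows publish
  no SD; it defaults to range/4.
* A subject's scores rise with age the way the group means do: a Gaussian
  copula with correlation rho (default 0.8) shares a latent quantile across
  the four ages.
* Asymmetry counts are truncated geometric on the published [min, max],
  fitted so the distribution's median equals the published median.  The
  typical cohort gets a single-asymmetry exam at the published frequency of
  10/228 (never more than one).
* Item-level score allocation is illustrative: it reproduces the target
  global score and asymmetry count exactly, and depresses the three
  age-related items for typical infants at 3-6 months (where low scores are
  still typical), but the per-item distributions are not calibrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm, truncnorm

from .proforma import (
    AGE_RELATED_ITEMS,
    ASSESSMENT_AGES,
    ITEM_IDS,
    PAIRED_ITEMS,
    ExamRecord,
    ItemResponse,
    OutcomeLabel,
    ValidationError,
)

__all__ = [
    "GROUPS",
    "GroupScoreSpec",
    "AsymmetrySpec",
    "StudyDesign",
    "TYPICAL_ASYMMETRY_RATE",
    "AllocationError",
    "default_score_specs",
    "default_asymmetry_specs",
    "default_specs",
    "truncated_normal",
    "truncated_normal_moments",
    "sample_global_scores",
    "fit_truncated_geometric",
    "sample_asymmetry_count",
    "allocate_items",
    "simulate_study",
]

GROUPS: tuple[str, ...] = ("typical", "cp_unilateral", "cp_diplegia", "cp_quadriplegia")

#: Published frequency of single-asymmetry exams in the typical cohort.
TYPICAL_ASYMMETRY_RATE: float = 10 / 228


@dataclass(frozen=True)
class GroupScoreSpec:
    """Truncated global-score distribution for one group at one age."""

    group: str
    age_months: int
    mean: float
    sd: float
    min_score: float
    max_score: float

    def __post_init__(self) -> None:
        if not (0 <= self.min_score <= self.mean <= self.max_score <= 33):
            raise ValidationError(
                f"{self.group}/{self.age_months}m: need 0 <= min <= mean <= max <= 33"
            )
        if self.sd <= 0:
            raise ValidationError(f"{self.group}/{self.age_months}m: sd must be > 0")


@dataclass(frozen=True)
class AsymmetrySpec:
    """Per-exam asymmetry-count distribution for one group at one age."""

    group: str
    age_months: int
    median: int
    min_count: int
    max_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.min_count <= self.median <= self.max_count <= 11):
            raise ValidationError(
                f"{self.group}/{self.age_months}m: need 0 <= min <= median <= max <= 11"
            )


@dataclass(frozen=True)
class StudyDesign:
    """Cohort composition and simulation controls; defaults match the study."""

    n_typical: int = 228
    n_unilateral: int = 40
    n_diplegia: int = 17
    n_quadriplegia: int = 25
    ages: tuple[int, ...] = ASSESSMENT_AGES
    seed: int = 0
    rho: float = 0.8

    def __post_init__(self) -> None:
        for name in ("n_typical", "n_unilateral", "n_diplegia", "n_quadriplegia"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.rho <= 1.0:
            raise ValidationError("rho must lie in [0, 1]")
        bad = [a for a in self.ages if a not in ASSESSMENT_AGES]
        if bad:
            raise ValidationError(f"unsupported ages: {bad}")

    @property
    def group_sizes(self) -> dict[str, int]:
        return {
            "typical": self.n_typical,
            "cp_unilateral": self.n_unilateral,
            "cp_diplegia": self.n_diplegia,
            "cp_quadriplegia": self.n_quadriplegia,
        }


# Published global-score summaries (Brief-HINE scale): (mean, sd, min, max);
# sd None where the source publishes none (subtype rows) -> defaults to range/4.
_SCORE_TABLE: dict[tuple[str, int], tuple[float, float | None, float, float]] = {
    ("typical", 3): (23.0, 2.2, 18.0, 30.0),
    ("typical", 6): (28.0, 1.9, 22.0, 32.0),
    ("typical", 9): (30.0, 2.2, 20.0, 33.0),
    ("typical", 12): (31.0, 1.6, 27.0, 33.0),
    ("cp_unilateral", 3): (16.5, None, 10.0, 24.0),
    ("cp_unilateral", 6): (21.0, None, 13.0, 30.0),
    ("cp_unilateral", 9): (25.5, None, 18.0, 28.0),
    ("cp_unilateral", 12): (25.0, None, 19.0, 30.0),
    ("cp_diplegia", 3): (14.5, None, 6.0, 23.0),
    ("cp_diplegia", 6): (20.0, None, 11.0, 26.0),
    ("cp_diplegia", 9): (22.0, None, 14.0, 27.0),
    ("cp_diplegia", 12): (24.5, None, 21.0, 33.0),
    ("cp_quadriplegia", 3): (13.5, None, 3.0, 18.0),
    ("cp_quadriplegia", 6): (12.5, None, 6.0, 21.0),
    ("cp_quadriplegia", 9): (11.0, None, 6.0, 21.0),
    ("cp_quadriplegia", 12): (12.5, None, 10.0, 21.0),
}

# Published asymmetry-count summaries: (median, min, max).  Unilateral CP has
# median 1 at 3-6 months and 2 at 9-12 months over a 0-6 range; both bilateral
# subtypes have median 0 at every age.  The typical cohort is handled by the
# 10/228 single-asymmetry rule rather than a spec.
_ASYMMETRY_TABLE: dict[tuple[str, int], tuple[int, int, int]] = {
    **{("cp_unilateral", a): (1, 0, 6) for a in (3, 6)},
    **{("cp_unilateral", a): (2, 0, 6) for a in (9, 12)},
    **{("cp_diplegia", a): (0, 0, 2) for a in ASSESSMENT_AGES},
    **{("cp_quadriplegia", a): (0, 0, 3) for a in ASSESSMENT_AGES},
}


def default_score_specs() -> dict[tuple[str, int], GroupScoreSpec]:
    specs = {}
    for (group, age), (mean, sd, lo, hi) in _SCORE_TABLE.items():
        if sd is None:
            sd = (hi - lo) / 4.0
        specs[(group, age)] = GroupScoreSpec(group, age, mean, sd, lo, hi)
    return specs


def default_asymmetry_specs() -> dict[tuple[str, int], AsymmetrySpec]:
    return {
        (group, age): AsymmetrySpec(group, age, med, lo, hi)
        for (group, age), (med, lo, hi) in _ASYMMETRY_TABLE.items()
    }


def default_specs() -> tuple[dict[tuple[str, int], GroupScoreSpec], dict[tuple[str, int], AsymmetrySpec]]:
    return default_score_specs(), default_asymmetry_specs()


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Global-score sampling


def truncated_normal(spec: GroupScoreSpec):
    """Frozen scipy truncated-normal distribution for a score spec."""
    a = (spec.min_score - spec.mean) / spec.sd
    b = (spec.max_score - spec.mean) / spec.sd
    return truncnorm(a, b, loc=spec.mean, scale=spec.sd)


def truncated_normal_moments(spec: GroupScoreSpec) -> tuple[float, float]:
    """Analytic mean and SD of the (unrounded) truncated normal."""
    mean, var = truncated_normal(spec).stats(moments="mv")
    return float(mean), float(math.sqrt(var))


def _round_half_grid(values: np.ndarray) -> np.ndarray:
    return np.round(values * 2.0) / 2.0


def sample_global_scores(
    spec: GroupScoreSpec, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw global scores: truncated normal, rounded to the 0.5 grid."""
    if n <= 0:
        raise ValidationError("n must be positive")
    rng = _rng(seed)
    draws = truncated_normal(spec).rvs(size=n, random_state=rng)
    return np.clip(_round_half_grid(draws), spec.min_score, spec.max_score)


# ---------------------------------------------------------------------------
# Asymmetry-count sampling


def fit_truncated_geometric(median: int, lo: int, hi: int) -> np.ndarray:
    """pmf over {lo..hi} proportional to q**k, with q chosen so the
    distribution's median is the requested one.

    q is solved by bisection so that the truncated CDF at the median is 0.6
    — comfortably above 1/2, while the CDF one step below stays under 1/2 —
    which pins the median at the requested value and keeps the empirical
    median of large samples stable.
    """
    if not lo <= median <= hi:
        raise ValidationError("need lo <= median <= hi")
    support = np.arange(lo, hi + 1)
    if lo == hi:
        return np.ones(1)

    def cdf_at_median(q: float) -> float:
        weights = q ** (support - lo)
        return float(weights[: median - lo + 1].sum() / weights.sum())

    target = 0.6
    if median == hi:
        # any q with enough mass at the top; flatten toward uniform
        return np.ones(support.size) / support.size
    q_lo, q_hi = 1e-9, 1.0 - 1e-9
    if cdf_at_median(q_hi) >= target:
        q = q_hi
    else:
        for _ in range(200):
            mid = 0.5 * (q_lo + q_hi)
            if cdf_at_median(mid) >= target:
                q_lo = mid
            else:
                q_hi = mid
        q = q_lo
    weights = q ** (support - lo)
    return weights / weights.sum()


def sample_asymmetry_count(
    spec: AsymmetrySpec,
    n: int = 1,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw per-exam asymmetry counts from the fitted truncated geometric."""
    rng = _rng(seed)
    support = np.arange(spec.min_count, spec.max_count + 1)
    pmf = fit_truncated_geometric(spec.median, spec.min_count, spec.max_count)
    return rng.choice(support, size=n, p=pmf)


# ---------------------------------------------------------------------------
# Item-level allocation


class AllocationError(ValidationError):
    """Raised when no item allocation satisfies the requested constraints."""


_PAIRED_ORDER = tuple(i for i in ITEM_IDS if i in PAIRED_ITEMS)

#: Chance a non-age-related item drops to column 2 in a typical 3-6 month
#: exam before the age-related items absorb the remaining deficit; keeps the
#: simulated typical cohort consistent with the column-2 definition
#: (findings observed in more than 10% of typically developing infants).
_COLUMN2_RATE = 0.15

# Side realizations for asymmetric effective scores.  Even differences give
# integer means; only (0,1)/(1,2)/(2,3)/(0,3) give half-point means.
_INTEGER_ASYM_SIDES: dict[float, tuple[tuple[int, int], ...]] = {
    1.0: ((0, 2),),
    2.0: ((1, 3),),
}
_HALF_ASYM_SIDES: dict[float, tuple[tuple[int, int], ...]] = {
    0.5: ((0, 1),),
    1.5: ((0, 3), (1, 2)),
    2.5: ((2, 3),),
}


def feasible_sum_range(asymmetry_target: int, half_grid: bool) -> tuple[float, float]:
    """Attainable [min, max] of the global score given the asymmetry count.

    Asymmetric items cannot score 0 or 3 (their sides differ), which
    shrinks the attainable range; a half-point total additionally needs one
    asymmetric item whose sides differ by an odd amount.
    """
    if asymmetry_target == 0:
        return 0.0, 33.0
    n_sym = len(ITEM_IDS) - asymmetry_target
    if half_grid:
        lo = 0.5 + (asymmetry_target - 1) * 1.0
        hi = 3.0 * n_sym + 2.0 * (asymmetry_target - 1) + 2.5
    else:
        lo = 1.0 * asymmetry_target
        hi = 3.0 * n_sym + 2.0 * asymmetry_target
    return lo, hi


def allocate_items(
    target_global_score: float,
    group: str,
    age_months: int,
    asymmetry_target: int = 0,
    seed: int | np.random.Generator | None = None,
) -> tuple[ItemResponse, ...]:
    """Build 11 item responses with the requested global score and asymmetry.

    The item scores start at their maxima and the deficit from 33 is
    drained one unit at a time.  For typical infants at 3 and 6 months the
    three age-related items are drained first, one item fully to zero
    before the next (in seeded random order): low scores on those items are
    themselves typical at these ages, and this keeps their zero/one
    frequencies high enough that a 90th-centile tabulation of the simulated
    cohort exempts them, as the published rule does.  The remaining deficit
    is spread round-robin so no item drops far below the others.

    Raises :class:`AllocationError` when the target sum is unattainable for
    the requested asymmetry count.  A half-point target with zero
    asymmetries is rounded to the nearest whole point (half-points can only
    arise from asymmetry averaging).
    """
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}")
    if age_months not in ASSESSMENT_AGES:
        raise ValidationError(f"age_months {age_months!r} not in {ASSESSMENT_AGES}")
    if not 0 <= target_global_score <= 33:
        raise AllocationError(f"target {target_global_score} outside [0, 33]")
    if not 0 <= asymmetry_target <= len(_PAIRED_ORDER):
        raise AllocationError(
            f"asymmetry target {asymmetry_target} outside [0, {len(_PAIRED_ORDER)}]"
        )
    rng = _rng(seed)

    target = round(target_global_score * 2.0) / 2.0
    half_grid = (round(target * 2.0) % 2) == 1
    if asymmetry_target == 0 and half_grid:
        target = float(math.floor(target + 0.5))
        half_grid = False
    lo_sum, hi_sum = feasible_sum_range(asymmetry_target, half_grid)
    if not lo_sum <= target <= hi_sum:
        raise AllocationError(
            f"target {target} unattainable with {asymmetry_target} asymmetries "
            f"(attainable range [{lo_sum}, {hi_sum}])"
        )

    asym_items = list(rng.choice(_PAIRED_ORDER, size=asymmetry_target, replace=False))
    carrier = asym_items[0] if (half_grid and asym_items) else None

    # per-item effective-score bounds (step size 1 everywhere)
    bounds: dict[str, tuple[float, float]] = {}
    for item in ITEM_IDS:
        if item == carrier:
            bounds[item] = (0.5, 2.5)
        elif item in asym_items:
            bounds[item] = (1.0, 2.0)
        else:
            bounds[item] = (0.0, 3.0)

    scores = {item: bounds[item][1] for item in ITEM_IDS}
    deficit = int(round(sum(scores.values()) - target))

    if group == "typical" and age_months in (3, 6):
        # Column 2 is by definition seen in >10% of typical infants, so a
        # slice of the deficit lands there before the age-related items
        # absorb the rest.
        candidates = [i for i in ITEM_IDS if i not in AGE_RELATED_ITEMS]
        for item in rng.permutation(candidates):
            if deficit > 0 and rng.random() < _COLUMN2_RATE and scores[item] == 3.0:
                scores[item] = 2.0
                deficit -= 1
        for item in rng.permutation(sorted(AGE_RELATED_ITEMS)):
            while deficit > 0 and scores[item] - 1.0 >= bounds[item][0]:
                scores[item] -= 1.0
                deficit -= 1

    order = list(rng.permutation(ITEM_IDS))
    while deficit > 0:
        progressed = False
        for item in order:
            if deficit == 0:
                break
            if scores[item] - 1.0 >= bounds[item][0]:
                scores[item] -= 1.0
                deficit -= 1
                progressed = True
        if not progressed:  # pragma: no cover - excluded by the bounds check
            raise AllocationError("allocation stalled; infeasible constraints")

    responses = []
    for item in ITEM_IDS:
        value = scores[item]
        if item not in PAIRED_ITEMS:
            responses.append(ItemResponse(item, int(value)))
        elif item not in asym_items:
            responses.append(ItemResponse(item, int(value), int(value)))
        else:
            sides_table = _HALF_ASYM_SIDES if item == carrier else _INTEGER_ASYM_SIDES
            options = sides_table[value]
            a, b = options[int(rng.integers(len(options)))]
            if rng.integers(2):
                a, b = b, a
            responses.append(ItemResponse(item, a, b))
    return tuple(responses)


# ---------------------------------------------------------------------------
# Full-study simulation


def _clamp_to_feasible(target: float, asymmetry_target: int) -> float:
    half_grid = (round(target * 2.0) % 2) == 1 and asymmetry_target > 0
    lo, hi = feasible_sum_range(asymmetry_target, half_grid)
    return float(min(max(target, lo), hi))


def simulate_study(
    design: StudyDesign | None = None,
    specs: tuple[Mapping[tuple[str, int], GroupScoreSpec], Mapping[tuple[str, int], AsymmetrySpec]] | None = None,
) -> tuple[list[ExamRecord], list[OutcomeLabel]]:
    """Simulate the full longitudinal study: every subject at every age.

    A per-subject latent standard-normal draw is shared across ages through
    a Gaussian copula (correlation ``design.rho``), so the per-age
    truncated-normal marginals are exact while individual trajectories rise
    with age.  Asymmetry counts are drawn independently per exam from the
    subtype specs (typical exams: a single asymmetry with probability
    10/228).  Item responses realizing each (score, asymmetry) pair come
    from :func:`allocate_items`; in the rare case the sampled pair is
    jointly infeasible the score is moved to the nearest attainable value.
    """
    design = design or StudyDesign()
    score_specs, asym_specs = specs if specs is not None else default_specs()
    rng = np.random.default_rng(design.seed)

    subtype_of = {
        "typical": None,
        "cp_unilateral": "unilateral",
        "cp_diplegia": "bilateral_diplegia",
        "cp_quadriplegia": "bilateral_quadriplegia",
    }

    exams: list[ExamRecord] = []
    outcomes: list[OutcomeLabel] = []
    subject_counter = 0
    rho = design.rho
    noise_scale = math.sqrt(max(0.0, 1.0 - rho**2))

    for group, n_subjects in design.group_sizes.items():
        for _ in range(n_subjects):
            subject_counter += 1
            subject_id = f"S{subject_counter:04d}"
            outcome = (
                OutcomeLabel(subject_id, "typical")
                if group == "typical"
                else OutcomeLabel(subject_id, "cp", subtype_of[group])
            )
            outcomes.append(outcome)
            z = rng.standard_normal()
            for age in design.ages:
                spec = score_specs[(group, age)]
                u = norm.cdf(rho * z + noise_scale * rng.standard_normal())
                u = min(max(u, 1e-12), 1.0 - 1e-12)
                draw = float(truncated_normal(spec).ppf(u))
                if group == "typical":
                    asym = int(rng.random() < TYPICAL_ASYMMETRY_RATE)
                else:
                    asym = int(sample_asymmetry_count(asym_specs[(group, age)], 1, rng)[0])
                # round the continuous draw straight to the grid the exam can
                # attain (half-points need an asymmetric item), keeping the
                # rounding unbiased
                grid = 2.0 if asym else 1.0
                score = float(
                    np.clip(np.round(draw * grid) / grid, spec.min_score, spec.max_score)
                )
                score = _clamp_to_feasible(score, asym)
                responses = allocate_items(score, group, age, asym, rng)
                exams.append(ExamRecord(subject_id, age, responses))
    return exams, outcomes
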