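"""Diagnostic-accuracy analysis: ROC, Liu cut-points, confusion metrics, CIs.

Cut-off estimation follows the Liu criterion — the threshold maximizing the
product of sensitivity and specificity on the empirical ROC — with the
screening orientation used throughout this package: a subject is called
positive (at risk of CP) when the global score falls *strictly below* the
threshold.  Low scores indicate risk, so the ROC is computed in this
orientation and never auto-flipped.

AUC is the Mann-Whitney estimator, P(typical score > CP score) plus half the
tie probability, which equals the trapezoidal area under the empirical ROC.
Confidence intervals are stratified (within-class) percentile bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .proforma import ValidationError

__all__ = [
    "LabeledScores",
    "ConfusionCounts",
    "DiagnosticMetrics",
    "CutoffResult",
    "confusion_at",
    "metrics",
    "metrics_from_rates",
    "roc_points",
    "auc",
    "candidate_thresholds",
    "liu_cutpoint",
    "youden_cutpoint",
    "bootstrap_ci",
    "round_half_up",
]


@dataclass(frozen=True)
class LabeledScores:
    """Global scores with outcome labels (CP = positive, typical = negative)."""

    scores: np.ndarray
    labels: np.ndarray  # boolean, True = CP
    age_months: int | None = None

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels, dtype=bool)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValidationError("scores and labels must be parallel 1-d arrays")
        if scores.size == 0:
            raise ValidationError("empty labeled-score set")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.labels).sum())

    @property
    def positives(self) -> np.ndarray:
        return self.scores[self.labels]

    @property
    def negatives(self) -> np.ndarray:
        return self.scores[~self.labels]

    def require_both_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise ValidationError(
                "ROC operations need at least one CP and one typical subject"
            )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValidationError(f"negative confusion count {name}")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Accuracy metrics; a metric with a zero denominator is None (undefined)."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None


def confusion_at(threshold: float, data: LabeledScores) -> ConfusionCounts:
    """Confusion counts for the rule "positive iff score < threshold"."""
    called = data.scores < threshold
    return ConfusionCounts(
        tp=int((called & data.labels).sum()),
        fp=int((called & ~data.labels).sum()),
        tn=int((~called & ~data.labels).sum()),
        fn=int((~called & data.labels).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(counts: ConfusionCounts) -> DiagnosticMetrics:
    return DiagnosticMetrics(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
    )


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero, matching printed tables."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)


def metrics_from_rates(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> tuple[ConfusionCounts, DiagnosticMetrics]:
    """Reconstruct integer confusion counts from reported rates and cohort sizes.

    tp and tn are the reported rates scaled to the class sizes and rounded
    half-up to whole subjects; the remaining metrics follow from the counts.
    Used to audit published sensitivity/specificity against published
    PPV/NPV/accuracy.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValidationError("rates must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValidationError("cohort sizes must be positive")
    tp = int(math.floor(sensitivity * n_pos + 0.5))
    tn = int(math.floor(specificity * n_neg + 0.5))
    counts = ConfusionCounts(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)
    return counts, metrics(counts)


def candidate_thresholds(scores: np.ndarray, integer_grid: bool = False) -> np.ndarray:
    """Candidate cut-offs: distinct observed scores plus one above the
    maximum (so "everything positive" is reachable), or the integer grid
    0..34 when published-style integer cut-offs are wanted."""
    if integer_grid:
        return np.arange(0.0, 35.0)
    distinct = np.unique(np.asarray(scores, dtype=float))
    return np.append(distinct, distinct[-1] + 1.0)


def roc_points(data: LabeledScores) -> list[tuple[float, float, float]]:
    """Empirical ROC: (threshold, sensitivity, 1 - specificity) per candidate
    threshold, ordered by increasing threshold.  Sensitivity is
    non-decreasing along the list because raising the threshold can only
    call more subjects positive."""
    data.require_both_classes()
    points = []
    for c in candidate_thresholds(data.scores):
        sens = float((data.positives < c).mean())
        fpr = float((data.negatives < c).mean())
        points.append((float(c), sens, fpr))
    return points


def auc(data: LabeledScores) -> float:
    """Mann-Whitney AUC: P(typical score > CP score) + 0.5 P(tie).

    Computed from midranks, so ties are handled exactly; equals the
    trapezoidal area under :func:`roc_points`.
    """
    data.require_both_classes()
    ranks = rankdata(data.scores)
    rank_sum_neg = float(ranks[~data.labels].sum())
    n_neg = data.n_neg
    u_neg = rank_sum_neg - n_neg * (n_neg + 1) / 2.0
    return u_neg / (n_neg * data.n_pos)


@dataclass(frozen=True)
class CutoffResult:
    """An estimated cut-off with its operating characteristics.

    ``degenerate`` marks the case where no threshold separates the classes
    at all (sensitivity x specificity is zero everywhere); the smallest
    candidate is returned so downstream code still has a threshold.
    ``cis`` maps metric name -> (low, high) bootstrap interval when
    requested.
    """

    threshold: float
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    accuracy: float
    auc: float
    n_pos: int
    n_neg: int
    degenerate: bool = False
    cis: Mapping[str, tuple[float, float]] | None = None


def _sweep(data: LabeledScores, candidates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = np.sort(data.positives)
    neg = np.sort(data.negatives)
    sens = np.searchsorted(pos, candidates, side="left") / pos.size
    # specificity from the true-negative count itself (not 1 - fpr), so the
    # product is bit-identical to count-based computation and ties break
    # consistently
    spec = (neg.size - np.searchsorted(neg, candidates, side="left")) / neg.size
    return sens, spec


def liu_cutpoint(
    data: LabeledScores,
    integer_grid: bool = False,
    *,
    ci_bootstrap: int = 0,
    seed: int | None = None,
    level: float = 0.95,
) -> CutoffResult:
    """Liu-criterion cut-point: maximize sensitivity x specificity.

    Candidates are the distinct observed scores plus one above the maximum
    (or the integer grid 0..34 with ``integer_grid``).  Ties in the product
    break toward the smallest threshold, the most specific rule.  With
    ``ci_bootstrap`` > 0, stratified percentile bootstrap intervals are
    attached for every metric (the threshold is held fixed; the AUC is
    re-estimated per resample).
    """
    data.require_both_classes()
    candidates = candidate_thresholds(data.scores, integer_grid)
    sens, spec = _sweep(data, candidates)
    product = sens * spec
    best = int(np.argmax(product))  # argmax takes the first (smallest) on ties
    threshold = float(candidates[best])
    degenerate = bool(product[best] == 0.0)
    if degenerate:
        threshold = float(candidates[0])
    counts = confusion_at(threshold, data)
    m = metrics(counts)
    cis = None
    if ci_bootstrap > 0:
        cis = _bootstrap_cutoff_cis(data, threshold, ci_bootstrap, seed, level)
    return CutoffResult(
        threshold=threshold,
        sensitivity=m.sensitivity or 0.0,
        specificity=m.specificity or 0.0,
        ppv=m.ppv,
        npv=m.npv,
        accuracy=m.accuracy or 0.0,
        auc=auc(data),
        n_pos=data.n_pos,
        n_neg=data.n_neg,
        degenerate=degenerate,
        cis=cis,
    )


def youden_cutpoint(data: LabeledScores, integer_grid: bool = False) -> CutoffResult:
    """Cross-check utility: threshold maximizing sensitivity + specificity - 1.

    Not used by the published analysis (which is Liu); provided for
    comparison only.
    """
    data.require_both_classes()
    candidates = candidate_thresholds(data.scores, integer_grid)
    sens, spec = _sweep(data, candidates)
    best = int(np.argmax(sens + spec - 1.0))
    threshold = float(candidates[best])
    m = metrics(confusion_at(threshold, data))
    return CutoffResult(
        threshold=threshold,
        sensitivity=m.sensitivity or 0.0,
        specificity=m.specificity or 0.0,
        ppv=m.ppv,
        npv=m.npv,
        accuracy=m.accuracy or 0.0,
        auc=auc(data),
        n_pos=data.n_pos,
        n_neg=data.n_neg,
    )


def _stratified_indices(
    rng: np.random.Generator, labels: np.ndarray, n_boot: int
) -> tuple[np.ndarray, np.ndarray]:
    pos_idx = np.flatnonzero(labels)
    neg_idx = np.flatnonzero(~labels)
    pos_draws = rng.choice(pos_idx, size=(n_boot, pos_idx.size), replace=True)
    neg_draws = rng.choice(neg_idx, size=(n_boot, neg_idx.size), replace=True)
    return pos_draws, neg_draws


def bootstrap_ci(
    statistic: Callable[[LabeledScores], float],
    data: LabeledScores,
    n_boot: int = 2000,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for a scalar statistic.

    Resampling is within class, so every resample retains both classes and
    ROC statistics stay defined.  Reproducible under a fixed seed.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValidationError("level must lie in (0, 1)")
    data.require_both_classes()
    rng = np.random.default_rng(seed)
    pos_draws, neg_draws = _stratified_indices(rng, data.labels, n_boot)
    values = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([pos_draws[b], neg_draws[b]])
        values[b] = statistic(
            LabeledScores(data.scores[idx], data.labels[idx], data.age_months)
        )
    alpha = (1.0 - level) / 2.0
    low, high = np.quantile(values, [alpha, 1.0 - alpha])
    return float(low), float(high)


def _bootstrap_cutoff_cis(
    data: LabeledScores,
    threshold: float,
    n_boot: int,
    seed: int | None,
    level: float,
) -> dict[str, tuple[float, float]]:
    rng = np.random.default_rng(seed)
    pos_draws, neg_draws = _stratified_indices(rng, data.labels, n_boot)
    names = ("sensitivity", "specificity", "ppv", "npv", "accuracy", "auc")
    values: dict[str, list[float]] = {name: [] for name in names}
    for b in range(n_boot):
        idx = np.concatenate([pos_draws[b], neg_draws[b]])
        resample = LabeledScores(data.scores[idx], data.labels[idx], data.age_months)
        m = metrics(confusion_at(threshold, resample))
        for name in names[:-1]:
            value = getattr(m, name)
            if value is not None:
                values[name].append(value)
        values["auc"].append(auc(resample))
    alpha = (1.0 - level) / 2.0
    cis = {}
    for name in names:
        if values[name]:
            low, high = np.quantile(values[name], [alpha, 1.0 - alpha])
            cis[name] = (float(low), float(high))
    return cis
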