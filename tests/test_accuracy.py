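"""ROC analysis, Liu cut-points, confusion metrics and bootstrap CIs.

The Liu cut-point and the Mann-Whitney AUC are each checked against
independent oracles: an exhaustive threshold sweep, an O(n^2) pairwise
comparison, the trapezoidal ROC area, and scikit-learn's roc_auc_score.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from briefhine.accuracy import (
    ConfusionCounts,
    LabeledScores,
    auc,
    bootstrap_ci,
    candidate_thresholds,
    confusion_at,
    liu_cutpoint,
    metrics,
    metrics_from_rates,
    roc_points,
    round_half_up,
    youden_cutpoint,
)
from briefhine.proforma import ValidationError


def labeled(cp_scores, typical_scores):
    scores = np.array(list(cp_scores) + list(typical_scores), dtype=float)
    labels = np.array([True] * len(cp_scores) + [False] * len(typical_scores))
    return LabeledScores(scores, labels)


@st.composite
def random_datasets(draw, max_n=30):
    n_pos = draw(st.integers(1, max_n))
    n_neg = draw(st.integers(1, max_n))
    grid = st.integers(0, 66)  # half-point global-score grid
    pos = [draw(grid) / 2 for _ in range(n_pos)]
    neg = [draw(grid) / 2 for _ in range(n_neg)]
    return labeled(pos, neg)


# -- confusion counts and metrics -------------------------------------------


def test_confusion_extremes_and_toy_set():
    data = labeled([10, 12], [25, 26])
    low = confusion_at(0, data)
    assert (low.tp, low.fp, low.fn, low.tn) == (0, 0, 2, 2)
    high = confusion_at(34, data)
    assert (high.tp, high.fp, high.fn, high.tn) == (2, 2, 0, 0)
    mid = confusion_at(22, data)
    assert (mid.tp, mid.fn, mid.tn, mid.fp) == (2, 0, 2, 0)


def test_metrics_match_published_three_month_row():
    m = metrics(ConfusionCounts(tp=72, fp=18, tn=210, fn=10))
    assert m.ppv == pytest.approx(0.80)
    assert m.npv == pytest.approx(210 / 220)
    assert m.accuracy == pytest.approx(282 / 310)
    assert round_half_up(m.npv) == 0.95
    assert round_half_up(m.accuracy) == 0.91


def test_perfect_classifier_metrics_all_one():
    m = metrics(ConfusionCounts(tp=82, fp=0, tn=228, fn=0))
    assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy) == (1, 1, 1, 1, 1)


def test_zero_denominator_is_undefined_not_zero():
    m = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
    assert m.ppv is None
    assert m.specificity == 1.0


@settings(max_examples=100, derandomize=True)
@given(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(0, 200))
def test_metrics_identities_on_random_counts(tp, fp, tn, fn):
    counts = ConfusionCounts(tp, fp, tn, fn)
    m = metrics(counts)
    assert counts.n_pos == tp + fn and counts.n_neg == tn + fp
    if counts.total and m.sensitivity is not None and m.specificity is not None:
        prevalence = counts.n_pos / counts.total
        assert m.accuracy == pytest.approx(
            m.sensitivity * prevalence + m.specificity * (1 - prevalence)
        )


@pytest.mark.parametrize(
    "sens,spec,expected_ppv,expected_npv",
    [
        (0.88, 0.92, 0.80, 0.95),  # 3-month row
        (0.93, 0.87, 0.72, 0.97),  # 6-month row
        (1.0, 0.86, 0.72, 1.0),  # 12-month row: fn = 0 forces npv = 1
    ],
)
def test_counts_reconstructed_from_rates(sens, spec, expected_ppv, expected_npv):
    counts, m = metrics_from_rates(sens, spec, n_pos=82, n_neg=228)
    assert counts.n_pos == 82 and counts.n_neg == 228
    assert round_half_up(m.ppv) == expected_ppv
    assert round_half_up(m.npv) == expected_npv


def test_perfect_rates_give_perfect_accuracy():
    _, m = metrics_from_rates(1.0, 1.0, 50, 70)
    assert m.accuracy == 1.0


# -- ROC and AUC -------------------------------------------------------------


def test_roc_contains_perfect_point_when_separated():
    points = roc_points(labeled([10, 12], [25, 26, 27]))
    assert any(sens == 1.0 and fpr == 0.0 for _, sens, fpr in points)
    sens_values = [sens for _, sens, _ in points]
    assert sens_values == sorted(sens_values)


def test_roc_degenerate_identical_scores():
    points = roc_points(labeled([20], [20, 20]))
    assert [(s, f) for _, s, f in points] == [(0.0, 0.0), (1.0, 1.0)]


def test_roc_matches_hand_enumeration():
    # CP: 10, 20; typical: 15, 20, 25, 30.  Candidates: distinct + max+1.
    data = labeled([10, 20], [15, 20, 25, 30])
    expected = [
        (10.0, 0.0, 0.0),
        (15.0, 0.5, 0.0),
        (20.0, 0.5, 0.25),
        (25.0, 1.0, 0.5),
        (30.0, 1.0, 0.75),
        (31.0, 1.0, 1.0),
    ]
    assert roc_points(data) == expected


def test_auc_extremes():
    assert auc(labeled([10, 12], [25, 26])) == 1.0
    assert auc(labeled([25, 26], [10, 12])) == 0.0
    assert auc(labeled([20, 20], [20, 20, 20])) == 0.5


def test_auc_matches_pairwise_oracle_on_toy_set():
    data = labeled([10, 15, 20, 20, 25], [12, 20, 22, 30, 30])
    wins = ties = 0
    for p in data.positives:
        for n in data.negatives:
            wins += n > p
            ties += n == p
    assert auc(data) == pytest.approx((wins + 0.5 * ties) / 25)


@settings(max_examples=150, derandomize=True)
@given(random_datasets())
def test_auc_equals_trapezoidal_roc_area(data):
    points = roc_points(data)
    fpr = [f for _, _, f in points]
    tpr = [s for _, s, _ in points]
    assert auc(data) == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-9)


@settings(max_examples=100, derandomize=True)
@given(random_datasets())
def test_auc_agrees_with_sklearn(data):
    # positive call = low score, so sklearn sees the negated scores
    expected = roc_auc_score(data.labels, -data.scores)
    assert auc(data) == pytest.approx(expected, abs=1e-12)


def test_single_class_data_rejected():
    with pytest.raises(ValidationError):
        auc(labeled([1, 2], []))
    with pytest.raises(ValidationError):
        liu_cutpoint(labeled([], [1, 2]))


# -- Liu cut-point ------------------------------------------------------------


def test_liu_on_separated_toy_set():
    result = liu_cutpoint(labeled([10, 12], [25, 26, 27]))
    assert result.threshold == 25.0
    assert result.sensitivity == 1.0 and result.specificity == 1.0
    assert not result.degenerate


def test_liu_degenerate_overlap_flagged():
    result = liu_cutpoint(labeled([20, 20], [20, 20]))
    assert result.degenerate
    assert result.threshold == 20.0  # smallest candidate


def test_liu_integer_grid_restricts_candidates():
    grid = candidate_thresholds(np.array([1.5, 20.5]), integer_grid=True)
    assert grid.tolist() == list(range(35))
    result = liu_cutpoint(labeled([10.5, 12.5], [25.5, 26.5]), integer_grid=True)
    assert result.threshold == int(result.threshold)


def _exhaustive_liu(data):
    best = None
    for c in candidate_thresholds(data.scores):
        counts = confusion_at(c, data)
        sens = counts.tp / data.n_pos
        spec = counts.tn / data.n_neg
        product = sens * spec
        if best is None or product > best[0]:
            best = (product, c)  # strict > keeps the smallest threshold on ties
    return best


@settings(max_examples=200, derandomize=True)
@given(random_datasets(max_n=100))
def test_liu_equals_exhaustive_sweep(data):
    result = liu_cutpoint(data)
    product, threshold = _exhaustive_liu(data)
    if product == 0:
        assert result.degenerate
    else:
        assert result.threshold == threshold
        assert result.sensitivity * result.specificity == pytest.approx(product)


def test_youden_cross_check_on_skewed_overlap():
    # Liu and Youden agree on this toy set; Youden is the off-by-default check
    data = labeled([10, 12, 18], [16, 25, 26, 27])
    assert youden_cutpoint(data).threshold == liu_cutpoint(data).threshold


# -- bootstrap ----------------------------------------------------------------


def test_bootstrap_is_deterministic_under_seed():
    data = labeled(np.arange(10.0), np.arange(15.0, 40.0))
    first = bootstrap_ci(auc, data, n_boot=200, seed=42)
    second = bootstrap_ci(auc, data, n_boot=200, seed=42)
    assert first == second
    assert first[0] <= first[1]


def test_bootstrap_constant_statistic_zero_width():
    data = labeled([1, 2, 3], [4, 5, 6])
    low, high = bootstrap_ci(lambda d: 0.7, data, n_boot=50, seed=0)
    assert (low, high) == (0.7, 0.7)


def test_bootstrap_stratification_keeps_both_classes():
    # a single CP subject: unstratified resampling would often lose the class
    data = labeled([10], [20, 21, 22, 23, 24])
    low, high = bootstrap_ci(auc, data, n_boot=300, seed=1)
    assert 0.0 <= low <= high <= 1.0


def test_bootstrap_coverage_near_nominal_on_known_distribution():
    """95% percentile interval for AUC covers the true value ~95% of the
    time when scores are normal with a known separation."""
    from scipy.stats import norm

    rng = np.random.default_rng(12345)
    delta = 1.0
    true_auc = norm.cdf(delta / np.sqrt(2))  # P(N(delta,1) > N(0,1))
    hits = 0
    trials = 60
    for t in range(trials):
        pos = rng.normal(0.0, 1.0, 40)
        neg = rng.normal(delta, 1.0, 40)
        data = LabeledScores(np.concatenate([pos, neg]),
                             np.array([True] * 40 + [False] * 40))
        low, high = bootstrap_ci(auc, data, n_boot=300, seed=t)
        hits += low <= true_auc <= high
    assert hits / trials >= 0.85


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(0.645) == 0.65
    assert round_half_up(0.6446) == 0.64
    assert round_half_up(2.25, 1) == 2.3
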