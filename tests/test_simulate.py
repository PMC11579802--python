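"""Synthetic-cohort generator: calibrated marginals, item allocation, copula."""

import numpy as np
import pytest

from briefhine.proforma import (
    AGE_RELATED_ITEMS,
    ExamRecord,
    count_asymmetries,
    global_score,
    score_item,
)
from briefhine.simulate import (
    AllocationError,
    AsymmetrySpec,
    GroupScoreSpec,
    StudyDesign,
    allocate_items,
    default_asymmetry_specs,
    default_score_specs,
    fit_truncated_geometric,
    sample_asymmetry_count,
    sample_global_scores,
    simulate_study,
    truncated_normal_moments,
)
from briefhine.proforma import ValidationError


def test_default_specs_carry_published_summaries():
    specs = default_score_specs()
    typical3 = specs[("typical", 3)]
    assert (typical3.mean, typical3.sd, typical3.min_score, typical3.max_score) == (
        23.0,
        2.2,
        18.0,
        30.0,
    )
    typical12 = specs[("typical", 12)]
    assert (typical12.mean, typical12.sd, typical12.min_score, typical12.max_score) == (
        31.0,
        1.6,
        27.0,
        33.0,
    )
    # subtype rows publish no SD -> defaults to range/4
    quad12 = specs[("cp_quadriplegia", 12)]
    assert (quad12.min_score, quad12.max_score) == (10.0, 21.0)
    assert quad12.sd == pytest.approx((21 - 10) / 4)


def test_sampled_scores_respect_bounds_grid_and_seed():
    spec = default_score_specs()[("cp_diplegia", 3)]
    scores = sample_global_scores(spec, 500, seed=9)
    assert scores.min() >= spec.min_score and scores.max() <= spec.max_score
    assert np.all(scores * 2 == np.round(scores * 2))  # half-point grid
    assert np.array_equal(scores, sample_global_scores(spec, 500, seed=9))


def test_sample_mean_matches_truncated_normal_oracle():
    spec = default_score_specs()[("typical", 3)]
    scores = sample_global_scores(spec, 50_000, seed=2)
    mean, sd = truncated_normal_moments(spec)
    assert scores.mean() == pytest.approx(mean, abs=0.1)
    assert scores.std(ddof=1) == pytest.approx(sd, abs=0.1)


def test_infeasible_spec_rejected():
    with pytest.raises(ValidationError):
        GroupScoreSpec("typical", 3, mean=35.0, sd=1.0, min_score=0, max_score=33)
    with pytest.raises(ValidationError):
        GroupScoreSpec("typical", 3, mean=10.0, sd=1.0, min_score=15, max_score=33)


def test_asymmetry_sampler_bounds_and_medians():
    specs = default_asymmetry_specs()
    diplegia = specs[("cp_diplegia", 6)]
    counts = sample_asymmetry_count(diplegia, 2000, seed=4)
    assert set(np.unique(counts)) <= {0, 1, 2}
    assert np.median(counts) == 0
    unilateral9 = specs[("cp_unilateral", 9)]
    counts = sample_asymmetry_count(unilateral9, 5000, seed=4)
    assert np.median(counts) == 2
    assert counts.max() <= 6


def test_truncated_geometric_pmf_is_monotone_and_normalized():
    pmf = fit_truncated_geometric(1, 0, 6)
    assert pmf.sum() == pytest.approx(1.0)
    assert all(pmf[i] >= pmf[i + 1] for i in range(len(pmf) - 1))
    assert pmf[:2].sum() >= 0.5  # median pinned at 1


def test_allocate_extremes():
    responses = allocate_items(33, "typical", 12, 0, seed=0)
    assert all(score_item(r) == 3 for r in responses)
    assert count_asymmetries(ExamRecord("x", 12, responses)) == 0
    responses = allocate_items(0, "cp_quadriplegia", 3, 0, seed=0)
    assert all(score_item(r) == 0 for r in responses)


@pytest.mark.parametrize("target,asym", [(20, 2), (15.5, 1), (27, 6), (6.5, 3), (31, 1)])
def test_allocation_hits_score_and_asymmetry_targets(target, asym):
    for seed in range(5):
        responses = allocate_items(target, "cp_unilateral", 9, asym, seed=seed)
        exam = ExamRecord("x", 9, responses)
        assert global_score(exam) == target
        assert count_asymmetries(exam) == asym


def test_half_point_target_without_asymmetry_rounds():
    responses = allocate_items(20.5, "typical", 9, 0, seed=1)
    assert global_score(ExamRecord("x", 9, responses)) == 21.0  # half rounds up


def test_infeasible_allocations_raise():
    with pytest.raises(AllocationError, match="unattainable"):
        allocate_items(0, "cp_unilateral", 3, 2, seed=0)  # asymmetric items score >= 1
    with pytest.raises(AllocationError, match="unattainable"):
        allocate_items(33, "typical", 3, 1, seed=0)  # asymmetric item cannot score 3
    with pytest.raises(AllocationError):
        allocate_items(20, "typical", 3, 7, seed=0)  # only six paired items


def test_typical_early_exams_depress_age_related_items():
    zeros = 0
    for seed in range(200):
        responses = allocate_items(23, "typical", 3, 0, seed=seed)
        by_item = {r.item_id: score_item(r) for r in responses}
        for item in AGE_RELATED_ITEMS:
            zeros += by_item[item] == 0
        for item, value in by_item.items():
            if item not in AGE_RELATED_ITEMS:
                assert value >= 2  # low scores land on the maturing items first
    assert zeros / (200 * 3) > 0.5


def test_study_shape_and_reproducibility():
    design = StudyDesign(n_typical=20, n_unilateral=4, n_diplegia=3, n_quadriplegia=3, seed=11)
    exams, outcomes = simulate_study(design)
    assert len(exams) == 30 * 4 and len(outcomes) == 30
    again, _ = simulate_study(design)
    assert [global_score(e) for e in exams] == [global_score(e) for e in again]
    by_outcome = {}
    for o in outcomes:
        by_outcome[o.outcome] = by_outcome.get(o.outcome, 0) + 1
    assert by_outcome == {"typical": 20, "cp": 10}


def test_default_design_counts():
    design = StudyDesign()
    assert (design.n_typical, design.n_unilateral, design.n_diplegia, design.n_quadriplegia) == (
        228,
        40,
        17,
        25,
    )
    assert sum(design.group_sizes.values()) * len(design.ages) == 1240


def test_scores_stay_within_group_bounds(small_study):
    exams, outcomes = small_study
    specs = default_score_specs()
    group_of = {}
    for o in outcomes:
        group_of[o.subject_id] = (
            "typical"
            if o.outcome == "typical"
            else {
                "unilateral": "cp_unilateral",
                "bilateral_diplegia": "cp_diplegia",
                "bilateral_quadriplegia": "cp_quadriplegia",
            }[o.cp_subtype]
        )
    for exam in exams:
        spec = specs[(group_of[exam.subject_id], exam.age_months)]
        assert spec.min_score <= global_score(exam) <= spec.max_score


def test_study_marginals_match_truncated_normal_oracle(small_study):
    """Cohort-level score means agree with the analytic truncated-normal
    mean within sampling error (3 SE at the group size)."""
    exams, outcomes = small_study
    typical = {o.subject_id for o in outcomes if o.outcome == "typical"}
    for age in (3, 12):
        spec = default_score_specs()[("typical", age)]
        values = [global_score(e) for e in exams
                  if e.subject_id in typical and e.age_months == age]
        mean, sd = truncated_normal_moments(spec)
        assert abs(np.mean(values) - mean) < 3 * sd / np.sqrt(len(values))


def test_typical_cohort_asymmetries_rare_and_single(small_study):
    exams, outcomes = small_study
    typical = {o.subject_id for o in outcomes if o.outcome == "typical"}
    counts = [count_asymmetries(e) for e in exams if e.subject_id in typical]
    assert max(counts) <= 1
    assert 0 < np.mean(counts) < 0.2


def test_full_copula_makes_trajectories_comonotone():
    """With rho = 1 a subject keeps the same within-group quantile at every
    age, so two subjects' score orderings never cross between ages."""
    design = StudyDesign(n_typical=15, n_unilateral=1, n_diplegia=1, n_quadriplegia=1,
                         seed=3, rho=1.0)
    exams, outcomes = simulate_study(design)
    typical = sorted({o.subject_id for o in outcomes if o.outcome == "typical"})
    scores = {
        s: {e.age_months: global_score(e) for e in exams if e.subject_id == s}
        for s in typical
    }
    for i, a in enumerate(typical):
        for b in typical[i + 1 :]:
            diffs = [scores[a][age] - scores[b][age] for age in (3, 6, 9, 12)]
            assert not (any(d > 0 for d in diffs) and any(d < 0 for d in diffs))
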