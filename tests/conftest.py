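import pytest
from hypothesis import strategies as st

from briefhine.proforma import ITEM_IDS, PAIRED_ITEMS, ExamRecord, ItemResponse


def make_exam(
    overrides: dict[str, int | tuple[int, int]] | None = None,
    age_months: int = 12,
    subject_id: str = "s1",
    default: int = 3,
) -> ExamRecord:
    """Build a valid exam: every item at `default`, with per-item overrides.

    An override may be a single column score (applied to both sides of a
    paired item) or a (left, right) pair.
    """
    overrides = overrides or {}
    responses = []
    for item in ITEM_IDS:
        value = overrides.get(item, default)
        if item in PAIRED_ITEMS:
            left, right = value if isinstance(value, tuple) else (value, value)
            responses.append(ItemResponse(item, left, right))
        else:
            assert not isinstance(value, tuple), f"{item} is unpaired"
            responses.append(ItemResponse(item, value))
    return ExamRecord(subject_id, age_months, tuple(responses))


@st.composite
def exam_records(draw, ages=(3, 6, 9, 12)):
    responses = []
    for item in ITEM_IDS:
        left = draw(st.integers(0, 3))
        if item in PAIRED_ITEMS:
            responses.append(ItemResponse(item, left, draw(st.integers(0, 3))))
        else:
            responses.append(ItemResponse(item, left))
    return ExamRecord("h1", draw(st.sampled_from(ages)), tuple(responses))


@pytest.fixture(scope="session")
def small_study():
    """A small seeded simulated study shared across tests."""
    from briefhine.simulate import StudyDesign, simulate_study

    return simulate_study(
        StudyDesign(n_typical=60, n_unilateral=12, n_diplegia=6, n_quadriplegia=8, seed=5)
    )
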