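"""Re-derive the warning-sign rule from a simulated normative cohort.

Simulates 1000 infants with a typical two-year outcome and tabulates, for
each item and age, which column scores fall outside the 90th centile of
the cohort's score distribution — the data-driven justification for the
fixed warning-sign table.
"""

from briefhine import DEFAULT_WARNING_RULES, StudyDesign, derive_warning_scores, simulate_study

design = StudyDesign(n_typical=1000, n_unilateral=1, n_diplegia=1, n_quadriplegia=1, seed=20)
exams, outcomes = simulate_study(design)
typical = {o.subject_id for o in outcomes if o.outcome == "typical"}

for age in (3, 6, 9, 12):
    cohort = [e for e in exams if e.subject_id in typical and e.age_months == age]
    derived = derive_warning_scores(cohort, age)
    flagged = {item: sorted(scores) for item, scores in derived.items() if scores}
    matches = all(
        frozenset(derived[item]) == DEFAULT_WARNING_RULES[item][age] for item in derived
    )
    print(f"{age:>2} months: {len(flagged)} items flag low scores; "
          f"matches fixed rule table: {matches}")
# At 3 and 6 months only the eight non-age-related items flag scores 0-1;
# trunk posture, lateral tilting and forward parachute join at 9-12 months
# because low scores on maturing postural items are typical early on.
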