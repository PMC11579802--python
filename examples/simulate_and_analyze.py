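"""Simulate the study cohort and re-estimate the age-specific cut-offs.

Generates the default synthetic study (228 typical infants, 82 who develop
cerebral palsy: 40 unilateral, 17 diplegia, 25 quadriplegia; exams at 3, 6,
9 and 12 months), then estimates the Liu cut-off, sensitivity, specificity
and AUC at each age.
"""

from briefhine import StudyConfig, StudyDesign, run_study, simulate_study

exams, outcomes = simulate_study(StudyDesign(seed=1))
print(f"simulated {len(exams)} exams for {len(outcomes)} subjects")

report = run_study(exams, outcomes, StudyConfig(seed=1, bootstrap_n=500))
print("age  cutoff  sens  spec   auc  (95% CI)")
for age, r in sorted(report.cutoffs.items()):
    low, high = r.cis["auc"]
    print(f"{age:>3}  {r.threshold:>6.0f}  {r.sensitivity:.2f}  {r.specificity:.2f}"
          f"  {r.auc:.2f}  ({low:.2f}-{high:.2f})")
# Each row is the threshold below which an infant screens at risk of CP at
# that age, with the operating characteristics the threshold achieves on
# the simulated cohort.  The Liu criterion picks the threshold maximizing
# sensitivity x specificity.
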