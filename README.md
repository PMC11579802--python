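# briefhine

Scoring, warning-sign classification and diagnostic-accuracy analysis for
the **Brief-HINE**, an 11-item short form of the Hammersmith Infant
Neurological Examination used to screen infants at 3, 6, 9 and 12 months
for early signs of cerebral palsy (CP).

The package is for clinicians and methodologists working with infant
neuromotor screening data: it implements the instrument's data model and
scoring arithmetic, the referral rules, and the statistical machinery used
to validate such an instrument — together with a calibrated synthetic
cohort generator so the entire analysis runs end to end without patient
data.

## The instrument and the analysis

Each of the 11 items (visual response, trunk posture, movement quantity
and quality, scarf sign, hip adductors, popliteal angle, pull to sit,
lateral tilting, forward parachute, tendon reflexes) is recorded in one of
four optimality columns with column score *s* ∈ {3, 2, 1, 0}; column 3 is
the optimal finding seen in >75 % of typically developing infants and
columns 1–0 are findings seen in <10 %. Six items are examined per body
side; when the sides land in different columns the item score is the mean
of the two, so the **global score** G = Σᵢ sᵢ lies in [0, 33] on a
half-point grid.

* **Risk screen** — an infant screens *at risk* of CP when G < c(age),
  with published thresholds c = 22, 25, 27, 27 at 3, 6, 9, 12 months.
* **Warning signs** — an item score of 0–1 (outside the 90th centile of
  the typical-outcome cohort); trunk posture, lateral tilting and forward
  parachute are exempt at 3–6 months, where low scores are still typical.
  More than one warning sign triggers referral for the full 26-item exam.
* **Cut-off estimation** — thresholds are re-estimated by the **Liu
  criterion**, argmax over thresholds of sensitivity × specificity on the
  empirical ROC (positive call: G < c). AUC is the Mann–Whitney
  estimator P(G_typical > G_CP) + ½·P(tie); confidence intervals are
  stratified percentile bootstrap.

## Worked example

`examples/simulate_and_analyze.py` simulates the default study cohort
(228 typical infants and 82 who develop CP — 40 unilateral, 17 bilateral
diplegia, 25 bilateral quadriplegia — each examined at all four ages) and
re-estimates the age-specific cut-offs:

```
simulated 1240 exams for 310 subjects
age  cutoff  sens  spec   auc  (95% CI)
  3      20  0.91  0.94  0.98  (0.95-0.99)
  6      26  0.95  0.90  0.96  (0.93-0.99)
  9      27  0.90  0.97  0.99  (0.97-0.99)
 12      29  0.94  0.96  0.98  (0.96-1.00)
```

Each row is the Liu-optimal threshold below which an infant screens at
risk at that age, with the sensitivity/specificity the threshold achieves
on the simulated cohort and the bootstrap AUC interval. The other examples
score a single exam (`score_an_exam.py`) and re-derive the warning-sign
rule from a simulated normative cohort (`derive_warning_rules.py`).

A thin CLI wraps the same pipeline for shell use:

```bash
bhine simulate --seed 1 --out-dir data/
bhine score data/exams.csv --out screening.csv
bhine analyze data/exams.csv data/outcomes.csv --out-dir analysis/
bhine report data/exams.csv data/outcomes.csv --out-dir report/
```

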