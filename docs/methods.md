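# Methods

## Scoring model

The Brief-HINE global score is the sum of 11 item column scores, each in
{0, 1, 2, 3}. Six items — scarf sign, hip adductors, popliteal angle,
tendon reflexes, lateral tilting, forward parachute — are recorded per
body side; which items admit left/right recording is an instrument-layout
choice and the set is configurable through the item-definition table. An
asymmetric paired item (sides in different columns) contributes the
arithmetic mean of the two column scores, so item scores live on a
half-point grid and the global score spans [0, 33]. Exams are accepted
only at the four assessment ages (3, 6, 9, 12 months); whether an age is
chronological or corrected for prematurity is the caller's
responsibility. Missing or duplicated item responses are hard validation
errors — no imputation.

## Warning signs

The rule table flags column scores {0, 1} for all items at every age,
except trunk posture, lateral tilting and forward parachute, which are
exempt at 3 and 6 months (their optimal responses mature with age, so low
scores there are still typical early on) and flagged from 9 months.
Referral for the full 26-item examination is triggered by **more than
one** warning sign; an optional strict mode also refers any exam with a
single sub-optimal item, for sites reading the referral guidance as a
second independent trigger.

Half-point scores from asymmetry averaging are handled conservatively: a
score is a warning sign only if it is itself ≤ 1 (0, 0.5 or 1). An
averaged 1.5 is *not* flagged by default, since the rule is stated on
scores of 0 or 1; a switch (`flag_half_scores`) flags 1.5 via its integer
part for sites preferring the sensitive reading.

The data-driven derivation (`derive_warning_scores`) flags score *s* for
an item when the cumulative relative frequency P(score ≤ s) in a
typical-outcome cohort is strictly below 0.10 — "outside the 90th
centile", read as the left tail of the score distribution. Ties at
exactly 10 % are not flagged. Because the cumulative frequency is
monotone, derived flag sets are always of the form {0..k}.

## Cut-off classification and estimation

Risk classification is strict: at risk iff global score < threshold, so a
half-point 21.5 is below a threshold of 22 while 22 exactly is not. The
classifier carries its threshold table explicitly; the defaults are the
published values {3 mo: 22, 6 mo: 25, 9 mo: 27, 12 mo: 27} and
re-estimated tables can be swapped in.

Cut-point estimation uses the Liu criterion — maximize sensitivity ×
specificity over the empirical ROC, with the positive call "score <
threshold" (low score = at risk; the curve is never auto-flipped).
Candidate thresholds are the distinct observed scores plus one point above
the maximum, which exhausts the distinct confusion configurations; a
reporting mode restricts candidates to the integer grid 0..34, matching
published integer cut-offs (this is the analysis default). Product ties
break toward the smallest threshold (the most specific rule). When no
threshold attains a positive product (complete overlap) the smallest
candidate is returned with a `degenerate` flag rather than an arbitrary
interior value.

AUC is the Mann–Whitney estimator computed from midranks
(P(typical > CP) + ½ P(tie)); it equals the trapezoidal area under the
empirical ROC, and the test suite holds the two to within 1e-9 and checks
both against an O(n²) pairwise oracle and scikit-learn. Confidence
intervals are stratified percentile bootstrap: resampling within outcome
class keeps every resample two-class, so ROC statistics stay defined
without retry logic; 1000 replicates by default, reproducible under the
configured seed. Cut-off metric CIs hold the estimated threshold fixed
across resamples. Metrics with zero denominators are reported as
undefined (None), never as 0. Display rounding is two decimals, ties away
from zero.

A Youden-index cut-point (`youden_cutpoint`) is provided as an off-by-
default cross-check utility only.

## Synthetic cohort generator

The generator emulates the validation study's structure: 228 typical
infants and 82 who develop CP (40 unilateral, 17 bilateral diplegia, 25
bilateral quadriplegia), each examined at all four ages. Calibrated
marginals:

* **Global scores** — truncated normal on the published [min, max] with
  the published group × age mean/SD, rounded to the half-point grid.
  Subtype rows publish no SD; it defaults to range/4 (the usual
  normal-range heuristic). The distribution family is an assumption — the
  source publishes only mean/SD/range — and alternative specs can be
  passed in.
* **Longitudinal dependence** — a Gaussian copula shares a per-subject
  latent quantile across ages (ρ = 0.8 by default, an assumption: the
  study reports no within-subject correlations). Marginals are exact for
  any ρ; at ρ = 1 a subject keeps the same within-group quantile at every
  age.
* **Asymmetry counts** — truncated geometric on the published ranges,
  with the decay parameter solved by bisection so the distribution's
  median equals the published one (unilateral: 1 at 3–6 months, 2 at 9–12
  months, range 0–6; both bilateral subtypes: median 0). The truncated
  CDF at the median is pinned at 0.6, keeping the empirical median of
  large samples stable. Typical-cohort exams carry a single asymmetry
  with probability 10/228 and never more than one.
* **Item allocation** — item responses realizing a (global score,
  asymmetry count) pair start from the per-item maxima and drain the
  deficit one unit at a time. For typical infants at 3–6 months a small
  share (~15 %) of non-age-related items first drop to column 2 —
  consistent with column 2's definition as a finding seen in more than
  10 % of typical infants — and the three age-related items then absorb
  the deficit depth-first (one item fully to 0 before the next), so their
  low scores are common at those ages as the instrument expects; the
  remainder spreads round-robin. Asymmetric items are realized as side
  pairs in different columns, one of them odd-spaced when the target has
  a half-point. Infeasible combinations (e.g. a target of 0 with
  asymmetries, whose items must score ≥ 0.5) raise an error from
  `allocate_items`; the study simulator instead clamps the sampled score
  into the feasible range, which perturbs the score marginal in well
  under 3 % of unilateral-CP exams. Item-level distributions are
  otherwise illustrative, not calibrated: only the global-score and
  asymmetry-count marginals are treated as matched to the source.

What passing tests on these cohorts show — and what they do not: the
pipeline recovers thresholds between the group means with high
sensitivity/specificity and AUC because the group-level summaries are
well separated; real item-level data have heavier overlap and
within-group structure the generator cannot reproduce, so simulated
operating characteristics (typically AUC ≈ 0.97–0.99) sit above the
published ones (0.88–0.94) and exact reproduction of the published
point estimates is out of reach by construction.

## Problem sizes and numerical conventions

The default simulated study (310 subjects × 4 ages) simulates in ≈ 2 s
and analyses in under a second with 1000 bootstrap replicates. Test
cohorts use 10 000 draws per group × age for parameter recovery (3
standard errors against the analytic truncated-normal moments) and a
1000-infant normative cohort for the warning-rule re-derivation. All
randomness flows through `numpy.random.Generator` seeds; identical seeds
give bit-identical cohorts, analyses and bootstrap intervals.

## Known limitations

* The 9-month published PPV cannot be reproduced from the published
  sensitivity/specificity and cohort sizes by any integer confusion
  table (reconstruction gives 0.64 vs 0.65 printed); the reconstruction
  report therefore checks NPV/accuracy only at that age.
* Published AUC confidence intervals place the point estimate at an
  interval edge; their construction is unclear and is not reproduced —
  this package's intervals are percentile bootstrap.
* No modeling of the full 26-item HINE, item-level clinical
  administration, covariates (gestational age, imaging), or probability
  calibration beyond the binary cut-off rule.
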