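"""Score a single Brief-HINE exam and apply the screening rules.

Builds the exam of a 3-month-old with mildly reduced movement quality, an
asymmetric scarf sign and immature postural reactions, then prints the
global score, the warning-sign profile and the screening decision.
"""

from briefhine import ItemResponse, ExamRecord, screen_exam

responses = (
    ItemResponse("visual_response", 3),
    ItemResponse("trunk_posture", 1),          # still typical at 3 months
    ItemResponse("movement_quantity", 2),
    ItemResponse("movement_quality", 1),       # warning sign
    ItemResponse("scarf_sign", 3, 2),          # asymmetric: scores 2.5
    ItemResponse("hip_adductors", 2, 2),
    ItemResponse("popliteal_angle", 3, 3),
    ItemResponse("pull_to_sit", 2),
    ItemResponse("lateral_tilting", 0, 0),     # exempt at 3 months
    ItemResponse("forward_parachute", 0, 0),   # exempt at 3 months
    ItemResponse("tendon_reflexes", 3, 3),
)
exam = ExamRecord("infant-01", 3, responses)

result = screen_exam(exam)
print(f"global score     : {result.global_score}")
print(f"asymmetries      : {result.asymmetry_count}")
print(f"warning signs    : {result.warnings.warning_count} {list(result.warnings.flagged_items)}")
print(f"risk class       : {result.risk_class} (threshold < 22 at 3 months)")
print(f"needs full HINE  : {result.needs_full_exam}")
# The global score sums the 11 item scores (asymmetric items contribute the
# mean of their two sides).  A score below the age cut-off flags CP risk;
# more than one warning sign would trigger referral for the full 26-item exam.
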