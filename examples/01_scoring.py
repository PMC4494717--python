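"""Score one infant on both severity scales and apply the oxygen-need rule.

A 3-month-old with a respiratory rate of 64/min, feeding difficulty
(dyspnea 1), intercostal retractions (accessory 1) and expiratory wheeze
with crackles (auscultation 2); the sonographer sees confluent B-lines
anterolaterally with spared areas (1), confluent posterior interstitial
syndrome (2), 9 bilaterally involved intercostal spaces, and a 1.4 cm
subpleural consolidation.
"""

from luscore import (
    ClinicalAssessment,
    LUSExam,
    encode_consolidation,
    encode_extension,
    encode_respiratory_rate,
    predict_oxygen_need,
    score_clinical,
    score_lus,
)

clinical = ClinicalAssessment(
    respiratory_rate_item=encode_respiratory_rate(64),
    dyspnea_item=1,
    accessory_muscle_item=1,
    auscultation_item=2,
)
exam = LUSExam(
    anterolateral_item=1,
    posterior_interstitial_item=2,
    extension_item=encode_extension(9),
    consolidation_item=encode_consolidation(1.4),
)

clin = score_clinical(clinical)
lus = score_lus(exam)
print(f"clinical score: {clin.total}/12 -> {clin.grade.label}")
print(f"LUS score:      {lus.total}/8  -> {lus.grade.label}")
print(f"oxygen predicted (LUS total > 3): {predict_oxygen_need(lus.total)}")
# Both scales grade this infant moderate; a LUS total above 3 predicts
# that supplementary oxygen will be required.
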