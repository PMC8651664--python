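"""Score recommendations with the similarity score and self-evaluation.

Builds a 4-patient example covering all outcome classes, tags each
recommendation Good/Bad/Unsure from the outcome and the AI-minus-clinical
dose difference, and prints the cohort report next to the clinical
baseline (which is scored on outcomes alone).
"""

from qdrlart import evaluate_cohort, self_evaluate, similarity_score
from qdrlart.cohort import PatientRecord, PatientState
from qdrlart.evaluation import format_report


def patient(pid, lc, rp2, dose):
    s = PatientState(30.0, 2.0, 30.0, 10.0, 0)
    return PatientRecord(pid, s, s, dose, lc, rp2)


records = [patient("A", 0, 0, 2.0), patient("B", 0, 1, 2.0),
           patient("C", 1, 0, 2.0), patient("D", 1, 1, 2.0)]
ai = {"A": 2.5, "B": 2.5, "C": 2.2, "D": 1.5}

for r in records:
    delta = ai[r.patient_id] - r.clinical_dose
    tag = self_evaluate(r.lc, r.rp2, delta)
    print(f"patient {r.patient_id}: outcome (LC={r.lc}, RP2={r.rp2}), "
          f"delta {delta:+.1f} Gy/frac -> {tag.value}")

print("\nRMSE similarity:",
      round(similarity_score(list(ai.values()), [r.clinical_dose for r in records]), 4),
      "Gy/frac")
print()
print(format_report(evaluate_cohort(records, ai)))
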