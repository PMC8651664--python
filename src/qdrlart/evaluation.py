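"""Decision-evaluation metrics.

Two complementary metrics compare AI dose recommendations with the
retrospective clinical decisions:

* **Similarity score** — the RMSE (Gy/frac) between the ensemble-averaged
  AI recommendation and the clinical dose per patient.  Zero would mean
  pure imitation of a practice assumed suboptimal, so low-but-nonzero is
  the desirable regime.
* **Self-evaluation scheme** — a rule table tagging each recommendation
  Good / Bad / Unsure from the observed binary outcomes (LC, RP2) and the
  dose difference Delta = AI dose - clinical dose, under the assumption
  that more dose raises both tumor control and toxicity risk:

  ====  ====  =================  ======
  LC    RP2   condition          tag
  ====  ====  =================  ======
  0     0     Delta <= 0         Bad
  0     0     Delta > 0          Good
  0     1     Delta < -0.1       Good
  0     1     Delta >= -0.1      Bad
  1     0     |Delta| <= 0.5     Good
  1     0     |Delta| > 0.5      Unsure
  1     1     Delta < 0          Good
  1     1     Delta >= 0         Bad
  ====  ====  =================  ======

The clinical decision itself is scored against outcomes alone: Good iff
the outcome was the desirable (LC=1, RP2=0) class, else Bad.
"""

from __future__ import annotations

import enum

import numpy as np

__all__ = ["EvalTag", "similarity_score", "self_evaluate", "evaluate_cohort",
           "clinical_baseline_tag"]


class EvalTag(enum.Enum):
    GOOD = "Good"
    BAD = "Bad"
    UNSURE = "Unsure"


def similarity_score(ai_doses, clinical_doses) -> float:
    """RMSE (Gy/frac) between AI recommendations and clinical decisions."""
    ai = np.asarray(ai_doses, dtype=float)
    cl = np.asarray(clinical_doses, dtype=float)
    if ai.ndim != 1 or ai.shape != cl.shape:
        raise ValueError("dose vectors must be 1-D and of equal length")
    if ai.size == 0:
        raise ValueError("dose vectors must be nonempty")
    return float(np.sqrt(np.mean((ai - cl) ** 2)))


def self_evaluate(lc: int, rp2: int, delta: float) -> EvalTag:
    """Tag one recommendation from outcomes and Delta = AI - clinical dose."""
    if lc not in (0, 1) or rp2 not in (0, 1):
        raise ValueError("lc and rp2 must be binary")
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    if lc == 0 and rp2 == 0:
        return EvalTag.GOOD if delta > 0 else EvalTag.BAD
    if lc == 0 and rp2 == 1:
        return EvalTag.GOOD if delta < -0.1 else EvalTag.BAD
    if lc == 1 and rp2 == 0:
        return EvalTag.GOOD if abs(delta) <= 0.5 else EvalTag.UNSURE
    return EvalTag.GOOD if delta < 0 else EvalTag.BAD


def clinical_baseline_tag(lc: int, rp2: int) -> EvalTag:
    """Score the clinic's own decision from outcomes alone."""
    if lc not in (0, 1) or rp2 not in (0, 1):
        raise ValueError("lc and rp2 must be binary")
    return EvalTag.GOOD if (lc == 1 and rp2 == 0) else EvalTag.BAD


def evaluate_cohort(records, recommendations: dict) -> dict:
    """Evaluate AI recommendations against a cohort.

    ``recommendations`` maps patient_id to the (ensemble-averaged) AI dose
    in Gy/frac.  Returns a report with Good/Bad/Unsure percentages for the
    AI and the clinical baseline, and the similarity score.
    """
    if not recommendations:
        raise ValueError("no recommendations to evaluate")
    ids = {r.patient_id for r in records}
    missing = set(recommendations) - ids
    if missing or not set(recommendations) >= ids:
        raise ValueError(
            f"patient id mismatch: unknown={sorted(missing)}, "
            f"missing={sorted(ids - set(recommendations))}")

    tags = {t: 0 for t in EvalTag}
    base = {t: 0 for t in EvalTag}
    ai, cl = [], []
    for r in records:
        dose = float(recommendations[r.patient_id])
        tags[self_evaluate(r.lc, r.rp2, dose - r.clinical_dose)] += 1
        base[clinical_baseline_tag(r.lc, r.rp2)] += 1
        ai.append(dose)
        cl.append(r.clinical_dose)
    n = len(records)
    report = {
        "n_patients": n,
        "similarity_score_gy_per_frac": similarity_score(ai, cl),
        "ai": {t.value: 100.0 * tags[t] / n for t in EvalTag},
        "clinical_baseline": {t.value: 100.0 * base[t] / n for t in EvalTag},
    }
    report["ai_rounded"] = {k: int(round(v)) for k, v in report["ai"].items()}
    report["clinical_baseline_rounded"] = {
        k: int(round(v)) for k, v in report["clinical_baseline"].items()}
    return report


def format_report(report: dict) -> str:
    """Human-readable table for a report produced by evaluate_cohort."""
    lines = [
        f"patients evaluated : {report['n_patients']}",
        f"similarity score   : {report['similarity_score_gy_per_frac']:.3f} Gy/frac",
        f"{'':18s}   Good   Bad    Unsure",
    ]
    for label, key in (("AI recommendation", "ai"), ("clinical baseline", "clinical_baseline")):
        row = report[key]
        lines.append(f"{label:18s}  {row['Good']:5.1f}% {row['Bad']:5.1f}% {row['Unsure']:5.1f}%")
    return "\n".join(lines)
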