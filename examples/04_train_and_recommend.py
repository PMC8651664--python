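"""Train a small double-DQN ensemble in the radiotherapy environment and
recommend adapted doses.

Fits the environment (biomarker transition net + logistic outcome
estimator) on a synthetic cohort, trains a 2-member ensemble with the
quantum controller backend, and prints per-patient recommendations with
the ensemble SEM and q-value confidence.  Sizes are kept small so the
script runs in under a minute.
"""

import numpy as np

from qdrlart import (
    Arte,
    CohortConfig,
    EstimatorConfig,
    RadiobioParams,
    TrainConfig,
    TransitionModel,
    fit_outcome_estimator,
    generate_cohort,
    recommend,
)
from qdrlart.agent import train_ensemble
from qdrlart.qdecision import DoseGrid

cohort = generate_cohort(CohortConfig(n_patients=150, seed=3))
grid = DoseGrid(5, 1.0, 4.1)
rb = RadiobioParams()

transition = TransitionModel(seed=0, dose_range=(grid.d_min, grid.d_max))
transition.fit(cohort, epochs=300)
estimator = fit_outcome_estimator(cohort, EstimatorConfig(), rb)
print("environment fitted (transition net + outcome estimator)")

cfg = TrainConfig(episodes=150, ensemble_size=2, seed=0, shots=256)
agents, traces = train_ensemble(cohort, lambda: Arte(transition, estimator, rb), cfg, grid=grid)
lengths = [len(t) for t in traces[0]]
print(f"member 0: {len(lengths)} episodes, mean length {np.mean(lengths):.1f} steps")

print("\npatient  clinical  AI dose  SEM    q-conf  (LC,RP2)")
for r in cohort[:8]:
    rec = recommend(agents, r.state_mid)
    print(f"{r.patient_id}    {r.clinical_dose:5.2f}    {rec.mean_dose:5.2f}  "
          f"{rec.sem:5.3f}  {np.mean(rec.member_q):6.2f}  ({r.lc},{r.rp2})")
print("\nA positive q-value marks a decision the agent expects to reach the")
print("clinically desirable outcome (p_LC > 0.7, p_RP2 < 0.172).")
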