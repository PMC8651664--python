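"""Dose-response building blocks: EQD2, gEUD, the gEUD update and reward.

Prints the fractionation-corrected dose, the generalized equivalent
uniform dose for tumor (a=-10, cold-spot dominated) and lung (a=1, mean
dose), one adaptation-period gEUD update, the logistic outcome
probability, and the reward the agent would collect.
"""

from qdrlart import (
    LogisticParams,
    RadiobioParams,
    compute_eqd2,
    compute_geud,
    geud_transition,
    outcome_probability,
    reward,
)

# EQD2: 30 fractions of 2 Gy is the reference schedule, so EQD2 = 60 Gy.
print("EQD2(2.0 Gy/frac, 30 frac, a/b=10) =", compute_eqd2(2.0, 30, 10.0), "Gy")
print("EQD2(3.0 Gy/frac, 10 frac, a/b=10) =", compute_eqd2(3.0, 10, 10.0), "Gy")

# gEUD over a two-voxel distribution: the tumor exponent punishes cold spots.
voxels = [(0.5, 40.0), (0.5, 60.0)]
print("tumor gEUD (a=-10):", round(compute_geud(voxels, -10.0), 3), "Gy  <- near the 40 Gy cold spot")
print("lung  gEUD (a=+1): ", round(compute_geud(voxels, 1.0), 3), "Gy  <- plain mean dose")

# One two-week adaptation period at 2.5 Gy/frac raises the tumor gEUD.
rb = RadiobioParams()
g_next = geud_transition(44.0, 2.5, rb.dt_weeks, rb, "tumor")
print("tumor gEUD after one period at 2.5 Gy/frac: 44.0 ->", round(g_next, 3), "Gy")

# Outcome probability rises with accumulated dose (T < 0 by convention).
p_lc = outcome_probability(g_next, LogisticParams(mu=45.0, T=-5.0))
p_rp2 = outcome_probability(18.0, LogisticParams(mu=32.0, T=-5.0))
print(f"p_LC = {p_lc:.3f}, p_RP2 = {p_rp2:.3f}")

# Reward = P+ plus +10 (clinical region), +5 (computational) or -1.
print("reward:", round(reward(p_lc, p_rp2), 3),
      " (base utility plus the region bonus)")
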