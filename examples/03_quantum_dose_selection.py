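"""Quantum dose selection: controller circuit, CU3 noise, Grover, QASM.

Selects an eigen-dose on the 5-qubit (32-level) register three ways:
the fixed-depth controller circuit (deterministic), the same circuit with
CU3 gates injecting decision stochasticity, and Grover amplification.
"""

import math

import numpy as np

from qdrlart import (
    build_controller_circuit,
    build_dose_grid,
    export_qasm,
    grover_amplify,
    grover_iterations,
    select_dose,
    simulate,
)

grid = build_dose_grid(5, 1.0, 4.1)
print(f"dose grid: {grid.n_levels} eigen-doses from {grid.d_min} to {grid.d_max} Gy/frac")

# Greedy selection through the controller circuit: q-values peak at index 21.
q_values = np.zeros(32)
q_values[21] = 1.0
decision = select_dose(q_values, grid, backend="controller-sim", seed=0)
print(f"controller-sim picked index {decision.index} "
      f"({grid.bitstring(decision.index)}) = {decision.dose_gy:.1f} Gy/frac")

# The controller is 4 gate layers for any register width.
circ = build_controller_circuit("10101")
print(f"controller on {circ.n_qubits} qubits, {circ.n_layers} gate layers;"
      f" noiseless counts: {simulate(circ, shots=1024, seed=0).counts}")

# CU3(theta, phi, lambda) replaces CNOT: each marked bit flips with
# probability sin^2(theta/2), modeling a dubious clinical situation.
noisy = build_controller_circuit("10101", cu3_angles=(math.pi / 3, 0.0, math.pi))
counts = simulate(noisy, shots=1024, seed=0).counts
top = sorted(counts.items(), key=lambda kv: -kv[1])[:3]
print("CU3(pi/3) counts (top 3):", top,
      f"- per-bit flip prob {math.sin(math.pi/6)**2:.2f}")

# Grover amplification: k = floor(pi/4 sqrt(32)) = 4 iterations.
k = grover_iterations(grid.n_levels)
state = grover_amplify(grid, 21, k)
print(f"Grover with k={k}: marked-state probability "
      f"{abs(state.amplitudes[21])**2:.5f}")

print("\nOpenQASM 2.0 export (first 6 lines):")
print("\n".join(export_qasm(circ).splitlines()[:6]))
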