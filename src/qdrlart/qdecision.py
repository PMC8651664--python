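"""Quantum dose-decision layer.

Dose options live on an n-qubit register: each computational basis state
|d> (an "eigen-dose") indexes one level of an evenly spaced dose grid, and
the superposition |D> represents all options at once.  Selecting a dose is
(1) amplifying the greedy eigen-dose and (2) measuring.

Two amplification mechanisms are provided:

* **Controller circuit** — a fixed-depth circuit on 2n qubits (control +
  main registers).  The marked state is prepared on the control with
  pre-control X gates, an X layer flips the main register to |1...1>,
  CNOTs (control_i -> main_i) write the complement of the marked string,
  and a second X layer restores it; measuring the main register then
  yields the marked state with probability 1.  Its depth (4 gate layers)
  does not grow with n, which is what makes it viable on near-term
  hardware where Grover circuits exceed the coherence length.
* **Grover amplification** — textbook amplitude amplification; after k
  iterations the marked amplitude is sin((2k+1) * arcsin(1/sqrt(N))).

Replacing the CNOTs with CU3(theta, phi, lambda) gates injects tunable
decision stochasticity: a control qubit in |1> then flips its target only
with probability sin^2(theta/2).  Circuits export to OpenQASM 2.0.

Bit convention: character 0 of a bitstring is the most significant bit of
the dose index (``index = int(bits, 2)``).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DoseGrid", "DoseDecision", "QuantumDoseState", "Gate", "ControllerCircuit",
    "MeasurementResult", "build_dose_grid", "build_controller_circuit",
    "apply_gate", "simulate", "grover_amplify", "grover_iterations",
    "select_dose", "export_qasm", "import_qasm",
]


@dataclass(frozen=True)
class DoseGrid:
    """2**n_qubits evenly spaced dose levels on [d_min, d_max] Gy/frac."""

    n_qubits: int
    d_min: float
    d_max: float

    def __post_init__(self):
        if self.n_qubits < 1:
            raise ValueError("n_qubits must be >= 1")
        if not self.d_min < self.d_max:
            raise ValueError("d_min must be < d_max")

    @property
    def n_levels(self) -> int:
        return 2 ** self.n_qubits

    @property
    def levels(self) -> np.ndarray:
        return np.linspace(self.d_min, self.d_max, self.n_levels)

    def dose(self, index: int) -> float:
        if not 0 <= index < self.n_levels:
            raise ValueError(f"dose index {index} out of range [0, {self.n_levels})")
        return float(self.levels[index])

    def index_of(self, dose: float) -> int:
        """Nearest grid index for a dose value."""
        return int(np.argmin(np.abs(self.levels - dose)))

    def bitstring(self, index: int) -> str:
        if not 0 <= index < self.n_levels:
            raise ValueError(f"dose index {index} out of range [0, {self.n_levels})")
        return format(index, f"0{self.n_qubits}b")


def build_dose_grid(n_qubits: int, d_min: float, d_max: float) -> DoseGrid:
    return DoseGrid(n_qubits, d_min, d_max)


DEFAULT_GRID = DoseGrid(5, 1.0, 4.1)


@dataclass(frozen=True)
class DoseDecision:
    """A measured eigen-dose: grid index plus its Gy/frac value."""

    index: int
    dose_gy: float


@dataclass(frozen=True)
class QuantumDoseState:
    """Amplitude vector over the 2**n eigen-dose basis states."""

    amplitudes: np.ndarray

    def __post_init__(self):
        amp = np.asarray(self.amplitudes, dtype=complex)
        n = int(np.log2(amp.size))
        if 2 ** n != amp.size:
            raise ValueError("amplitude vector length must be a power of 2")
        if abs(np.sum(np.abs(amp) ** 2) - 1.0) > 1e-9:
            raise ValueError("state is not normalized")
        object.__setattr__(self, "amplitudes", amp)

    @property
    def probabilities(self) -> np.ndarray:
        return np.abs(self.amplitudes) ** 2


# ---------------------------------------------------------------------------
# Gates and statevector simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gate:
    name: str                 # 'x', 'cx' or 'cu3'
    qubits: tuple[int, ...]
    params: tuple[float, ...] = ()


@dataclass
class ControllerCircuit:
    """Gate list over 2n qubits (qubits 0..n-1 control, n..2n-1 main)."""

    n: int                    # qubits per register
    marked: str
    gates: list[Gate] = field(default_factory=list)
    measured: tuple[int, ...] = ()   # qubits measured, MSB first

    @property
    def n_qubits(self) -> int:
        return 2 * self.n

    @property
    def n_layers(self) -> int:
        """Number of parallel gate layers, constant in n: pre-control X,
        first reverse layer, entangling layer, second reverse layer."""
        return 4


def build_controller_circuit(marked: str, cu3_angles: tuple[float, float, float] | None = None,
                             ) -> ControllerCircuit:
    """Controller circuit selecting ``marked`` on the main register.

    Layers (depth fixed for any n): (1) pre-control X gates preparing the
    marked state on the control, in parallel with the first reverse (X)
    layer on the main; (2) CNOT (or CU3) from each control qubit to its
    main partner; (3) the second reverse layer on the main; then main-
    register measurement.
    """
    if not marked or any(c not in "01" for c in marked):
        raise ValueError(f"marked state must be a nonempty bitstring, got {marked!r}")
    n = len(marked)
    circ = ControllerCircuit(n=n, marked=marked)
    for i, c in enumerate(marked):        # layer 1a: pre-control gates
        if c == "1":
            circ.gates.append(Gate("x", (i,)))
    for i in range(n):                    # layer 1b: first reverse layer on main
        circ.gates.append(Gate("x", (n + i,)))
    for i in range(n):                    # layer 2: entangle control -> main
        if cu3_angles is None:
            circ.gates.append(Gate("cx", (i, n + i)))
        else:
            circ.gates.append(Gate("cu3", (i, n + i), tuple(float(a) for a in cu3_angles)))
    for i in range(n):                    # layer 3: second reverse layer
        circ.gates.append(Gate("x", (n + i,)))
    circ.measured = tuple(range(n, 2 * n))
    return circ


def _u3_matrix(theta: float, phi: float, lam: float) -> np.ndarray:
    return np.array([
        [math.cos(theta / 2), -np.exp(1j * lam) * math.sin(theta / 2)],
        [np.exp(1j * phi) * math.sin(theta / 2),
         np.exp(1j * (phi + lam)) * math.cos(theta / 2)],
    ])


def apply_gate(state: np.ndarray, gate: Gate, n_qubits: int) -> np.ndarray:
    """Apply one gate to a 2**n_qubits statevector (qubit 0 = MSB)."""
    psi = state.reshape([2] * n_qubits)
    if gate.name == "x":
        (q,) = gate.qubits
        psi = np.flip(psi, axis=q)
    elif gate.name in ("cx", "cu3"):
        c, t = gate.qubits
        u = _u3_matrix(math.pi, 0.0, math.pi) if gate.name == "cx" else _u3_matrix(*gate.params)
        psi = psi.copy()
        sel = [slice(None)] * n_qubits
        sel[c] = 1
        block = np.moveaxis(psi[tuple(sel)], t if t < c else t - 1, 0)
        block[...] = np.tensordot(u, block, axes=(1, 0))
    else:
        raise ValueError(f"unsupported gate {gate.name!r}")
    out = psi.reshape(-1)
    norm = np.sum(np.abs(out) ** 2)
    if abs(norm - 1.0) > 1e-9:
        raise AssertionError("state norm drifted after gate application")
    return out


@dataclass(frozen=True)
class MeasurementResult:
    """Shot counts per bitstring and the selected eigen-dose index
    (argmax count; ties broken toward the lowest index)."""

    counts: dict
    shots: int
    selected_index: int


def statevector(circuit: ControllerCircuit) -> np.ndarray:
    nq = circuit.n_qubits
    state = np.zeros(2 ** nq, dtype=complex)
    state[0] = 1.0
    for gate in circuit.gates:
        state = apply_gate(state, gate, nq)
    return state


def measurement_probabilities(circuit: ControllerCircuit) -> np.ndarray:
    """Probability of each measured-register bitstring (marginalized)."""
    state = statevector(circuit)
    nq = circuit.n_qubits
    probs = (np.abs(state) ** 2).reshape([2] * nq)
    keep = circuit.measured
    drop = tuple(q for q in range(nq) if q not in keep)
    marg = probs.sum(axis=drop) if drop else probs
    # measured qubits are already in MSB-first order for the dose index
    return marg.reshape(-1)


def simulate(circuit: ControllerCircuit, shots: int = 1024, seed=None) -> MeasurementResult:
    """Noiseless sampling of the circuit's measured register."""
    if shots < 1:
        raise ValueError("shots must be >= 1")
    probs = measurement_probabilities(circuit)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(shots, probs)
    n = len(circuit.measured)
    counts = {format(i, f"0{n}b"): int(c) for i, c in enumerate(draws) if c > 0}
    best = max(counts, key=lambda b: (counts[b], -int(b, 2)))
    return MeasurementResult(counts=counts, shots=shots, selected_index=int(best, 2))


# ---------------------------------------------------------------------------
# Grover amplification
# ---------------------------------------------------------------------------

def grover_iterations(n_levels: int) -> int:
    """Default iteration schedule floor(pi/4 * sqrt(N))."""
    return int(math.floor(math.pi / 4.0 * math.sqrt(n_levels)))


def grover_amplify(grid: DoseGrid, marked: int, iterations: int) -> QuantumDoseState:
    """State after k Grover iterations marking one eigen-dose.

    The marked amplitude is sin((2k+1) * arcsin(1/sqrt(N))) and the
    N - 1 unmarked amplitudes stay equal (closed form of the rotation in
    the two-dimensional marked/unmarked subspace).
    """
    n_levels = grid.n_levels
    if not 0 <= marked < n_levels:
        raise ValueError(f"marked index {marked} out of range [0, {n_levels})")
    if iterations < 0:
        raise ValueError("iteration count must be >= 0")
    theta = math.asin(1.0 / math.sqrt(n_levels))
    amp = np.full(n_levels, 0.0, dtype=complex)
    a_marked = math.sin((2 * iterations + 1) * theta)
    if n_levels > 1:
        amp[:] = math.cos((2 * iterations + 1) * theta) / math.sqrt(n_levels - 1)
    amp[marked] = a_marked
    return QuantumDoseState(amp)


# ---------------------------------------------------------------------------
# Dose selection
# ---------------------------------------------------------------------------

def select_dose(q_values, grid: DoseGrid = DEFAULT_GRID, backend: str = "controller-sim",
                shots: int = 1024, seed=None,
                cu3_angles: tuple[float, float, float] | None = None,
                external_runner=None) -> DoseDecision:
    """Greedy eigen-dose selection through the quantum layer.

    The argmax of the q-values (ties -> lowest index) marks the eigen-dose,
    which is amplified by the chosen backend and measured.  Under the
    noiseless controller backend the measured dose always equals the
    argmax dose.

    ``backend='external'`` delegates to ``external_runner(qasm, shots)``,
    which must return a ``{bitstring: count}`` histogram (hardware hook;
    no vendor calls are bundled).
    """
    q = np.asarray(q_values, dtype=float)
    if q.shape != (grid.n_levels,):
        raise ValueError(f"q_values must have length {grid.n_levels}, got {q.shape}")
    marked = int(np.argmax(q))  # np.argmax returns the first (lowest) maximizer
    if backend == "controller-sim":
        circ = build_controller_circuit(grid.bitstring(marked), cu3_angles=cu3_angles)
        result = simulate(circ, shots=shots, seed=seed)
        idx = result.selected_index
    elif backend == "grover-sim":
        state = grover_amplify(grid, marked, grover_iterations(grid.n_levels))
        rng = np.random.default_rng(seed)
        draws = rng.multinomial(shots, state.probabilities)
        idx = int(max(range(grid.n_levels), key=lambda i: (draws[i], -i)))
    elif backend == "external":
        if external_runner is None:
            raise ValueError("backend 'external' requires an external_runner callable")
        circ = build_controller_circuit(grid.bitstring(marked), cu3_angles=cu3_angles)
        counts = external_runner(export_qasm(circ), shots)
        idx = int(max(counts, key=lambda b: (counts[b], -int(b, 2))), 2)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return DoseDecision(index=idx, dose_gy=grid.dose(idx))


# ---------------------------------------------------------------------------
# OpenQASM 2.0 export / import
# ---------------------------------------------------------------------------

def export_qasm(circuit: ControllerCircuit) -> str:
    """Emit the circuit as OpenQASM 2.0 text."""
    lines = [
        "OPENQASM 2.0;",
        'include "qelib1.inc";',
        f"qreg q[{circuit.n_qubits}];",
        f"creg c[{len(circuit.measured)}];",
    ]
    for g in circuit.gates:
        if g.name == "x":
            lines.append(f"x q[{g.qubits[0]}];")
        elif g.name == "cx":
            lines.append(f"cx q[{g.qubits[0]}],q[{g.qubits[1]}];")
        elif g.name == "cu3":
            th, ph, la = g.params
            lines.append(f"cu3({th!r},{ph!r},{la!r}) q[{g.qubits[0]}],q[{g.qubits[1]}];")
        else:
            raise ValueError(f"cannot export gate {g.name!r}")
    for i, q in enumerate(circuit.measured):
        lines.append(f"measure q[{q}] -> c[{i}];")
    return "\n".join(lines) + "\n"


_QASM_GATE = re.compile(
    r"^(x|cx|cu3)\s*(?:\(([^)]*)\))?\s+q\[(\d+)\](?:\s*,\s*q\[(\d+)\])?;$")
_QASM_MEASURE = re.compile(r"^measure\s+q\[(\d+)\]\s*->\s*c\[(\d+)\];$")


def import_qasm(text: str) -> ControllerCircuit:
    """Parse OpenQASM 2.0 produced by :func:`export_qasm` back to a circuit."""
    gates: list[Gate] = []
    measured: dict[int, int] = {}
    n_qubits = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(("OPENQASM", "include", "creg", "//")):
            continue
        m = re.match(r"^qreg\s+q\[(\d+)\];$", line)
        if m:
            n_qubits = int(m.group(1))
            continue
        m = _QASM_MEASURE.match(line)
        if m:
            measured[int(m.group(2))] = int(m.group(1))
            continue
        m = _QASM_GATE.match(line)
        if not m:
            raise ValueError(f"cannot parse QASM line: {line!r}")
        name, params, q0, q1 = m.groups()
        qubits = (int(q0),) if q1 is None else (int(q0), int(q1))
        p = tuple(float(x) for x in params.split(",")) if params else ()
        gates.append(Gate(name, qubits, p))
    if n_qubits is None:
        raise ValueError("QASM text has no qreg declaration")
    circ = ControllerCircuit(n=n_qubits // 2, marked="", gates=gates,
                             measured=tuple(measured[i] for i in sorted(measured)))
    return circ
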