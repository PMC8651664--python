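"""Quantum layer: dose grid, controller circuit, Grover, QASM round-trip."""

import math

import numpy as np
import pytest

from qdrlart.qdecision import (
    DoseGrid,
    Gate,
    apply_gate,
    build_controller_circuit,
    build_dose_grid,
    export_qasm,
    grover_amplify,
    grover_iterations,
    import_qasm,
    measurement_probabilities,
    select_dose,
    simulate,
)


class TestDoseGrid:
    def test_five_qubits_give_32_levels(self):
        grid = build_dose_grid(5, 1.0, 4.1)
        assert grid.n_levels == 32
        assert grid.levels[0] == 1.0 and grid.levels[-1] == pytest.approx(4.1)
        assert np.diff(grid.levels) == pytest.approx(0.1)

    def test_single_qubit_grid(self):
        grid = build_dose_grid(1, 1.0, 2.0)
        assert list(grid.levels) == [1.0, 2.0]

    def test_index_dose_bijection(self):
        grid = build_dose_grid(3, 0.0, 7.0)
        for i in range(8):
            assert grid.index_of(grid.dose(i)) == i

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            build_dose_grid(5, 2.0, 2.0)


class TestControllerCircuit:
    def test_structure_for_10101(self):
        circ = build_controller_circuit("10101")
        assert circ.n_qubits == 10
        assert sum(g.name == "cx" for g in circ.gates) == 5
        # 3 pre-control X (the set bits) + 2 * 5 reverse X gates
        assert sum(g.name == "x" for g in circ.gates) == 13
        assert circ.n_layers == 4

    def test_depth_constant_in_n(self):
        for marked in ("0", "10", "110010", "10101010"):
            assert build_controller_circuit(marked).n_layers == 4

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_noiseless_selection_exhaustive(self, n):
        """Every marked string on up to 5 qubits is measured with
        probability 1 (the double-complement identity)."""
        for idx in range(2 ** n):
            marked = format(idx, f"0{n}b")
            probs = measurement_probabilities(build_controller_circuit(marked))
            assert probs[idx] == pytest.approx(1.0, abs=1e-12)

    def test_simulation_concentrates_all_shots(self):
        result = simulate(build_controller_circuit("10101"), shots=1024, seed=0)
        assert result.counts == {"10101": 1024}
        assert result.selected_index == 0b10101

    def test_cu3_pi_reduces_to_cnot(self):
        marked = "101"
        plain = measurement_probabilities(build_controller_circuit(marked))
        cu3 = measurement_probabilities(
            build_controller_circuit(marked, cu3_angles=(math.pi, 0.0, math.pi)))
        assert cu3 == pytest.approx(plain, abs=1e-12)

    def test_cu3_half_pi_flips_half_the_time(self):
        # one qubit marked |1>: the CU3 target flips with prob sin^2(theta/2)
        circ = build_controller_circuit("1", cu3_angles=(math.pi / 2, 0.0, math.pi))
        result = simulate(circ, shots=100_000, seed=1)
        freq = result.counts.get("1", 0) / 100_000
        assert freq == pytest.approx(math.sin(math.pi / 4) ** 2, abs=0.01)

    def test_invalid_marked_string_rejected(self):
        with pytest.raises(ValueError):
            build_controller_circuit("10102")
        with pytest.raises(ValueError):
            build_controller_circuit("")

    def test_gate_application_preserves_norm(self):
        state = np.zeros(8, dtype=complex)
        state[0] = 1.0
        for gate in (Gate("x", (0,)), Gate("cx", (0, 2)), Gate("cu3", (0, 1), (0.7, 0.2, 0.9))):
            state = apply_gate(state, gate, 3)
            assert np.sum(np.abs(state) ** 2) == pytest.approx(1.0, abs=1e-12)


def _grover_operator_sim(n_levels: int, marked: int, k: int) -> np.ndarray:
    """Independent oracle: explicit oracle+diffusion matrix iteration."""
    psi = np.full(n_levels, 1.0 / math.sqrt(n_levels))
    oracle = np.eye(n_levels)
    oracle[marked, marked] = -1.0
    diffusion = 2.0 * np.full((n_levels, n_levels), 1.0 / n_levels) - np.eye(n_levels)
    for _ in range(k):
        psi = diffusion @ (oracle @ psi)
    return psi


class TestGrover:
    def test_exact_on_four_items(self):
        grid = build_dose_grid(2, 0.0, 3.0)
        state = grover_amplify(grid, 2, 1)
        assert abs(state.amplitudes[2]) ** 2 == pytest.approx(1.0, abs=1e-12)

    def test_zero_iterations_is_uniform(self):
        grid = build_dose_grid(3, 0.0, 7.0)
        state = grover_amplify(grid, 5, 0)
        assert state.probabilities == pytest.approx(np.full(8, 1 / 8), abs=1e-12)

    def test_closed_form_reference_value(self):
        grid = build_dose_grid(5, 1.0, 4.1)
        state = grover_amplify(grid, 7, 4)
        expected = math.sin(9 * math.asin(1 / math.sqrt(32))) ** 2
        assert abs(state.amplitudes[7]) ** 2 == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.99918, abs=5e-5)

    @pytest.mark.parametrize("n_qubits", [1, 2, 3, 4, 5])
    @pytest.mark.parametrize("k", list(range(7)))
    def test_matches_explicit_operator_simulation(self, n_qubits, k):
        n_levels = 2 ** n_qubits
        marked = n_levels // 2
        grid = build_dose_grid(n_qubits, 0.0, 1.0)
        closed = grover_amplify(grid, marked, k).amplitudes.real
        explicit = _grover_operator_sim(n_levels, marked, k)
        assert closed == pytest.approx(explicit, abs=1e-9)

    def test_unit_norm(self):
        grid = build_dose_grid(4, 0.0, 1.0)
        for k in range(5):
            state = grover_amplify(grid, 3, k)
            assert np.sum(state.probabilities) == pytest.approx(1.0, abs=1e-9)

    def test_marked_out_of_range(self):
        with pytest.raises(ValueError):
            grover_amplify(build_dose_grid(2, 0.0, 1.0), 4, 1)


class TestSelectDose:
    GRID = build_dose_grid(5, 1.0, 4.1)

    def test_controller_backend_returns_argmax(self):
        q = np.zeros(32)
        q[21] = 1.0   # "10101"
        decision = select_dose(q, self.GRID, backend="controller-sim", seed=0)
        assert decision.index == 21
        assert decision.dose_gy == pytest.approx(self.GRID.dose(21))

    def test_tie_breaks_to_lowest_index(self):
        decision = select_dose(np.zeros(32), self.GRID, backend="controller-sim", seed=0)
        assert decision.index == 0

    def test_grover_backend_selects_argmax_with_high_frequency(self):
        q = np.zeros(32)
        q[13] = 2.0
        hits = sum(
            select_dose(q, self.GRID, backend="grover-sim", shots=256, seed=s).index == 13
            for s in range(100))
        assert hits >= 99

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            select_dose(np.zeros(8), self.GRID)

    def test_external_backend_uses_runner(self):
        q = np.zeros(32)
        q[5] = 1.0
        seen = {}

        def runner(qasm, shots):
            seen["qasm"] = qasm
            return {"00101": shots}

        decision = select_dose(q, self.GRID, backend="external", external_runner=runner)
        assert decision.index == 5
        assert "OPENQASM 2.0" in seen["qasm"]


class TestQasm:
    def test_structural_counts(self):
        text = export_qasm(build_controller_circuit("101"))
        assert "qreg q[6];" in text
        assert text.count("cx ") == 3
        assert text.count("measure") == 3

    def test_round_trip_reproduces_distribution(self):
        circ = build_controller_circuit("1101")
        back = import_qasm(export_qasm(circ))
        assert measurement_probabilities(back) == pytest.approx(
            measurement_probabilities(circ), abs=1e-12)

    def test_cu3_gate_name_exported(self):
        circ = build_controller_circuit("10", cu3_angles=(0.3, 0.1, 0.2))
        text = export_qasm(circ)
        assert "cu3(0.3,0.1,0.2)" in text
        back = import_qasm(text)
        assert measurement_probabilities(back) == pytest.approx(
            measurement_probabilities(circ), abs=1e-12)

    def test_unparseable_line_rejected(self):
        with pytest.raises(ValueError, match="parse"):
            import_qasm("OPENQASM 2.0;\nqreg q[2];\nh q[0];")
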