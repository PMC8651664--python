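"""Shared fixtures: small synthetic cohorts and a deterministic toy
environment with an enumeration oracle for the optimal dose."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from qdrlart.arte import OutcomeEstimate, StepResult
from qdrlart.cohort import CohortConfig, PatientRecord, PatientState, generate_cohort
from qdrlart.qdecision import DoseGrid

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

GRID = DoseGrid(5, 1.0, 4.1)


def toy_target_dose(state: PatientState) -> float:
    """Ground-truth optimal dose of the toy environment (linear in IP10)."""
    return 1.0 + 3.1 * state.ip10


class ToyEnv:
    """Deterministic one-step environment: reward = 5 - 10 (d - d*(s))^2,
    maximized at the state-dependent dose d*(s)."""

    def __init__(self):
        self._state = None

    def reset(self, record):
        self._state = record.state_mid
        return self._state

    def step(self, dose_gy: float) -> StepResult:
        s = self._state
        r = 5.0 - 10.0 * (dose_gy - toy_target_dose(s)) ** 2
        return StepResult(s, OutcomeEstimate(0.5, 0.5), float(r), True)


class NeverTerminatingEnv:
    """Constant-reward environment that never reaches a terminal outcome."""

    def __init__(self):
        self._state = None

    def reset(self, record):
        self._state = record.state_mid
        return self._state

    def step(self, dose_gy: float) -> StepResult:
        return StepResult(self._state, OutcomeEstimate(0.5, 0.5), 0.0, False)


def toy_state(x: float) -> PatientState:
    return PatientState(ip10=float(x), glszm_zsv=1.0, tumor_geud=30.0,
                        lung_geud=10.0, cxcr1_genotype=0)


def toy_cohort(n: int, seed: int) -> list[PatientRecord]:
    rng = np.random.default_rng(seed)
    return [PatientRecord(f"T{i:03d}", toy_state(x), toy_state(x), 2.0, 1, 0)
            for i, x in enumerate(rng.random(n))]


def oracle_best_index(state: PatientState, env=None) -> int:
    """Brute-force optimum: evaluate every eigen-dose through the
    environment and return the argmax-reward grid index."""
    env = env or ToyEnv()
    rewards = []
    for d in GRID.levels:
        env.reset(type("R", (), {"state_mid": state, "patient_id": "x"})())
        rewards.append(env.step(float(d)).reward)
    return int(np.argmax(rewards))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_patients=60, seed=11))


@pytest.fixture(scope="session")
def labeled_cohort():
    """Larger cohort for statistics on the dose-outcome relationship."""
    return generate_cohort(CohortConfig(n_patients=2000, seed=5))
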