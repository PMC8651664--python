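"""The clinical AI agent: deep Q-net, replay memory and double Q-learning.

The agent maps a 5-feature patient state to a q-value per eigen-dose of
the quantum grid, picks the greedy dose through the quantum decision
layer (amplify + measure), and learns from environment feedback with the
double-DQN rule: the online net selects the bootstrap action, the target
net evaluates it, which removes the maximization bias of vanilla DQN.

Recommendations are reported as the mean over an ensemble of identically
configured, independently seeded models, with the standard error of the
mean (SEM) as the uncertainty and each member's greedy q-value as a
confidence indicator.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from ._nn import MLP, Adam, Standardizer
from .qdecision import DEFAULT_GRID, DoseDecision, DoseGrid, select_dose

__all__ = [
    "TrainConfig", "ReplayBuffer", "double_q_target", "act",
    "DQNAgent", "train", "train_ensemble", "recommend", "Recommendation",
]


@dataclass
class TrainConfig:
    gamma: float = 0.99
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    lr: float = 1e-3
    batch_size: int = 64
    target_sync: int = 100          # updates between target-net syncs
    episodes: int = 300
    max_steps: int = 10             # terminating step cap per episode
    replay_capacity: int = 10_000
    hidden: tuple[int, ...] = (64, 64, 64)
    ensemble_size: int = 5
    seed: int = 0
    backend: str = "controller-sim"
    shots: int = 1024

    def __post_init__(self):
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must be in [0, 1)")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


class ReplayBuffer:
    """Bounded FIFO of (state, action, reward, next_state, done) tuples."""

    def __init__(self, capacity: int = 10_000):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._buf: deque = deque(maxlen=capacity)

    def push(self, state, action: int, reward: float, next_state, done: bool) -> None:
        self._buf.append((np.asarray(state, float), int(action), float(reward),
                          np.asarray(next_state, float), bool(done)))

    def __len__(self) -> int:
        return len(self._buf)

    def sample(self, batch_size: int, rng) -> tuple:
        """Uniform sample without replacement within the batch."""
        idx = rng.choice(len(self._buf), size=min(batch_size, len(self._buf)),
                         replace=False)
        batch = [self._buf[i] for i in idx]
        s = np.stack([b[0] for b in batch])
        a = np.array([b[1] for b in batch])
        r = np.array([b[2] for b in batch])
        s2 = np.stack([b[3] for b in batch])
        d = np.array([b[4] for b in batch])
        return s, a, r, s2, d


def double_q_target(r: float, gamma: float, q_online_next, q_target_next,
                    done: bool) -> float:
    """Double-DQN bootstrap: ``r + gamma * Q_target[argmax Q_online]``
    (just ``r`` on terminal transitions)."""
    q_online_next = np.asarray(q_online_next, dtype=float)
    q_target_next = np.asarray(q_target_next, dtype=float)
    if q_online_next.shape != q_target_next.shape:
        raise ValueError("online and target q-vectors must have the same length")
    if done:
        return float(r)
    return float(r + gamma * q_target_next[int(np.argmax(q_online_next))])


def act(state_vec, qnet: MLP, epsilon: float, grid: DoseGrid, rng,
        backend: str = "controller-sim", shots: int = 1024) -> DoseDecision:
    """Epsilon-greedy action through the quantum decision layer."""
    if rng.random() < epsilon:
        idx = int(rng.integers(grid.n_levels))
        return DoseDecision(index=idx, dose_gy=grid.dose(idx))
    q = qnet(np.asarray(state_vec, float)[None, :])[0]
    return select_dose(q, grid, backend=backend, shots=shots,
                       seed=int(rng.integers(2 ** 31)))


@dataclass
class DQNAgent:
    """A trained Q-net plus the feature standardizer and dose grid."""

    qnet: MLP
    scaler: Standardizer
    grid: DoseGrid

    def q_values(self, state) -> np.ndarray:
        vec = state.as_vector() if hasattr(state, "as_vector") else np.asarray(state, float)
        return self.qnet(self.scaler.transform(vec[None, :]))[0]

    def greedy_dose(self, state) -> DoseDecision:
        q = self.q_values(state)
        idx = int(np.argmax(q))
        return DoseDecision(index=idx, dose_gy=self.grid.dose(idx))

    def to_dict(self) -> dict:
        return {"qnet": self.qnet.to_dict(), "scaler": self.scaler.to_dict(),
                "grid": {"n_qubits": self.grid.n_qubits, "d_min": self.grid.d_min,
                         "d_max": self.grid.d_max}}

    @classmethod
    def from_dict(cls, d: dict) -> "DQNAgent":
        return cls(MLP.from_dict(d["qnet"]), Standardizer.from_dict(d["scaler"]),
                   DoseGrid(**d["grid"]))


def train(cohort, env, config: TrainConfig | None = None,
          grid: DoseGrid = DEFAULT_GRID, seed: int | None = None):
    """Train one double-DQN agent in the environment.

    Per episode: sample a patient, start from the week-4 state, roll out
    at most ``max_steps`` dose decisions, store transitions, and update
    the online net from uniform replay minibatches with the double-Q
    target; the target net syncs every ``target_sync`` updates.  Fully
    deterministic given the seed under a noiseless backend.

    Returns ``(DQNAgent, traces)`` where traces is a list of
    :class:`~qdrlart.arte.EpisodeTrace`.
    """
    from .arte import EpisodeTrace

    if not cohort:
        raise ValueError("cannot train on an empty cohort")
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    feats = np.array([r.state_mid.as_vector() for r in cohort])
    scaler = Standardizer(feats)
    qnet = MLP([5, *config.hidden, grid.n_levels], activation="relu",
               rng=int(rng.integers(2 ** 31)))
    target = qnet.copy()
    opt = Adam(qnet, lr=config.lr)
    buffer = ReplayBuffer(config.replay_capacity)

    n_updates = 0
    traces: list[EpisodeTrace] = []

    for ep in range(config.episodes):
        frac = ep / max(config.episodes - 1, 1)   # linear anneal per episode
        epsilon = config.epsilon_start + frac * (config.epsilon_end - config.epsilon_start)
        record = cohort[int(rng.integers(len(cohort)))]
        state = env.reset(record)
        trace = EpisodeTrace(patient_id=record.patient_id)
        for _ in range(config.max_steps):
            svec = scaler.transform(state.as_vector()[None, :])[0]
            decision = act(svec, qnet, epsilon, grid, rng,
                           backend=config.backend, shots=config.shots)
            result = env.step(decision.dose_gy)
            trace.append(state, decision.index, decision.dose_gy, result)
            s2vec = scaler.transform(result.next_state.as_vector()[None, :])[0]
            buffer.push(svec, decision.index, result.reward, s2vec, result.done)
            state = result.next_state

            if len(buffer) >= config.batch_size:
                s, a, r, s2, d = buffer.sample(config.batch_size, rng)
                q_online_next = qnet(s2)
                q_target_next = target(s2)
                sel = np.argmax(q_online_next, axis=1)
                boot = q_target_next[np.arange(len(a)), sel]
                y = r + config.gamma * boot * (~d)
                pred, cache = qnet.forward(s)
                grad = np.zeros_like(pred)
                rows = np.arange(len(a))
                grad[rows, a] = 2.0 * (pred[rows, a] - y) / len(a)
                gW, gb, _ = qnet.backward(cache, grad)
                opt.step(gW, gb)
                n_updates += 1
                if n_updates % config.target_sync == 0:
                    target.set_weights_from(qnet)
            if result.done:
                break
        traces.append(trace)

    return DQNAgent(qnet=qnet, scaler=scaler, grid=grid), traces


def train_ensemble(cohort, env_factory, config: TrainConfig | None = None,
                   grid: DoseGrid = DEFAULT_GRID):
    """Train ``config.ensemble_size`` identically configured agents with
    member-specific seeds derived from ``config.seed``."""
    config = config or TrainConfig()
    agents, all_traces = [], []
    for m in range(config.ensemble_size):
        env = env_factory() if callable(env_factory) else env_factory
        agent, traces = train(cohort, env, config, grid=grid,
                              seed=config.seed * 10_000 + m)
        agents.append(agent)
        all_traces.append(traces)
    return agents, all_traces


@dataclass(frozen=True)
class Recommendation:
    mean_dose: float
    sem: float
    member_doses: tuple[float, ...]
    member_q: tuple[float, ...]   # greedy q-value per member (confidence)


def recommend(agents, state) -> Recommendation:
    """Ensemble dose recommendation: mean of the member greedy doses,
    SEM = sd/sqrt(m) (0 by convention for a single member), and each
    member's greedy q-value."""
    if not agents:
        raise ValueError("ensemble must be nonempty")
    doses, qvals = [], []
    for agent in agents:
        q = agent.q_values(state)
        idx = int(np.argmax(q))
        doses.append(agent.grid.dose(idx))
        qvals.append(float(q[idx]))
    doses = np.asarray(doses)
    sem = 0.0 if len(doses) < 2 else float(doses.std(ddof=1) / np.sqrt(len(doses)))
    return Recommendation(mean_dose=float(doses.mean()), sem=sem,
                          member_doses=tuple(doses), member_q=tuple(qvals))
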