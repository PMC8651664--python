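"""The artificial radiotherapy environment (ARTE).

A model-based RL environment for adaptive radiotherapy described by the
5-tuple (S, |D>, TF, P, R): patient states S, a quantum dose-decision
register |D> (see :mod:`qdrlart.qdecision`), a transition function TF, an
RT outcome estimator P and a reward function R.

Radiobiology conventions
------------------------
* EQD2 (equivalent dose in 2 Gy fractions): ``N_frac * d * (d + a/b) / (2 + a/b)``
  with the linear-quadratic alpha/beta ratio; the conversion leaves the
  physical dose unchanged exactly at d = 2 Gy per fraction.
* gEUD (generalized equivalent uniform dose): the generalized mean of
  voxel EQD2 values with organ exponent ``a`` (tumor a = -10, lung a = 1).
* The per-period gEUD update is the monotone prior
  ``g_next = g + kappa * dt * d * (1 + d / (a/b))`` — the change in gEUD
  is proportional to dose fractionation and tissue radiosensitivity.
* Outcome probabilities use the logistic ``p = 1 / (1 + exp((g - mu)/T))``
  with patient-specific (mu, T) produced by two small neural nets; T is
  constrained negative so that probability rises with accumulated dose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

from ._nn import MLP, Adam, Standardizer

__all__ = [
    "RadiobioParams", "LogisticParams", "OutcomeEstimate", "StepResult",
    "compute_eqd2", "compute_geud", "geud_transition", "outcome_probability",
    "reward", "TransitionModel", "OutcomeEstimator", "EstimatorConfig",
    "fit_outcome_estimator", "Arte", "EpisodeTrace",
    "P_LC_CLINICAL", "P_RP2_CLINICAL", "P_LC_COMPUTATIONAL", "P_RP2_COMPUTATIONAL",
]

# Desirable-outcome regions (probabilities): the clinical region earns the
# +10 bonus and terminates an episode; the computational region earns +5.
P_LC_CLINICAL = 0.70
P_RP2_CLINICAL = 0.172
P_LC_COMPUTATIONAL = 0.50
P_RP2_COMPUTATIONAL = 0.50


@dataclass(frozen=True)
class RadiobioParams:
    """Tissue radiosensitivity constants.

    alpha/beta: fractionation sensitivity (10 Gy tumor, 4 Gy lung);
    ``a``: gEUD organ exponent (-10 tumor: cold-spot dominated; 1 lung:
    mean dose); ``kappa``: per-tissue proportionality constant of the gEUD
    update, in Gy per (Gy/frac) per week; ``dt_weeks``: length of one
    adaptation period.
    """

    alpha_beta_tumor: float = 10.0
    alpha_beta_lung: float = 4.0
    a_tumor: float = -10.0
    a_lung: float = 1.0
    kappa_tumor: float = 1.0
    kappa_lung: float = 1.0
    dt_weeks: float = 2.0

    def __post_init__(self):
        if self.alpha_beta_tumor <= 0 or self.alpha_beta_lung <= 0:
            raise ValueError("alpha/beta ratios must be positive")
        if self.a_tumor == 0 or self.a_lung == 0:
            raise ValueError("gEUD exponents must be nonzero")

    def for_tissue(self, tissue: str) -> tuple[float, float, float]:
        """(alpha_beta, a, kappa) for 'tumor' or 'lung'."""
        if tissue == "tumor":
            return self.alpha_beta_tumor, self.a_tumor, self.kappa_tumor
        if tissue == "lung":
            return self.alpha_beta_lung, self.a_lung, self.kappa_lung
        raise ValueError(f"unknown tissue {tissue!r}")


@dataclass(frozen=True)
class LogisticParams:
    """Midpoint mu (Gy) and slope T (Gy) of the outcome logistic; T < 0
    makes probability increase with dose."""

    mu: float
    T: float

    def __post_init__(self):
        if self.T == 0:
            raise ValueError("logistic slope T must be nonzero")


@dataclass(frozen=True)
class OutcomeEstimate:
    p_lc: float
    p_rp2: float

    def __post_init__(self):
        for name, v in (("p_lc", self.p_lc), ("p_rp2", self.p_rp2)):
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0,1], got {v!r}")


@dataclass(frozen=True)
class StepResult:
    next_state: "object"        # cohort.PatientState
    outcome: OutcomeEstimate
    reward: float
    done: bool


def compute_eqd2(d: float, n_frac: float, alpha_beta: float) -> float:
    """Equivalent dose in 2 Gy fractions: ``N_frac * d * (d + a/b)/(2 + a/b)``."""
    if d < 0 or n_frac < 0:
        raise ValueError("dose and fraction count must be nonnegative")
    if alpha_beta <= 0:
        raise ValueError("alpha/beta must be positive")
    return n_frac * d * (d + alpha_beta) / (2.0 + alpha_beta)


def compute_geud(voxels: Sequence[tuple[float, float]], a: float) -> float:
    """gEUD = (sum_i nu_i * eqd2_i**a)**(1/a) over (volume fraction, EQD2) pairs."""
    if a == 0:
        raise ValueError("gEUD exponent a must be nonzero")
    voxels = list(voxels)
    if not voxels:
        raise ValueError("need at least one voxel")
    nu = np.array([v for v, _ in voxels], dtype=float)
    dose = np.array([e for _, e in voxels], dtype=float)
    if np.any(nu <= 0):
        raise ValueError("volume fractions must be positive")
    if abs(nu.sum() - 1.0) > 1e-6:
        raise ValueError(f"volume fractions must sum to 1, got {nu.sum()}")
    if a < 0 and np.any(dose <= 0):
        raise ValueError("zero/negative voxel dose is undefined for a < 0")
    if np.any(dose < 0):
        raise ValueError("voxel doses must be nonnegative")
    return float((nu * dose ** a).sum() ** (1.0 / a))


def geud_transition(g_prev: float, d: float, dt: float,
                    params: RadiobioParams, tissue: str) -> float:
    """One-period gEUD update ``g + kappa * dt * d * (1 + d/(a/b))``.

    Monotone nondecreasing in d and additive over consecutive equal-dose
    periods.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if g_prev < 0 or d < 0:
        raise ValueError("gEUD and dose must be nonnegative")
    alpha_beta, _, kappa = params.for_tissue(tissue)
    return g_prev + kappa * dt * d * (1.0 + d / alpha_beta)


def outcome_probability(g_week6, params: LogisticParams):
    """Logistic outcome probability ``1 / (1 + exp((g - mu)/T))``.

    Accepts scalars or arrays of week-6 gEUD.  With T < 0 the probability
    is nondecreasing in g.
    """
    g = np.asarray(g_week6, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("g_week6 must be finite")
    u = (g - params.mu) / params.T
    out = expit(-u)   # stable logistic of -u
    return float(out) if np.isscalar(g_week6) else out


def reward(p_lc: float, p_rp2: float) -> float:
    """Reward on the base utility ``P+ = p_LC * (1 - p_RP2)``.

    Top-down rule: clinical region (p_LC > 0.7 and p_RP2 < 0.172) earns
    +10; otherwise the computational region (p_LC > 0.5 and p_RP2 < 0.5)
    earns +5; everything else is penalized -1.  Total on [0,1]^2.
    """
    for name, v in (("p_lc", p_lc), ("p_rp2", p_rp2)):
        if not (np.isfinite(v) and 0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be a probability in [0,1], got {v!r}")
    base = p_lc * (1.0 - p_rp2)
    if p_lc > P_LC_CLINICAL and p_rp2 < P_RP2_CLINICAL:
        return base + 10.0
    if p_lc > P_LC_COMPUTATIONAL and p_rp2 < P_RP2_COMPUTATIONAL:
        return base + 5.0
    return base - 1.0


def in_clinical_region(outcome: OutcomeEstimate) -> bool:
    return outcome.p_lc > P_LC_CLINICAL and outcome.p_rp2 < P_RP2_CLINICAL


# ---------------------------------------------------------------------------
# Transition function TF
# ---------------------------------------------------------------------------

class TransitionModel:
    """DNN transition for the IP10 and GLSZM-ZSV biomarkers.

    Trained on longitudinal records: input = 5-feature pre state + dose
    per fraction, output = (ip10, zsv) after the period.  gEUD features
    use the process-driven :func:`geud_transition` instead, so they are
    not part of this model.
    """

    def __init__(self, hidden: tuple[int, ...] = (32, 32), seed: int = 0,
                 dose_range: tuple[float, float] | None = None):
        self.hidden = tuple(hidden)
        self.seed = seed
        self.dose_range = dose_range
        self.net: MLP | None = None
        self.x_scaler: Standardizer | None = None
        self.y_scaler: Standardizer | None = None
        self._identity = False

    @classmethod
    def identity(cls) -> "TransitionModel":
        """A toy model that returns the pre-state biomarkers unchanged."""
        model = cls()
        model._identity = True
        return model

    @property
    def is_trained(self) -> bool:
        return self._identity or self.net is not None

    def fit(self, records, epochs: int = 400, lr: float = 1e-2,
            dose_range: tuple[float, float] | None = None) -> "TransitionModel":
        if not records:
            raise ValueError("cannot fit transition model on an empty cohort")
        if dose_range is not None:
            self.dose_range = dose_range
        X = np.array([np.concatenate([r.state_pre.as_vector(), [r.clinical_dose]])
                      for r in records])
        Y = np.array([[r.state_mid.ip10, r.state_mid.glszm_zsv] for r in records])
        self.x_scaler = Standardizer(X)
        self.y_scaler = Standardizer(Y)
        Xs, Ys = self.x_scaler.transform(X), self.y_scaler.transform(Y)
        self.net = MLP([6, *self.hidden, 2], activation="tanh", rng=self.seed)
        opt = Adam(self.net, lr=lr)
        n = len(records)
        for _ in range(epochs):
            pred, cache = self.net.forward(Xs)
            grad = 2.0 * (pred - Ys) / n
            gW, gb, _ = self.net.backward(cache, grad)
            opt.step(gW, gb)
        return self

    def predict(self, state, dose: float) -> tuple[float, float]:
        """(ip10_next, zsv_next) after one adaptation period at ``dose``."""
        if not self.is_trained:
            raise RuntimeError("transition model has not been trained")
        if self.dose_range is not None:
            lo, hi = self.dose_range
            if not lo <= dose <= hi:
                raise ValueError(f"dose {dose} Gy/frac outside grid range [{lo}, {hi}]")
        if self._identity:
            return state.ip10, state.glszm_zsv
        x = np.concatenate([state.as_vector(), [dose]])[None, :]
        y = self.y_scaler.mean + self.net(self.x_scaler.transform(x))[0] * self.y_scaler.std
        ip10 = max(float(y[0]), 1e-6)
        zsv = max(float(y[1]), 0.0)
        return ip10, zsv

    def to_dict(self) -> dict:
        if self._identity:
            return {"identity": True}
        return {
            "identity": False,
            "hidden": list(self.hidden),
            "seed": self.seed,
            "dose_range": list(self.dose_range) if self.dose_range else None,
            "net": self.net.to_dict() if self.net else None,
            "x_scaler": self.x_scaler.to_dict() if self.x_scaler else None,
            "y_scaler": self.y_scaler.to_dict() if self.y_scaler else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionModel":
        if d.get("identity"):
            return cls.identity()
        model = cls(hidden=tuple(d["hidden"]), seed=d["seed"],
                    dose_range=tuple(d["dose_range"]) if d["dose_range"] else None)
        if d["net"]:
            model.net = MLP.from_dict(d["net"])
            model.x_scaler = Standardizer.from_dict(d["x_scaler"])
            model.y_scaler = Standardizer.from_dict(d["y_scaler"])
        return model


# ---------------------------------------------------------------------------
# RT outcome estimator P
# ---------------------------------------------------------------------------

@dataclass
class EstimatorConfig:
    hidden: tuple[int, ...] = (16,)
    lr: float = 3e-2
    inner_epochs: int = 60
    max_rounds: int = 25
    tol: float = 1e-5
    t_min: float = 0.5
    weight_decay: float = 1e-2   # shrinks patient-specific (mu, T) variation
    seed: int = 0


def _softplus(x):
    return np.logaddexp(0.0, x)


_sigmoid = expit


class _EndpointEstimator:
    """Logistic dose-response for one endpoint with patient-specific
    (mu, T) from two alternately trained nets; T is constrained negative."""

    def __init__(self, config: EstimatorConfig, seed_offset: int = 0):
        self.config = config
        rng = config.seed + seed_offset
        self.mu_net = MLP([3, *config.hidden, 1], activation="tanh", rng=rng)
        self.t_net = MLP([3, *config.hidden, 1], activation="tanh", rng=rng + 1)
        self.cov_scaler: Standardizer | None = None
        self.g_mean = 0.0
        self.g_std = 1.0

    # covariates: (ip10, zsv, genotype); g: endpoint gEUD
    def _mu_t(self, cov_s: np.ndarray, caches: bool = False):
        mu_raw, mu_cache = self.mu_net.forward(cov_s)
        t_raw, t_cache = self.t_net.forward(cov_s)
        mu = self.g_mean + mu_raw[:, 0] * self.g_std
        T = -(self.config.t_min + _softplus(t_raw[:, 0]) * self.g_std)
        if caches:
            return mu, T, mu_cache, t_cache, t_raw[:, 0]
        return mu, T

    def predict(self, cov: np.ndarray, g: np.ndarray) -> np.ndarray:
        cov_s = self.cov_scaler.transform(cov)
        mu, T = self._mu_t(cov_s)
        u = (np.asarray(g, dtype=float) - mu) / T
        return _sigmoid(-u)

    def logistic_params(self, cov_row: np.ndarray) -> LogisticParams:
        cov_s = self.cov_scaler.transform(np.atleast_2d(cov_row))
        mu, T = self._mu_t(cov_s)
        return LogisticParams(float(mu[0]), float(T[0]))

    def _loss_and_grads(self, cov_s, g, y, which: str):
        mu, T, mu_cache, t_cache, t_raw = self._mu_t(cov_s, caches=True)
        u = (g - mu) / T
        p = _sigmoid(-u)
        eps = 1e-9
        loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        dl_du = (y - p) / len(y)          # d(mean BCE)/du per sample
        wd = self.config.weight_decay
        if which == "mu":
            # du/dmu = -1/T ; dmu/draw = g_std
            grad_out = (dl_du * (-1.0 / T) * self.g_std)[:, None]
            gW, gb, _ = self.mu_net.backward(mu_cache, grad_out)
            gW = [g + wd * W for g, W in zip(gW, self.mu_net.W)]
            return loss, self.mu_net, gW, gb
        # du/dT = -u/T ; dT/draw = -sigmoid(t_raw)*g_std
        grad_out = (dl_du * (-u / T) * (-_sigmoid(t_raw) * self.g_std))[:, None]
        gW, gb, _ = self.t_net.backward(t_cache, grad_out)
        gW = [g + wd * W for g, W in zip(gW, self.t_net.W)]
        return loss, self.t_net, gW, gb

    def fit(self, cov: np.ndarray, g: np.ndarray, y: np.ndarray) -> "_EndpointEstimator":
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("cannot fit outcome estimator on single-class labels")
        self.cov_scaler = Standardizer(cov)
        self.g_mean, self.g_std = float(np.mean(g)), float(np.std(g) or 1.0)
        cov_s = self.cov_scaler.transform(cov)
        g = np.asarray(g, dtype=float)
        cfg = self.config
        opt_mu, opt_t = Adam(self.mu_net, lr=cfg.lr), Adam(self.t_net, lr=cfg.lr)
        prev = np.inf
        # alternating optimization: tune mu with T frozen, then swap
        for _ in range(cfg.max_rounds):
            for _ in range(cfg.inner_epochs):
                loss, _, gW, gb = self._loss_and_grads(cov_s, g, y, "mu")
                opt_mu.step(gW, gb)
            for _ in range(cfg.inner_epochs):
                loss, _, gW, gb = self._loss_and_grads(cov_s, g, y, "t")
                opt_t.step(gW, gb)
            if abs(prev - loss) < cfg.tol:
                break
            prev = loss
        return self

    def to_dict(self) -> dict:
        return {
            "mu_net": self.mu_net.to_dict(), "t_net": self.t_net.to_dict(),
            "cov_scaler": self.cov_scaler.to_dict(),
            "g_mean": self.g_mean, "g_std": self.g_std, "t_min": self.config.t_min,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_EndpointEstimator":
        obj = cls(EstimatorConfig(t_min=d["t_min"]))
        obj.mu_net = MLP.from_dict(d["mu_net"])
        obj.t_net = MLP.from_dict(d["t_net"])
        obj.cov_scaler = Standardizer.from_dict(d["cov_scaler"])
        obj.g_mean, obj.g_std = d["g_mean"], d["g_std"]
        return obj


def _cov_of_state(state) -> np.ndarray:
    return np.array([state.ip10, state.glszm_zsv, float(state.cxcr1_genotype)])


class OutcomeEstimator:
    """Joint (p_LC, p_RP2) estimator.

    p_LC is a logistic in the tumor gEUD, p_RP2 in the lung gEUD, each
    with patient-specific (mu, T) from the biomarker/genotype covariates.
    """

    def __init__(self, lc: _EndpointEstimator, rp2: _EndpointEstimator):
        self.lc = lc
        self.rp2 = rp2

    def predict_state(self, state) -> OutcomeEstimate:
        cov = _cov_of_state(state)[None, :]
        p_lc = float(self.lc.predict(cov, np.array([state.tumor_geud]))[0])
        p_rp2 = float(self.rp2.predict(cov, np.array([state.lung_geud]))[0])
        return OutcomeEstimate(p_lc, p_rp2)

    def to_dict(self) -> dict:
        return {"lc": self.lc.to_dict(), "rp2": self.rp2.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "OutcomeEstimator":
        return cls(_EndpointEstimator.from_dict(d["lc"]),
                   _EndpointEstimator.from_dict(d["rp2"]))


def fit_outcome_estimator(records, config: EstimatorConfig | None = None,
                          radbio: RadiobioParams | None = None) -> OutcomeEstimator:
    """Fit the RT outcome estimator on a cohort.

    Post-irradiation (week 6) gEUDs are reconstructed from the mid states
    by one more adaptation period at the clinical dose; LC labels then
    supervise the tumor-gEUD logistic and RP2 labels the lung-gEUD one.
    """
    if not records:
        raise ValueError("cannot fit outcome estimator on an empty cohort")
    config = config or EstimatorConfig()
    radbio = radbio or RadiobioParams()
    cov = np.array([_cov_of_state(r.state_mid) for r in records])
    g_t = np.array([geud_transition(r.state_mid.tumor_geud, r.clinical_dose,
                                    radbio.dt_weeks, radbio, "tumor") for r in records])
    g_l = np.array([geud_transition(r.state_mid.lung_geud, r.clinical_dose,
                                    radbio.dt_weeks, radbio, "lung") for r in records])
    lc = np.array([r.lc for r in records])
    rp2 = np.array([r.rp2 for r in records])
    lc_est = _EndpointEstimator(config, seed_offset=0).fit(cov, g_t, lc)
    rp2_est = _EndpointEstimator(config, seed_offset=100).fit(cov, g_l, rp2)
    return OutcomeEstimator(lc_est, rp2_est)


# ---------------------------------------------------------------------------
# Episode API
# ---------------------------------------------------------------------------

@dataclass
class EpisodeTrace:
    """Ordered transitions of one adaptation episode."""

    patient_id: str
    transitions: list[dict] = field(default_factory=list)

    def append(self, state, dose_index: int, dose_gy: float, result: StepResult):
        self.transitions.append({
            "state": list(state.as_vector()),
            "dose_index": int(dose_index),
            "dose_gy": float(dose_gy),
            "next_state": list(result.next_state.as_vector()),
            "p_lc": result.outcome.p_lc,
            "p_rp2": result.outcome.p_rp2,
            "reward": result.reward,
            "done": bool(result.done),
        })

    def __len__(self) -> int:
        return len(self.transitions)

    def to_jsonl(self) -> str:
        return "\n".join(
            json.dumps({"patient_id": self.patient_id, **t}) for t in self.transitions
        )


class Arte:
    """Step/episode interface of the artificial radiotherapy environment.

    An episode starts from a patient's mid-treatment state (the week-4
    decision point).  Each step applies the biomarker transition net and
    the gEUD update for one adaptation period, estimates (p_LC, p_RP2) at
    the new state, and scores the reward.  Episodes terminate when the
    outcome estimate enters the clinically desirable region or after
    ``max_steps`` decisions.
    """

    def __init__(self, transition: TransitionModel, estimator: OutcomeEstimator,
                 radbio: RadiobioParams | None = None, max_steps: int = 10):
        if max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        self.transition = transition
        self.estimator = estimator
        self.radbio = radbio or RadiobioParams()
        self.max_steps = max_steps
        self._state = None
        self._patient_id = None
        self._steps = 0

    # pure, stateless one-step dynamics
    def step_state(self, state, dose_gy: float) -> StepResult:
        from .cohort import PatientState  # deferred: avoids circular import
        rb = self.radbio
        ip10, zsv = self.transition.predict(state, dose_gy)
        g_t = geud_transition(state.tumor_geud, dose_gy, rb.dt_weeks, rb, "tumor")
        g_l = geud_transition(state.lung_geud, dose_gy, rb.dt_weeks, rb, "lung")
        nxt = PatientState(ip10, zsv, g_t, g_l, state.cxcr1_genotype)
        outcome = self.estimator.predict_state(nxt)
        r = reward(outcome.p_lc, outcome.p_rp2)
        return StepResult(nxt, outcome, r, in_clinical_region(outcome))

    def reset(self, record) -> "object":
        self._state = record.state_mid
        self._patient_id = record.patient_id
        self._steps = 0
        return self._state

    @property
    def state(self):
        return self._state

    def step(self, dose_gy: float) -> StepResult:
        if self._state is None:
            raise RuntimeError("call reset(record) before step()")
        result = self.step_state(self._state, dose_gy)
        self._steps += 1
        done = result.done or self._steps >= self.max_steps
        result = StepResult(result.next_state, result.outcome, result.reward, done)
        self._state = None if done else result.next_state
        return result
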