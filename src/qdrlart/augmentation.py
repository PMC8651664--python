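"""Tabular cohort augmentation with a Wasserstein GAN + gradient penalty.

Small patient cohorts under-sample the state space, so a WGAN-GP learns
the joint distribution of the tabular records and emits additional
synthetic rows (default 4000) for training the RL agent.  The critic is
trained with the two-sided gradient penalty ``lambda * E[(||grad_xhat
f(xhat)|| - 1)^2]`` on random interpolates between real and fake batches;
the generator minimizes ``-E[f(fake)]``.

The critic uses ReLU activations, whose second derivative vanishes almost
everywhere; the gradient of the penalty with respect to the critic
weights therefore has a closed form (backprop through the locally linear
network with fixed activation masks), which is what this numpy
implementation uses in place of nested automatic differentiation.

Post-processing snaps the genotype to {0,1,2}, binarizes outcomes and
clips continuous fields to the training support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import MLP, Adam

__all__ = ["GanConfig", "gradient_penalty", "WganGp", "fit_and_generate",
           "AUGMENT_FEATURES"]

AUGMENT_FEATURES = [
    "ip10_pre", "zsv_pre", "tumor_geud_pre", "lung_geud_pre", "genotype",
    "ip10_mid", "zsv_mid", "tumor_geud_mid", "lung_geud_mid",
    "clinical_dose", "lc", "rp2",
]
STATE_FEATURES = AUGMENT_FEATURES[:9]


@dataclass
class GanConfig:
    latent_dim: int = 8
    critic_hidden: tuple[int, ...] = (64, 64)
    gen_hidden: tuple[int, ...] = (64, 64)
    lambda_gp: float = 10.0
    n_critic: int = 5             # critic iterations per generator step
    epochs: int = 1000            # generator iterations
    batch_size: int = 64
    lr: float = 2e-3              # critic step size
    gen_lr: float | None = None   # generator step size (default: lr / 10)
    n_generate: int = 4000
    seed: int = 0
    states_only: bool = False     # augment states, not full records

    def __post_init__(self):
        if self.lambda_gp < 0:
            raise ValueError("gradient-penalty weight must be >= 0")
        if self.n_generate < 0:
            raise ValueError("n_generate must be >= 0")


def _interp_gradients(critic: MLP, x_hat: np.ndarray) -> np.ndarray:
    """Per-sample gradient of the critic output w.r.t. its input."""
    return critic.input_gradient(x_hat)


def gradient_penalty(critic: MLP, real: np.ndarray, fake: np.ndarray,
                     lam: float, rng=None) -> float:
    """Two-sided WGAN-GP penalty ``lam * E[(||grad f(x_hat)|| - 1)^2]``
    on per-sample random interpolates of the real and fake batches."""
    real = np.atleast_2d(np.asarray(real, float))
    fake = np.atleast_2d(np.asarray(fake, float))
    if real.shape != fake.shape:
        raise ValueError(f"real {real.shape} and fake {fake.shape} batches must match")
    rng = np.random.default_rng(rng)
    eps = rng.random((real.shape[0], 1))
    x_hat = eps * real + (1.0 - eps) * fake
    grads = _interp_gradients(critic, x_hat)
    norms = np.linalg.norm(grads, axis=1)
    return float(lam * np.mean((norms - 1.0) ** 2))


def _gp_param_grads(critic: MLP, x_hat: np.ndarray, lam: float):
    """Penalty value and its gradient w.r.t. the critic weights.

    Valid for ReLU critics: with the activation masks held fixed (they
    are piecewise constant), the input gradient is a product of linear
    maps and the penalty gradient follows by the chain rule.
    """
    out, (zs, acts) = critic.forward(x_hat)
    L = critic.n_layers
    masks = [(zs[k] > 0.0).astype(float) for k in range(L - 1)]
    # reverse sweep: delta_k = d f/d z_k with masks fixed
    deltas = [None] * L
    deltas[L - 1] = np.ones_like(out)
    for k in range(L - 2, -1, -1):
        deltas[k] = (deltas[k + 1] @ critic.W[k + 1].T) * masks[k]
    v = deltas[0] @ critic.W[0].T                      # per-sample input gradient
    norms = np.linalg.norm(v, axis=1)
    B = x_hat.shape[0]
    penalty = lam * np.mean((norms - 1.0) ** 2)
    safe = np.maximum(norms, 1e-12)
    G = (2.0 * lam * (norms - 1.0) / safe / B)[:, None] * v   # dPenalty/dv
    grad_W = [np.zeros_like(W) for W in critic.W]
    grad_b = [np.zeros_like(b) for b in critic.b]      # penalty ignores biases
    grad_W[0] = G.T @ deltas[0]
    u = G @ critic.W[0]
    for k in range(1, L):
        u = u * masks[k - 1]
        grad_W[k] = u.T @ deltas[k]
        u = u @ critic.W[k]
    return penalty, grad_W, grad_b


class WganGp:
    """WGAN-GP on feature-wise min-max scaled tables."""

    def __init__(self, config: GanConfig | None = None):
        self.config = config or GanConfig()
        self.critic: MLP | None = None
        self.generator: MLP | None = None
        self.lo = self.hi = None
        self.wasserstein_history: list[float] = []

    # -- scaling -----------------------------------------------------------
    def _scale(self, X):
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        return 2.0 * (X - self.lo) / span - 1.0

    def _unscale(self, Xs):
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        return (Xs + 1.0) / 2.0 * span + self.lo

    def _gen_forward(self, Z):
        raw, cache = self.generator.forward(Z)
        out = np.tanh(raw)
        return out, (cache, out)

    def fit(self, X: np.ndarray) -> "WganGp":
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] == 0:
            raise ValueError("cannot fit the GAN on an empty table")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.lo, self.hi = X.min(axis=0), X.max(axis=0)
        Xs = self._scale(X)
        d = X.shape[1]
        self.critic = MLP([d, *cfg.critic_hidden, 1], activation="relu",
                          rng=int(rng.integers(2 ** 31)))
        self.generator = MLP([cfg.latent_dim, *cfg.gen_hidden, d], activation="tanh",
                             rng=int(rng.integers(2 ** 31)))
        opt_c = Adam(self.critic, lr=cfg.lr, beta1=0.5, beta2=0.9)
        gen_lr = cfg.gen_lr if cfg.gen_lr is not None else cfg.lr / 10.0
        opt_g = Adam(self.generator, lr=gen_lr, beta1=0.5, beta2=0.9)
        n = Xs.shape[0]
        B = min(cfg.batch_size, n)
        self.wasserstein_history = []

        for _ in range(cfg.epochs):
            for _ in range(cfg.n_critic):
                real = Xs[rng.choice(n, B, replace=n < B)]
                z = rng.standard_normal((B, cfg.latent_dim))
                fake, _ = self._gen_forward(z)
                # critic loss: E[f(fake)] - E[f(real)] + GP
                out_f, cache_f = self.critic.forward(fake)
                gWf, gbf, _ = self.critic.backward(cache_f, np.full_like(out_f, 1.0 / B))
                out_r, cache_r = self.critic.forward(real)
                gWr, gbr, _ = self.critic.backward(cache_r, np.full_like(out_r, -1.0 / B))
                eps = rng.random((B, 1))
                x_hat = eps * real + (1.0 - eps) * fake
                _, gWp, gbp = _gp_param_grads(self.critic, x_hat, cfg.lambda_gp)
                gW = [a + b + c for a, b, c in zip(gWf, gWr, gWp)]
                gb = [a + b + c for a, b, c in zip(gbf, gbr, gbp)]
                opt_c.step(gW, gb)
                w_est = float(out_r.mean() - out_f.mean())
            # generator step: minimize -E[f(fake)]
            z = rng.standard_normal((B, cfg.latent_dim))
            fake, (gcache, gout) = self._gen_forward(z)
            out_f, cache_f = self.critic.forward(fake)
            _, _, dfake = self.critic.backward(cache_f, np.full_like(out_f, -1.0 / B))
            draw = dfake * (1.0 - gout * gout)   # through the output tanh
            gWg, gbg, _ = self.generator.backward(gcache, draw)
            opt_g.step(gWg, gbg)
            self.wasserstein_history.append(w_est)
        return self

    def generate(self, n: int, seed=None) -> np.ndarray:
        if self.generator is None:
            raise RuntimeError("fit the GAN before generating")
        if n == 0:
            return np.empty((0, self.lo.size))
        rng = np.random.default_rng(self.config.seed + 1 if seed is None else seed)
        z = rng.standard_normal((n, self.config.latent_dim))
        fake, _ = self._gen_forward(z)
        X = self._unscale(fake)
        return np.clip(X, self.lo, self.hi)


def fit_and_generate(records, config: GanConfig | None = None):
    """Fit the WGAN-GP on a cohort and emit ``n_generate`` synthetic rows.

    Returns ``(frame, model)`` where frame is a DataFrame in the cohort
    feature schema (without patient ids).  Deterministic given the seed.
    """
    import pandas as pd

    from .cohort import records_to_frame

    if not records:
        raise ValueError("cannot augment an empty cohort")
    config = config or GanConfig()
    cols = STATE_FEATURES if config.states_only else AUGMENT_FEATURES
    df = records_to_frame(records)
    X = df[cols].to_numpy(dtype=float)
    model = WganGp(config).fit(X)
    out = model.generate(config.n_generate)
    frame = pd.DataFrame(out, columns=cols)
    frame["genotype"] = frame["genotype"].round().clip(0, 2).astype(int)
    if not config.states_only:
        frame["lc"] = (frame["lc"] > 0.5).astype(int)
        frame["rp2"] = (frame["rp2"] > 0.5).astype(int)
        frame["clinical_dose"] = frame["clinical_dose"].clip(lower=1e-3)
    return frame, model
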