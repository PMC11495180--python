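"""Adversarial training of (G, E) against the joint critic D.

The three networks play the bidirectional Wasserstein game

    min_{E,G} max_D  E_x[D(x, E(x))] - E_z[D(G(z), z)],

with latents z drawn i.i.d. Uniform[-1, 1]^l.  The critic ascends the
gap (its loss is the negated gap plus a gradient penalty pushing the
norm of its joint input-gradient toward 1, the standard soft Lipschitz
constraint), while the encoder and generator jointly descend it.  Each
outer iteration performs ``critic_steps`` critic updates followed by one
E/G update, all with the Adam optimizer.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .networks import (
    CriticNet,
    EncoderNet,
    GeneratorNet,
    NetworkConfig,
    build_networks,
    save_checkpoint,
)


class TrainingDivergence(RuntimeError):
    """Raised when a loss turns non-finite; carries the iteration index."""

    def __init__(self, message, iteration=None):
        super().__init__(message)
        self.iteration = iteration


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 64
    critic_steps: int = 5
    n_iter: int = 150_000
    gp_weight: float = 10.0
    beta1: float = 0.5
    beta2: float = 0.9
    seed: int = 0
    checkpoint_every: int = 0          # 0 disables periodic checkpoints
    checkpoint_path: str | None = None

    def __post_init__(self):
        if self.critic_steps < 1:
            raise ValueError("critic_steps must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (penalty interpolates in-batch)")
        if self.gp_weight < 0:
            raise ValueError("gp_weight must be >= 0")


class Adam:
    """Standard Adam over a named parameter dict of leaf Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float, beta1: float, beta2: float,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            p.data = p.data - self.lr * (self.m[k] / c1) / (
                np.sqrt(self.v[k] / c2) + self.eps
            )


@dataclass
class TrainState:
    """Networks, optimizers, and per-step loss bookkeeping."""

    generator: GeneratorNet
    encoder: EncoderNet
    critic: CriticNet
    net_config: NetworkConfig
    train_config: TrainConfig
    opt_g: Adam = None
    opt_e: Adam = None
    opt_d: Adam = None
    iteration: int = 0
    critic_loss_history: list[float] = field(default_factory=list)
    eg_loss_history: list[float] = field(default_factory=list)
    gp_history: list[float] = field(default_factory=list)

    @classmethod
    def initialize(cls, net_config: NetworkConfig, train_config: TrainConfig):
        g, e, d = build_networks(net_config, seed=train_config.seed)
        mk = lambda net: Adam(
            net.params, train_config.learning_rate,
            train_config.beta1, train_config.beta2,
        )
        return cls(g, e, d, net_config, train_config,
                   opt_g=mk(g), opt_e=mk(e), opt_d=mk(d))

    def write_log(self, path) -> None:
        """Training log as CSV: iteration, critic loss, eg loss, penalty term."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        k = self.train_config.critic_steps
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "critic_loss", "eg_loss", "gradient_penalty"])
            for i in range(self.iteration):
                # one row per outer iteration; critic columns show the last
                # of that iteration's k critic steps
                writer.writerow([
                    i + 1,
                    self.critic_loss_history[(i + 1) * k - 1],
                    self.eg_loss_history[i],
                    self.gp_history[(i + 1) * k - 1],
                ])


# -------------------------------------------------------------------------
# objective pieces
# -------------------------------------------------------------------------

def sample_latent(m: int, l: int, rng) -> np.ndarray:
    """i.i.d. Uniform[-1, 1] latent batch of shape (m, l)."""
    if m < 1 or l < 1:
        raise ValueError("batch size and latent dimension must be >= 1")
    return rng.uniform(-1.0, 1.0, size=(m, l)).astype(np.float32)


def wasserstein_gap(critic, x_batch, z_batch, encoder, generator) -> Tensor:
    """mean D(x, E(x)) - mean D(G(z), z) over the batch.

    ``critic`` is any callable (x, z) -> (m, 1) scores; the networks'
    phase-shuffle randomness is handled by the caller via closure.
    """
    x = x_batch if isinstance(x_batch, Tensor) else Tensor(np.asarray(x_batch, np.float32))
    z = z_batch if isinstance(z_batch, Tensor) else Tensor(np.asarray(z_batch, np.float32))
    if x.shape[0] != z.shape[0]:
        raise ValueError("x and z batches must have equal size")
    real = critic(x, encoder.forward(x))
    fake = critic(generator.forward(z), z)
    return real.mean() - fake.mean()


def gradient_penalty(critic, real_pair, fake_pair, rng) -> Tensor:
    """mean over pairs of (||∇_(x̂,ẑ) D(x̂, ẑ)||₂ - 1)².

    One ε ~ Uniform[0, 1] is drawn per pair and the joint interpolate is
    (x̂, ẑ) = ε (x, E(x)) + (1-ε) (G(z), z).  The result stays on the
    graph, so its parameter-gradient flows through the critic update.
    """
    x_real, z_real = (np.asarray(getattr(t, "data", t), np.float32) for t in real_pair)
    x_fake, z_fake = (np.asarray(getattr(t, "data", t), np.float32) for t in fake_pair)
    m = x_real.shape[0]
    eps = rng.uniform(0.0, 1.0, size=m).astype(np.float32)
    x_hat = Tensor(eps[:, None, None] * x_real.reshape(m, 1, -1)
                   + (1.0 - eps)[:, None, None] * x_fake.reshape(m, 1, -1))
    z_hat = Tensor(eps[:, None] * z_real + (1.0 - eps)[:, None] * z_fake)
    scores = critic(x_hat, z_hat)
    gx, gz = ad.grad(scores.sum(), [x_hat, z_hat])
    sq = (gx * gx).sum(axis=(1, 2)) + (gz * gz).sum(axis=1)
    norm = ad.sqrt(sq + 1e-16)  # stabilizer keeps the backward pass finite at 0
    return ((norm - 1.0) ** 2).mean()


# -------------------------------------------------------------------------
# update steps
# -------------------------------------------------------------------------

def _grad_dict(loss: Tensor, params: dict[str, Tensor]) -> dict[str, np.ndarray]:
    names = list(params)
    grads = ad.grad(loss, [params[k] for k in names])
    return {k: g.data for k, g in zip(names, grads)}


def critic_step(state: TrainState, x_batch, z_batch, rng) -> float:
    """One critic ascent step: loss = -(gap) + λ · gradient penalty."""
    cfg = state.train_config
    d, e, g = state.critic, state.encoder, state.generator
    crit = lambda x, z: d.forward(x, z, rng=rng)
    x_t = Tensor(np.asarray(x_batch, np.float32))
    z_t = Tensor(np.asarray(z_batch, np.float32))
    e_x = e.forward(x_t)
    g_z = g.forward(z_t)
    gap = crit(x_t, e_x).mean() - crit(g_z, z_t).mean()
    if cfg.gp_weight > 0:
        gp = gradient_penalty(crit, (x_t, e_x), (g_z, z_t), rng)
    else:
        gp = Tensor(np.float32(0.0))
    loss = -gap + cfg.gp_weight * gp
    value = float(loss.data)
    if not np.isfinite(value):
        raise TrainingDivergence(
            f"critic loss became non-finite ({value})", iteration=state.iteration
        )
    state.opt_d.step(_grad_dict(loss, d.params))
    state.critic_loss_history.append(value)
    state.gp_history.append(float(gp.data))
    return value


def eg_step(state: TrainState, x_batch, z_batch, rng) -> float:
    """One joint descent step for E and G on the shared loss = gap."""
    d, e, g = state.critic, state.encoder, state.generator
    loss = wasserstein_gap(
        lambda x, z: d.forward(x, z, rng=rng), x_batch, z_batch, e, g
    )
    value = float(loss.data)
    if not np.isfinite(value):
        raise TrainingDivergence(
            f"E/G loss became non-finite ({value})", iteration=state.iteration
        )
    params = dict(e.params) | {f"G::{k}": v for k, v in g.params.items()}
    grads = _grad_dict(loss, params)
    state.opt_e.step({k: grads[k] for k in e.params})
    state.opt_g.step({k: grads[f"G::{k}"] for k in g.params})
    state.eg_loss_history.append(value)
    return value


class _BatchSampler:
    """Shuffled without-replacement minibatches, reshuffling each epoch."""

    def __init__(self, n: int, batch_size: int, rng):
        self.n, self.bs, self.rng = n, batch_size, rng
        self._order = rng.permutation(n)
        self._pos = 0

    def next_indices(self) -> np.ndarray:
        if self._pos + self.bs > self.n:
            self._order = self.rng.permutation(self.n)
            self._pos = 0
        out = self._order[self._pos:self._pos + self.bs]
        self._pos += self.bs
        return out


def train(corpus, net_config: NetworkConfig, train_config: TrainConfig,
          state: TrainState | None = None, callback=None) -> TrainState:
    """Run the outer loop: k critic steps then one E/G step per iteration.

    ``corpus`` is an (N, L) array or an object with ``to_array``.  Fully
    reproducible given the config seed.  On divergence the last good
    checkpoint is written (if a checkpoint path is configured) and the
    error re-raised.
    """
    data = corpus if isinstance(corpus, np.ndarray) else corpus.to_array(
        net_config.output_length
    )
    data = np.asarray(data, dtype=np.float32)
    cfg = train_config
    if data.shape[0] < cfg.batch_size:
        raise ValueError("corpus smaller than the batch size")
    if data.shape[1] != net_config.output_length:
        raise ValueError(
            f"corpus length {data.shape[1]} != model length {net_config.output_length}"
        )
    if state is None:
        state = TrainState.initialize(net_config, cfg)
    rng = np.random.default_rng(cfg.seed)
    sampler = _BatchSampler(data.shape[0], cfg.batch_size, rng)
    l = net_config.latent_dim

    def checkpoint(tag):
        if cfg.checkpoint_path:
            save_checkpoint(
                cfg.checkpoint_path,
                {"G": state.generator, "E": state.encoder, "D": state.critic},
                net_config,
                {"iteration": state.iteration, "tag": tag},
            )

    for _ in range(cfg.n_iter):
        try:
            for _ in range(cfg.critic_steps):
                z = sample_latent(cfg.batch_size, l, rng)
                x = data[sampler.next_indices()]
                critic_step(state, x, z, rng)
            z = sample_latent(cfg.batch_size, l, rng)
            x = data[sampler.next_indices()]
            eg_step(state, x, z, rng)
        except TrainingDivergence:
            checkpoint("diverged-last-good")
            raise
        state.iteration += 1
        if cfg.checkpoint_every and state.iteration % cfg.checkpoint_every == 0:
            checkpoint("periodic")
        if callback is not None:
            callback(state)
    checkpoint("final")
    return state
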