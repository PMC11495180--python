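"""Algorithm contracts of the adversarial loop: objective terms, update
exclusivity, critic/generator step ratio, and seed determinism."""

import numpy as np
import pytest

from usvgan import (
    NetworkConfig,
    TrainConfig,
    TrainState,
    TrainingDivergence,
    critic_step,
    eg_step,
    gradient_penalty,
    sample_latent,
    train,
    wasserstein_gap,
)
from usvgan.autodiff import Tensor


@pytest.fixture(scope="module")
def quiet_cfg():
    # phase shuffle disabled so gap evaluations are deterministic
    return NetworkConfig(latent_dim=4, model_size=2, num_blocks=2,
                         joint_filters=8, phase_shuffle_radius=0)


def _data(n, length, seed=0):
    return np.random.default_rng(seed).normal(0, 0.3, (n, length)).clip(-1, 1).astype(np.float32)


def _snapshot(net):
    return {k: p.data.copy() for k, p in net.params.items()}


def _identical(snap, net):
    return all(np.array_equal(snap[k], net.params[k].data) for k in snap)


class TestSampleLatent:
    def test_entries_within_unit_box(self, rng):
        z = sample_latent(100, 10, rng)
        assert z.shape == (100, 10)
        assert np.all(z >= -1) and np.all(z <= 1)

    def test_large_sample_mean_near_zero(self):
        z = sample_latent(1_000_000, 1, np.random.default_rng(0))
        assert abs(z.mean()) < 0.01

    def test_seeded_draws_identical(self):
        a = sample_latent(8, 5, np.random.default_rng(42))
        b = sample_latent(8, 5, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_invalid_sizes_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_latent(0, 5, rng)


class _StubNet:
    """Identity-ish encoder/generator stand-ins for objective arithmetic."""

    def __init__(self, out):
        self._out = out

    def forward(self, x):
        m = x.shape[0]
        return Tensor(np.broadcast_to(self._out, (m,) + self._out.shape[1:]).copy())


class TestWassersteinGap:
    def test_constant_critic_gives_zero(self):
        critic = lambda x, z: Tensor(np.full((x.shape[0], 1), 3.0, np.float32))
        e = _StubNet(np.zeros((1, 4), np.float32))
        g = _StubNet(np.zeros((1, 1, 16), np.float32))
        gap = wasserstein_gap(critic, np.zeros((5, 1, 16)), np.zeros((5, 4)), e, g)
        assert gap.item() == 0.0

    def test_signed_stub_gives_two(self):
        # +1 on real pairs (nonzero x), -1 on fake pairs (zero x)
        def critic(x, z):
            real = np.any(np.abs(x.data) > 0, axis=(1, 2))
            return Tensor(np.where(real, 1.0, -1.0).astype(np.float32).reshape(-1, 1))

        e = _StubNet(np.zeros((1, 4), np.float32))
        g = _StubNet(np.zeros((1, 1, 16), np.float32))
        gap = wasserstein_gap(critic, np.ones((6, 1, 16)), np.ones((6, 4)), e, g)
        assert gap.item() == 2.0

    def test_matches_loop_recomputation_with_real_nets(self, quiet_cfg):
        state = TrainState.initialize(quiet_cfg, TrainConfig(batch_size=4, n_iter=1, seed=0))
        x = _data(4, quiet_cfg.output_length, seed=1)
        z = sample_latent(4, quiet_cfg.latent_dim, np.random.default_rng(2))
        critic = lambda a, b: state.critic.forward(a, b, shuffle=False)
        gap = wasserstein_gap(critic, x, z, state.encoder, state.generator).item()
        # brute force: score each pair individually and average
        real, fake = [], []
        for i in range(4):
            exi = state.encoder.forward(x[i:i + 1])
            real.append(state.critic.forward(x[i:i + 1], exi, shuffle=False).item())
            gzi = state.generator.forward(z[i:i + 1])
            fake.append(state.critic.forward(gzi, z[i:i + 1], shuffle=False).item())
        assert np.isclose(gap, np.mean(real) - np.mean(fake), atol=1e-5)


class TestGradientPenalty:
    def _pairs(self, m=6, length=16, l=3, seed=0):
        rng = np.random.default_rng(seed)
        return (
            (rng.normal(size=(m, 1, length)).astype(np.float32),
             rng.normal(size=(m, l)).astype(np.float32)),
            (rng.normal(size=(m, 1, length)).astype(np.float32),
             rng.normal(size=(m, l)).astype(np.float32)),
        )

    def test_constant_critic_penalty_is_one(self):
        real, fake = self._pairs()
        critic = lambda x, z: x.sum() * 0.0 + z.sum() * 0.0 + Tensor(np.zeros((x.shape[0], 1), np.float32))
        gp = gradient_penalty(critic, real, fake, np.random.default_rng(0))
        assert np.isclose(gp.item(), 1.0, atol=1e-6)

    def test_unit_gradient_linear_critic_penalty_is_zero(self):
        real, fake = self._pairs(seed=1)
        rng = np.random.default_rng(2)
        w = rng.normal(size=19)
        w /= np.linalg.norm(w)
        wx = Tensor(w[:16].reshape(1, 1, 16).astype(np.float32))
        wz = Tensor(w[16:].reshape(1, 3).astype(np.float32))
        critic = lambda x, z: (
            (x * wx).sum(axis=(1, 2)).reshape(x.shape[0], 1)
            + (z * wz).sum(axis=1).reshape(z.shape[0], 1)
        )
        gp = gradient_penalty(critic, real, fake, np.random.default_rng(3))
        assert np.isclose(gp.item(), 0.0, atol=1e-6)

    def test_quadratic_critic_matches_hand_computation(self):
        real, fake = self._pairs(seed=4)
        critic = lambda x, z: (
            (x * x).sum(axis=(1, 2)).reshape(x.shape[0], 1)
            + (z * z).sum(axis=1).reshape(z.shape[0], 1)
        )
        gp = gradient_penalty(critic, real, fake, np.random.default_rng(5))
        # gradient of sum of squares is 2*(x̂, ẑ): recompute with same eps draw
        eps = np.random.default_rng(5).uniform(0, 1, 6).astype(np.float32)
        xh = eps[:, None, None] * real[0] + (1 - eps)[:, None, None] * fake[0]
        zh = eps[:, None] * real[1] + (1 - eps)[:, None] * fake[1]
        norms = 2 * np.sqrt((xh ** 2).sum(axis=(1, 2)) + (zh ** 2).sum(axis=1))
        assert np.isclose(gp.item(), ((norms - 1) ** 2).mean(), rtol=1e-5)


class TestSteps:
    def _state(self, quiet_cfg, lam=10.0, lr=1e-3):
        tc = TrainConfig(batch_size=4, n_iter=1, seed=0, learning_rate=lr, gp_weight=lam)
        return TrainState.initialize(quiet_cfg, tc), tc

    def test_critic_step_touches_only_critic(self, quiet_cfg):
        state, tc = self._state(quiet_cfg)
        x = _data(4, quiet_cfg.output_length)
        z = sample_latent(4, quiet_cfg.latent_dim, np.random.default_rng(1))
        sg, se, sd = map(_snapshot, (state.generator, state.encoder, state.critic))
        critic_step(state, x, z, np.random.default_rng(2))
        assert _identical(sg, state.generator) and _identical(se, state.encoder)
        assert not _identical(sd, state.critic)
        assert len(state.critic_loss_history) == 1 and len(state.gp_history) == 1

    def test_eg_step_touches_only_encoder_and_generator(self, quiet_cfg):
        state, tc = self._state(quiet_cfg)
        x = _data(4, quiet_cfg.output_length)
        z = sample_latent(4, quiet_cfg.latent_dim, np.random.default_rng(1))
        sg, se, sd = map(_snapshot, (state.generator, state.encoder, state.critic))
        eg_step(state, x, z, np.random.default_rng(2))
        assert _identical(sd, state.critic)
        assert not _identical(sg, state.generator) and not _identical(se, state.encoder)
        assert len(state.eg_loss_history) == 1

    def test_critic_step_ascends_gap_on_frozen_batch(self, quiet_cfg):
        state, _ = self._state(quiet_cfg, lam=0.0, lr=1e-3)
        x = _data(4, quiet_cfg.output_length, seed=3)
        z = sample_latent(4, quiet_cfg.latent_dim, np.random.default_rng(4))
        crit = lambda a, b: state.critic.forward(a, b, shuffle=False)
        before = wasserstein_gap(crit, x, z, state.encoder, state.generator).item()
        for _ in range(3):
            critic_step(state, x, z, np.random.default_rng(5))
        after = wasserstein_gap(crit, x, z, state.encoder, state.generator).item()
        assert after >= before

    def test_eg_step_descends_gap_on_frozen_batch(self, quiet_cfg):
        state, _ = self._state(quiet_cfg, lam=0.0, lr=1e-3)
        x = _data(4, quiet_cfg.output_length, seed=3)
        z = sample_latent(4, quiet_cfg.latent_dim, np.random.default_rng(4))
        crit = lambda a, b: state.critic.forward(a, b, shuffle=False)
        before = wasserstein_gap(crit, x, z, state.encoder, state.generator).item()
        for _ in range(3):
            eg_step(state, x, z, np.random.default_rng(5))
        after = wasserstein_gap(crit, x, z, state.encoder, state.generator).item()
        assert after <= before

    def test_divergent_parameters_raise(self, quiet_cfg):
        state, _ = self._state(quiet_cfg)
        state.generator.params["dense_w"].data[:] = np.inf
        x = _data(4, quiet_cfg.output_length)
        z = sample_latent(4, quiet_cfg.latent_dim, np.random.default_rng(0))
        with pytest.raises(TrainingDivergence):
            critic_step(state, x, z, np.random.default_rng(1))


class TestTrainLoop:
    def test_five_critic_updates_per_eg_update(self, quiet_cfg):
        tc = TrainConfig(batch_size=8, n_iter=4, critic_steps=5, seed=0)
        state = train(_data(32, quiet_cfg.output_length), quiet_cfg, tc)
        assert state.iteration == 4
        assert len(state.eg_loss_history) == 4
        assert len(state.critic_loss_history) == 20  # 5 : 1 ratio

    def test_loss_history_is_seed_deterministic(self, quiet_cfg):
        tc = TrainConfig(batch_size=8, n_iter=3, seed=11)
        data = _data(24, quiet_cfg.output_length)
        a = train(data, quiet_cfg, tc)
        b = train(data, quiet_cfg, tc)
        assert a.critic_loss_history == b.critic_loss_history
        assert a.eg_loss_history == b.eg_loss_history

    def test_corpus_smaller_than_batch_rejected(self, quiet_cfg):
        with pytest.raises(ValueError):
            train(_data(4, quiet_cfg.output_length),
                  quiet_cfg, TrainConfig(batch_size=8, n_iter=1))

    def test_large_penalty_weight_pins_critic_gradient_norm_near_one(self, quiet_cfg):
        """With a heavy gradient penalty the critic's joint input-gradient
        norm at interpolates settles near 1 (the soft Lipschitz target)."""
        from usvgan import autodiff as ad

        rng = np.random.default_rng(0)
        data = _data(32, quiet_cfg.output_length, seed=0)
        tc = TrainConfig(batch_size=8, n_iter=30, seed=0,
                         learning_rate=1e-3, gp_weight=100.0)
        state = train(data, quiet_cfg, tc)
        x = data[:8]
        z = sample_latent(8, quiet_cfg.latent_dim, np.random.default_rng(1))
        e_x = state.encoder.forward(x)
        g_z = state.generator.forward(z)
        eps = np.random.default_rng(2).uniform(0, 1, 8).astype(np.float32)
        xh = Tensor(eps[:, None, None] * x.reshape(8, 1, -1)
                    + (1 - eps)[:, None, None] * g_z.data)
        zh = Tensor(eps[:, None] * e_x.data + (1 - eps)[:, None] * z)
        score = state.critic.forward(xh, zh, shuffle=False).sum()
        gx, gz = ad.grad(score, [xh, zh])
        norms = np.sqrt((gx.data ** 2).sum(axis=(1, 2)) + (gz.data ** 2).sum(axis=1))
        assert 0.5 < norms.mean() < 1.5

    def test_checkpoint_and_loss_log_written(self, quiet_cfg, tmp_path):
        tc = TrainConfig(batch_size=8, n_iter=2, seed=0,
                         checkpoint_path=str(tmp_path / "m.ckpt"))
        state = train(_data(16, quiet_cfg.output_length), quiet_cfg, tc)
        assert (tmp_path / "m.ckpt").exists()
        state.write_log(tmp_path / "losses.csv")
        lines = (tmp_path / "losses.csv").read_text().strip().splitlines()
        assert len(lines) == 3  # header + one row per iteration
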