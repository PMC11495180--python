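"""Generator, encoder, and critic graphs for the bidirectional waveform GAN.

The generator expands an l-dimensional latent code through a dense layer
to a (32d, 16) feature map, then through stride-4 transposed convolutions
(zero-stuffing upsample followed by a length-25 kernel) and a final
stride-2 stage with tanh output, reaching 16 * 4**num_blocks * 2 samples
(32,768 with the default five stride-4 blocks).  The encoder mirrors it
with plain convolutions (strides 2, 4, 4, ...) and LeakyReLU(0.2),
ending in an unbounded linear map to the latent space.  The critic is a
joint function D(x, z) = D_joint(Concat(D_x(x), D_z(z))): D_x is a
phase-shuffled convolutional stack over the waveform, D_z and D_joint
are stacks of kernel-length-1 convolutions.

Phase shuffle randomly translates each sample's feature maps by an
integer drawn from [-n, n] (reflection fill at the edges), so the critic
cannot lock onto the fixed phase of upsampling artifacts.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

CHECKPOINT_VERSION = 1

_F32 = np.float32


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters shared by the three networks.

    latent_dim (l), model_size (d), phase-shuffle radius (n) and the
    D_z/D_joint filter count (f) default to the published values
    (10, 32, 2, 512); num_blocks counts the stride-4 stages, so the
    waveform length is 16 * 4**num_blocks * 2.
    """

    latent_dim: int = 10
    model_size: int = 32
    phase_shuffle_radius: int = 2
    joint_filters: int = 512
    num_blocks: int = 5
    kernel_len: int = 25

    def __post_init__(self):
        for name in ("latent_dim", "model_size", "joint_filters", "num_blocks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.phase_shuffle_radius < 0:
            raise ValueError("phase_shuffle_radius must be >= 0")
        if self.kernel_len < 4:
            raise ValueError("kernel_len must cover the largest stride (4)")

    @property
    def output_length(self) -> int:
        return 16 * 4 ** self.num_blocks * 2

    def encoder_channels(self) -> list[int]:
        d = self.model_size
        cap = 32 * d
        return [2 * d] + [min(cap, 2 * d * 2 ** i) for i in range(1, self.num_blocks + 1)]

    def critic_x_channels(self) -> list[int]:
        d = self.model_size
        cap = 32 * d
        return [d] + [min(cap, d * 2 ** i) for i in range(1, self.num_blocks + 1)]


def _same_pad(kernel: int, stride: int) -> tuple[int, int]:
    # Chosen so a stride-s layer divides the length exactly by s.
    total = kernel - stride
    return total // 2, total - total // 2


def _conv_w(rng, out_ch, in_ch, k):
    std = _F32(np.sqrt(2.0 / (in_ch * k)))
    return Tensor(rng.standard_normal((out_ch, in_ch, k), dtype=_F32) * std)


def _dense_w(rng, n_in, n_out):
    std = _F32(np.sqrt(2.0 / n_in))
    return Tensor(rng.standard_normal((n_in, n_out), dtype=_F32) * std)


def _zeros(*shape):
    return Tensor(np.zeros(shape, dtype=_F32))


def _as_batch(x, expected_last: int, name: str) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=_F32))
    if t.shape[-1] != expected_last:
        raise ValueError(
            f"{name}: expected trailing dimension {expected_last}, got {t.shape}"
        )
    return t


class _Net:
    """Base: a named parameter dict of leaf Tensors."""

    def __init__(self):
        self.params: dict[str, Tensor] = {}

    @property
    def param_count(self) -> int:
        return sum(int(p.size) for p in self.params.values())

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: p.data for k, p in self.params.items()}

    def load_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            arr = np.asarray(arrays[k], dtype=p.dtype)
            if arr.shape != p.shape:
                raise ValueError(f"checkpoint shape mismatch for {k}")
            p.data = arr


class GeneratorNet(_Net):
    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        enc = config.encoder_channels()
        self.c0 = enc[-1]
        self.stage_channels = list(reversed(enc))[1:]  # stride-4 outputs
        k = config.kernel_len
        self.params["dense_w"] = _dense_w(rng, config.latent_dim, 16 * self.c0)
        self.params["dense_b"] = _zeros(16 * self.c0)
        in_ch = self.c0
        for i, out_ch in enumerate(self.stage_channels):
            self.params[f"tconv{i}_w"] = _conv_w(rng, out_ch, in_ch, k)
            self.params[f"tconv{i}_b"] = _zeros(out_ch)
            in_ch = out_ch
        self.params["tconv_out_w"] = _conv_w(rng, 1, in_ch, k)
        self.params["tconv_out_b"] = _zeros(1)

    def forward(self, z, trace: list | None = None) -> Tensor:
        cfg = self.config
        z = _as_batch(z, cfg.latent_dim, "generator latent input")
        m = z.shape[0]
        h = ad.relu(ad.dense(z, self.params["dense_w"], self.params["dense_b"]))
        if trace is not None:
            trace.append(("dense", (m, 1, h.shape[1])))
        h = h.reshape(m, self.c0, 16)
        if trace is not None:
            trace.append(("reshape", h.shape))
        for i in range(len(self.stage_channels)):
            h = ad.conv1d_transpose(
                h, self.params[f"tconv{i}_w"], self.params[f"tconv{i}_b"], stride=4
            )
            h = ad.relu(h)
            if trace is not None:
                trace.append((f"tconv{i}", h.shape))
        h = ad.conv1d_transpose(
            h, self.params["tconv_out_w"], self.params["tconv_out_b"], stride=2
        )
        h = ad.tanh(h)
        if trace is not None:
            trace.append(("tconv_out", h.shape))
        return h


class EncoderNet(_Net):
    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.channels = config.encoder_channels()
        self.strides = [2] + [4] * config.num_blocks
        k = config.kernel_len
        in_ch = 1
        for i, out_ch in enumerate(self.channels):
            self.params[f"conv{i}_w"] = _conv_w(rng, out_ch, in_ch, k)
            self.params[f"conv{i}_b"] = _zeros(out_ch)
            in_ch = out_ch
        self.flat_width = self.channels[-1] * 16
        self.params["dense_w"] = _dense_w(rng, self.flat_width, config.latent_dim)
        self.params["dense_b"] = _zeros(config.latent_dim)

    def forward(self, x, trace: list | None = None) -> Tensor:
        cfg = self.config
        x = _as_batch(x, cfg.output_length, "encoder waveform input")
        if x.ndim == 2:
            x = x.reshape(x.shape[0], 1, x.shape[1])
        m = x.shape[0]
        h = x
        for i, stride in enumerate(self.strides):
            pad = _same_pad(cfg.kernel_len, stride)
            h = ad.conv1d(
                h, self.params[f"conv{i}_w"], self.params[f"conv{i}_b"],
                stride=stride, pad=pad,
            )
            h = ad.leaky_relu(h, 0.2)
            if trace is not None:
                trace.append((f"conv{i}", h.shape))
        h = h.reshape(m, self.flat_width)
        if trace is not None:
            trace.append(("flatten", (m, 1, self.flat_width)))
        out = ad.dense(h, self.params["dense_w"], self.params["dense_b"])
        if trace is not None:
            trace.append(("dense", out.shape))
        return out


def phase_shuffle(x, radius: int, rng=None, shifts=None) -> Tensor:
    """Translate each sample's feature maps by an integer in [-radius, radius].

    One shift is drawn per batch sample and shared across its channels;
    vacated edges are filled by reflection.  ``shifts`` overrides the
    random draw (used for testing).
    """
    if radius < 0:
        raise ValueError("phase-shuffle radius must be >= 0")
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=_F32))
    if t.ndim != 3:
        raise ValueError("phase_shuffle expects (m, channels, time)")
    m, _, n_time = t.shape
    if shifts is None:
        if radius == 0:
            return t
        if rng is None:
            raise ValueError("phase_shuffle with radius > 0 needs an rng")
        shifts = rng.integers(-radius, radius + 1, size=m)
    shifts = np.asarray(shifts, dtype=np.intp)
    if np.all(shifts == 0):
        return t
    base = np.arange(n_time)
    idx = base[None, :] - shifts[:, None]
    idx = np.abs(idx)                       # reflect below 0
    idx = np.where(idx >= n_time, 2 * n_time - 2 - idx, idx)  # reflect above
    return ad.take_per_sample(t, idx)


class CriticNet(_Net):
    """Joint critic: D(x, z) = D_joint(Concat(D_x(x), D_z(z))), unbounded scores."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        d, f, k, l = (
            config.model_size,
            config.joint_filters,
            config.kernel_len,
            config.latent_dim,
        )
        self.x_channels = config.critic_x_channels()
        self.x_strides = [2] + [4] * config.num_blocks
        # phase shuffle follows every strided conv except the last two
        self.n_shuffled = max(0, len(self.x_channels) - 2)
        in_ch = 1
        for i, out_ch in enumerate(self.x_channels):
            self.params[f"dx_conv{i}_w"] = _conv_w(rng, out_ch, in_ch, k)
            self.params[f"dx_conv{i}_b"] = _zeros(out_ch)
            in_ch = out_ch
        self.params["dx_out_w"] = _conv_w(rng, 32 * d, in_ch, k)
        self.params["dx_out_b"] = _zeros(32 * d)
        for i, (ci, co) in enumerate([(l, f), (f, f), (f, f)]):
            self.params[f"dz_conv{i}_w"] = _conv_w(rng, co, ci, 1)
            self.params[f"dz_conv{i}_b"] = _zeros(co)
        for i, (ci, co) in enumerate([(32 * d + f, f), (f, f), (f, 1)]):
            self.params[f"dj_conv{i}_w"] = _conv_w(rng, co, ci, 1)
            self.params[f"dj_conv{i}_b"] = _zeros(co)

    def forward_x(self, x, rng=None, shuffle: bool = True, trace=None) -> Tensor:
        cfg = self.config
        x = _as_batch(x, cfg.output_length, "critic waveform input")
        if x.ndim == 2:
            x = x.reshape(x.shape[0], 1, x.shape[1])
        h = x
        radius = cfg.phase_shuffle_radius if shuffle else 0
        for i, stride in enumerate(self.x_strides):
            pad = _same_pad(cfg.kernel_len, stride)
            h = ad.conv1d(
                h, self.params[f"dx_conv{i}_w"], self.params[f"dx_conv{i}_b"],
                stride=stride, pad=pad,
            )
            h = ad.leaky_relu(h, 0.2)
            if i < self.n_shuffled and radius > 0:
                h = phase_shuffle(h, radius, rng)
            if trace is not None:
                trace.append((f"dx_conv{i}", h.shape))
        # final conv padded so a single temporal position remains
        l_in = h.shape[2]
        pad_total = max(0, cfg.kernel_len - l_in)
        h = ad.conv1d(
            h, self.params["dx_out_w"], self.params["dx_out_b"],
            stride=4, pad=(pad_total // 2, pad_total - pad_total // 2),
        )
        h = ad.leaky_relu(h, 0.2)
        if trace is not None:
            trace.append(("dx_out", h.shape))
        return h

    def forward_z(self, z) -> Tensor:
        z = _as_batch(z, self.config.latent_dim, "critic latent input")
        h = z.reshape(z.shape[0], z.shape[1], 1)
        for i in range(3):
            h = ad.conv1d(h, self.params[f"dz_conv{i}_w"], self.params[f"dz_conv{i}_b"])
            h = ad.leaky_relu(h, 0.2)
        return h

    def forward(self, x, z, rng=None, shuffle: bool = True, trace=None) -> Tensor:
        hx = self.forward_x(x, rng=rng, shuffle=shuffle, trace=trace)
        hz = self.forward_z(z)
        if hx.shape[0] != hz.shape[0]:
            raise ValueError(
                f"batch size mismatch: waveforms {hx.shape[0]}, latents {hz.shape[0]}"
            )
        h = ad.concat([hx, hz], axis=1)
        if trace is not None:
            trace.append(("concat", h.shape))
        for i in range(3):
            h = ad.conv1d(h, self.params[f"dj_conv{i}_w"], self.params[f"dj_conv{i}_b"])
            if i < 2:
                h = ad.leaky_relu(h, 0.2)
        out = h.reshape(h.shape[0], 1)
        if trace is not None:
            trace.append(("dj_out", out.shape))
        return out


# -------------------------------------------------------------------------
# functional wrappers (batch in, batch out)
# -------------------------------------------------------------------------

def generator_forward(net: GeneratorNet, z_batch, trace=None) -> Tensor:
    return net.forward(z_batch, trace=trace)


def encoder_forward(net: EncoderNet, x_batch, trace=None) -> Tensor:
    return net.forward(x_batch, trace=trace)


def critic_forward(net: CriticNet, x_batch, z_batch, rng=None, shuffle=True) -> Tensor:
    return net.forward(x_batch, z_batch, rng=rng, shuffle=shuffle)


def build_networks(
    config: NetworkConfig, seed: int = 0
) -> tuple[GeneratorNet, EncoderNet, CriticNet]:
    """Construct G, E, D with deterministic per-network init seeds."""
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    return (
        GeneratorNet(config, seeds[0]),
        EncoderNet(config, seeds[1]),
        CriticNet(config, seeds[2]),
    )


# -------------------------------------------------------------------------
# checkpoints: one zip archive holding all parameter arrays + the config
# -------------------------------------------------------------------------

def save_checkpoint(path, nets: dict, config: NetworkConfig, extra: dict | None = None):
    """``nets`` maps prefixes (e.g. 'G', 'E', 'D') to network objects."""
    arrays = {}
    for prefix, net in nets.items():
        for k, arr in net.state_arrays().items():
            arrays[f"{prefix}/{k}"] = arr
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(config),
        "extra": extra or {},
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        zf.writestr("arrays.npz", buf.getvalue())


def load_checkpoint(path):
    """Return (nets dict with 'G'/'E'/'D', NetworkConfig, extra metadata)."""
    with zipfile.ZipFile(Path(path)) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta["version"] > CHECKPOINT_VERSION:
            raise ValueError(f"checkpoint version {meta['version']} is newer than supported")
        with np.load(io.BytesIO(zf.read("arrays.npz"))) as npz:
            arrays = {k: npz[k] for k in npz.files}
    config = NetworkConfig(**meta["config"])
    prefixes = sorted({k.split("/", 1)[0] for k in arrays})
    nets = {}
    for prefix in prefixes:
        if prefix == "G":
            net = GeneratorNet(config)
        elif prefix == "E":
            net = EncoderNet(config)
        elif prefix == "D":
            net = CriticNet(config)
        else:
            continue
        net.load_arrays(
            {k.split("/", 1)[1]: v for k, v in arrays.items() if k.startswith(prefix + "/")}
        )
        nets[prefix] = net
    return nets, config, meta.get("extra", {})
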