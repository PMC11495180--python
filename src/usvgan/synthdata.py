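"""Synthetic USV-like corpora and ground-truth spiking responses.

Mouse ultrasonic syllables are whistle-like frequency-modulated sweeps:
10–130 ms long, confined to roughly 40–110 kHz, with smooth amplitude
envelopes over a low noise floor.  The generator here emulates exactly
that structure — four sweep families (up, down, chevron, flat) with a
raised-cosine envelope and additive Gaussian noise — so every stage of
the toolkit (training, synthesis, receptive-field fitting) can be
exercised end-to-end without recordings.  Spike rasters are drawn from
the same logistic spike-probability model the receptive-field fitter
assumes, making parameter recovery a round-trip test with known ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import Raster
from .audio import DEFAULT_RATE, SyllableCorpus, Waveform, fix_length
from .mne import MNEParams, StimulusDesign, spike_probability

KINDS = ("up-sweep", "down-sweep", "chevron", "flat")


@dataclass
class SynthSyllableSpec:
    """Parameters of one synthetic frequency-modulated syllable."""

    kind: str = "up-sweep"
    duration_ms: float = 50.0
    f_start: float = 60_000.0
    f_end: float = 80_000.0
    rise_ms: float = 5.0
    fall_ms: float = 5.0
    noise_floor: float = 0.01
    amplitude: float = 0.9

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")


def _freq_trajectory(spec: SynthSyllableSpec, t: np.ndarray) -> np.ndarray:
    """Instantaneous frequency over normalized time u in [0, 1]."""
    u = t / t[-1] if t[-1] > 0 else t
    if spec.kind == "flat":
        return np.full_like(u, spec.f_start)
    if spec.kind == "up-sweep":
        lo, hi = sorted((spec.f_start, spec.f_end))
        return lo + (hi - lo) * u
    if spec.kind == "down-sweep":
        lo, hi = sorted((spec.f_start, spec.f_end))
        return hi - (hi - lo) * u
    # chevron: rise to the higher frequency at midpoint, then fall back
    lo, hi = sorted((spec.f_start, spec.f_end))
    return lo + (hi - lo) * (1.0 - (2.0 * u - 1.0) ** 2)


def synth_syllable(
    spec: SynthSyllableSpec, rate: int = DEFAULT_RATE, rng=None
) -> Waveform:
    """An FM sinusoid following the spec's trajectory, with envelope and noise.

    The phase is the cumulative integral of the instantaneous frequency,
    so spectrogram frame peaks track the commanded trajectory.
    """
    n = int(round(spec.duration_ms / 1000.0 * rate))
    if n < 2:
        raise ValueError("duration too short for the sampling rate")
    t = np.arange(n) / rate
    freq = _freq_trajectory(spec, t)
    if freq.max() >= rate / 2:
        raise ValueError(
            f"frequency {freq.max():.0f} Hz is at or above Nyquist ({rate / 2:.0f} Hz)"
        )
    phase = 2.0 * np.pi * np.cumsum(freq) / rate
    tone = np.sin(phase)

    env = np.ones(n)
    n_rise = min(n // 2, int(round(spec.rise_ms / 1000.0 * rate)))
    n_fall = min(n // 2, int(round(spec.fall_ms / 1000.0 * rate)))
    if n_rise:
        env[:n_rise] = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_rise) / n_rise))
    if n_fall:
        env[n - n_fall:] = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_fall, 0, -1) / n_fall))

    samples = spec.amplitude * env * tone
    if spec.noise_floor > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        samples = samples + rng.normal(0.0, spec.noise_floor, size=n)
    peak = np.abs(samples).max()
    if peak > 1.0:
        samples = samples / peak
    return Waveform(samples, rate)


def synth_corpus(
    n: int,
    seed: int = 0,
    rate: int = DEFAULT_RATE,
    target_length: int | None = None,
    duration_range_ms: tuple[float, float] = (10.0, 130.0),
    band_hz: tuple[float, float] = (40_000.0, 110_000.0),
    noise_floor: float = 0.01,
) -> SyllableCorpus:
    """A corpus of ``n`` syllables with randomized kinds, durations, and sweeps.

    Durations are drawn log-uniformly over 10–130 ms (natural syllable
    corpora are dominated by short syllables) and sweep endpoints
    uniformly inside the 40–110 kHz band.  Reproducible under ``seed``;
    ``target_length`` additionally zero-pads/truncates every item.
    """
    if n < 1:
        raise ValueError("corpus size must be >= 1")
    rng = np.random.default_rng(seed)
    items, labels = [], []
    lo_d, hi_d = duration_range_ms
    lo_f, hi_f = band_hz
    for _ in range(n):
        kind = KINDS[rng.integers(len(KINDS))]
        duration = float(np.exp(rng.uniform(np.log(lo_d), np.log(hi_d))))
        f_a = float(rng.uniform(lo_f, hi_f))
        # sweep span between 5 and 40 kHz, clipped into the band
        span = float(rng.uniform(5_000.0, 40_000.0))
        f_b = float(np.clip(f_a + rng.choice([-1.0, 1.0]) * span, lo_f, hi_f))
        spec = SynthSyllableSpec(
            kind=kind, duration_ms=duration, f_start=f_a, f_end=f_b,
            rise_ms=min(5.0, duration / 4), fall_ms=min(5.0, duration / 4),
            noise_floor=noise_floor,
        )
        w = synth_syllable(spec, rate=rate, rng=rng)
        if target_length is not None:
            w = fix_length(w, target_length)
        items.append(w)
        labels.append(kind)
    return SyllableCorpus(items, labels, split_seed=seed)


# -------------------------------------------------------------------------
# ground-truth neurons
# -------------------------------------------------------------------------

@dataclass
class SynthNeuronSpec:
    """A simulated unit defined by ground-truth spike-probability parameters."""

    params: MNEParams
    trials: int = 20
    bin_ms: float = 5.0
    seed: int = 0


def random_mne_params(
    dim: int,
    seed: int = 0,
    offset: float = 1.5,
    h_scale: float | None = None,
    j_scale: float | None = None,
) -> MNEParams:
    """A random ground-truth (a, h, J) with moderate spiking statistics.

    Default scales put the exponent's stimulus-driven variance near 1 for
    a z-scored design, giving per-bin spike probabilities mostly in
    (0.05, 0.5) at the default offset.
    """
    rng = np.random.default_rng(seed)
    h_scale = 0.5 / np.sqrt(dim) if h_scale is None else h_scale
    j_scale = 0.5 / dim if j_scale is None else j_scale
    h = rng.normal(0.0, h_scale, size=dim)
    raw = rng.normal(0.0, j_scale, size=(dim, dim))
    return MNEParams(offset, h, 0.5 * (raw + raw.T))


def white_noise_design(n_bins: int, dim: int, seed: int = 0, bin_ms: float = 5.0) -> StimulusDesign:
    """A z-scored Gaussian white-noise design matrix (n_bins x dim)."""
    rng = np.random.default_rng(seed)
    return StimulusDesign(rng.normal(size=(n_bins, dim)), bin_ms=bin_ms)


def synth_spikes(spec: SynthNeuronSpec, design: StimulusDesign) -> Raster:
    """Bernoulli raster: trials x bins, spike probability from the ground truth.

    Probabilities are clipped into (0, 1) with a warning when extreme
    parameters push them to the numerical boundary.
    """
    p = spike_probability(spec.params, design.matrix)
    p = np.atleast_1d(p)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        import warnings

        warnings.warn("spike probabilities clipped away from {0, 1}")
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
    rng = np.random.default_rng(spec.seed)
    counts = (rng.uniform(size=(spec.trials, p.size)) < p[None, :]).astype(np.int64)
    return Raster(counts, spec.bin_ms)
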