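"""Generation, encoding, latent interpolation, and stimulus assembly.

A trained generator/encoder pair supports four inference operations:
drawing novel syllables from latent codes, encoding waveforms to codes,
reconstructing syllables as G(E(x)), and decoding linear latent
traversals.  Playback tracks are built by band-limiting syllables to the
ultrasonic band (6th-order Chebyshev Type II high/low-pass cascade,
applied forward-backward so onsets are not delayed) and concatenating
them with fixed silent gaps (100 ms within ordinary stimulus blocks; the
interpolation protocol uses 1 s within a traversal and 2 s between
traversals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .audio import Waveform
from .networks import EncoderNet, GeneratorNet


def _nets(model):
    """Accept a TrainState, a checkpoint-style dict, or a (G, E) tuple."""
    if hasattr(model, "generator"):
        return model.generator, model.encoder
    if isinstance(model, dict):
        return model["G"], model.get("E")
    g, e = model
    return g, e


@dataclass
class StimulusTrack:
    """A playback-ready waveform plus its per-syllable onset table."""

    waveform: Waveform
    onsets: np.ndarray
    offsets: np.ndarray
    gap_ms: float
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("syllable onsets must be strictly increasing")
        if self.offsets[-1] > len(self.waveform):
            raise ValueError("offsets exceed track length")

    def __len__(self):
        return len(self.waveform)

    def onset_table(self):
        """Rows of (index, onset sample, offset sample, provenance)."""
        prov = self.provenance or [""] * len(self.onsets)
        return [
            (i, int(a), int(b), p)
            for i, (a, b, p) in enumerate(zip(self.onsets, self.offsets, prov))
        ]


# -------------------------------------------------------------------------
# model inference
# -------------------------------------------------------------------------

def generate(model, z: np.ndarray, rate: int = 250_000) -> list[Waveform]:
    """Decode latent codes (m, l) or (l,) into waveforms."""
    g, _ = _nets(model)
    z = np.atleast_2d(np.asarray(z, dtype=np.float32))
    out = g.forward(z).data
    return [Waveform(row[0].astype(np.float64), rate) for row in out]


def encode(model, x) -> np.ndarray:
    """Map waveforms onto their latent representations."""
    _, e = _nets(model)
    arr = _as_matrix(x)
    return e.forward(arr.astype(np.float32)).data.astype(np.float64)


def reconstruct(model, x) -> list[Waveform] | Waveform:
    """G(E(x)): deterministic round trip through the latent space."""
    g, e = _nets(model)
    arr = _as_matrix(x)
    z = e.forward(arr.astype(np.float32))
    out = g.forward(z).data
    rate = x.rate if isinstance(x, Waveform) else 250_000
    waves = [Waveform(row[0].astype(np.float64), rate) for row in out]
    return waves[0] if _is_single(x) else waves


def interpolate(model, z_a, z_b, n_points: int = 10, rate: int = 250_000):
    """Decode the linear traversal z_t = (1-t) z_a + t z_b, t = i/(n-1).

    Returns (waveforms, latents); the endpoints decode exactly to
    G(z_a) and G(z_b).
    """
    z_a = np.asarray(z_a, dtype=np.float32).ravel()
    z_b = np.asarray(z_b, dtype=np.float32).ravel()
    if z_a.shape != z_b.shape:
        raise ValueError("latent endpoints must have the same dimension")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    t = np.linspace(0.0, 1.0, n_points, dtype=np.float32)[:, None]
    latents = (1.0 - t) * z_a[None, :] + t * z_b[None, :]
    # decode one code at a time so the endpoint waveforms are bit-identical
    # to single-code generation (batched BLAS sums in a different order)
    waves = [generate(model, latents[i], rate=rate)[0] for i in range(n_points)]
    return waves, latents


def _is_single(x) -> bool:
    return isinstance(x, Waveform) or np.asarray(
        getattr(x, "samples", x)
    ).ndim == 1


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, Waveform):
        return x.samples[None, :]
    arr = np.asarray(x)
    return arr[None, :] if arr.ndim == 1 else arr


# -------------------------------------------------------------------------
# stimulus conditioning
# -------------------------------------------------------------------------

def band_filter(
    w: Waveform,
    hp_hz: float = 40_000.0,
    lp_hz: float = 100_000.0,
    order: int = 6,
    stop_atten_db: float = 40.0,
) -> Waveform:
    """Chebyshev Type II band-limiting cascade (highpass then lowpass).

    Both filters are applied zero-phase (forward-backward), which squares
    the magnitude response and preserves onset alignment.  The cutoff
    frequencies are the stopband edges at ``stop_atten_db``.
    """
    nyq = w.rate / 2.0
    if not 0 < hp_hz < nyq or not 0 < lp_hz < nyq:
        raise ValueError(f"cutoffs must lie below the Nyquist frequency {nyq} Hz")
    sos_hp = signal.cheby2(order, stop_atten_db, hp_hz, btype="highpass",
                           fs=w.rate, output="sos")
    sos_lp = signal.cheby2(order, stop_atten_db, lp_hz, btype="lowpass",
                           fs=w.rate, output="sos")
    y = signal.sosfiltfilt(sos_hp, w.samples)
    y = signal.sosfiltfilt(sos_lp, y)
    return Waveform(y, w.rate)


def assemble_stimulus(
    syllables,
    gap_ms: float = 100.0,
    provenance: list[str] | None = None,
) -> StimulusTrack:
    """Concatenate syllables separated by ``gap_ms`` of silence.

    The onset/offset table indexes each syllable within the track.
    """
    syllables = list(syllables)
    if not syllables:
        raise ValueError("cannot assemble an empty syllable list")
    rates = {s.rate for s in syllables}
    if len(rates) > 1:
        raise ValueError("syllables must share one sampling rate")
    rate = rates.pop()
    gap = int(round(gap_ms * rate / 1000.0))
    pieces, onsets, offsets = [], [], []
    pos = 0
    for i, s in enumerate(syllables):
        if i > 0:
            pieces.append(np.zeros(gap))
            pos += gap
        pieces.append(s.samples)
        onsets.append(pos)
        pos += len(s)
        offsets.append(pos)
    return StimulusTrack(
        Waveform(np.concatenate(pieces), rate),
        np.asarray(onsets), np.asarray(offsets), gap_ms,
        provenance or [],
    )


# -------------------------------------------------------------------------
# spectrograms
# -------------------------------------------------------------------------

def spectrogram(
    w: Waveform,
    window: int = 512,
    overlap: float = 0.75,
):
    """Magnitude-squared STFT.  Returns (power (freq, time), freqs_hz, times_s)."""
    if window >= len(w):
        raise ValueError("STFT window must be shorter than the waveform")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    noverlap = int(window * overlap)
    freqs, times, stft = signal.stft(
        w.samples, fs=w.rate, nperseg=window, noverlap=noverlap,
        boundary=None, padded=False,
    )
    return np.abs(stft) ** 2, freqs, times


def threshold_spectrogram(power: np.ndarray, n_sd: float = 2.0) -> np.ndarray:
    """Display variant: zero cells below mean + n_sd standard deviations."""
    cut = power.mean() + n_sd * power.std()
    out = power.copy()
    out[out < cut] = 0.0
    return out
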