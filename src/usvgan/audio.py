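"""Reading, normalizing, length-standardizing and splitting syllable corpora.

Syllables are short mono waveforms (mouse ultrasonic vocalizations are
recorded at 250 kHz).  A corpus is standardized to one fixed length —
2**15 = 32,768 samples (~130 ms at 250 kHz) by default — by zero-padding
short syllables at the end and keeping the head of long ones, so syllable
onsets stay aligned at t = 0.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

DEFAULT_RATE = 250_000
STANDARD_LENGTH = 2 ** 15  # 32,768 samples


class AudioIOError(IOError):
    """Raised when a WAV file cannot be read or written."""


class UnsupportedFormatError(AudioIOError):
    """Raised for WAV encodings the toolkit does not handle (e.g. multichannel)."""


@dataclass
class Waveform:
    """A mono amplitude series with its sampling rate in Hz."""

    samples: np.ndarray
    rate: int = DEFAULT_RATE

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self):
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.rate


@dataclass
class SyllableCorpus:
    """An ordered collection of equal-rate syllable waveforms."""

    items: list[Waveform]
    labels: list[str] | None = None
    split_seed: int = 0

    def __post_init__(self):
        if self.items:
            rates = {w.rate for w in self.items}
            if len(rates) > 1:
                raise ValueError(f"corpus mixes sampling rates: {sorted(rates)}")
        if self.labels is not None and len(self.labels) != len(self.items):
            raise ValueError("labels length must match items length")

    def __len__(self):
        return len(self.items)

    @property
    def rate(self) -> int:
        return self.items[0].rate if self.items else DEFAULT_RATE

    def to_array(self, target: int | None = None) -> np.ndarray:
        """Stack the corpus as an (N, L) matrix, length-standardizing first."""
        if not self.items:
            raise ValueError("empty corpus")
        if target is None:
            lengths = {len(w) for w in self.items}
            if len(lengths) > 1:
                raise ValueError("items have unequal lengths; pass target")
            target = lengths.pop()
        return np.stack([fix_length(w, target).samples for w in self.items])


# -------------------------------------------------------------------------
# I/O
# -------------------------------------------------------------------------

_PCM_SCALE = {
    np.dtype(np.int16): 2.0 ** 15,
    np.dtype(np.int32): 2.0 ** 31,
}


def read_wav(path) -> Waveform:
    """Read a mono WAV file, scaling integer PCM to [-1, 1].

    16-bit codes are divided by 32768, 32-bit by 2**31; float data is
    taken as-is.  Multichannel files are rejected.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as err:  # noqa: BLE001 - scipy raises plain ValueError
        raise AudioIOError(f"could not read WAV file {path}: {err}") from err
    if data.ndim > 1:
        raise UnsupportedFormatError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype.kind == "f":
        samples = data.astype(np.float64)
    else:
        raise UnsupportedFormatError(f"{path}: unsupported sample dtype {data.dtype}")
    return Waveform(samples, int(rate))


def write_wav(path, w: Waveform, dtype: str = "float32") -> None:
    """Write a waveform as float32 or 16-bit PCM WAV."""
    path = Path(path)
    if dtype == "float32":
        wavfile.write(path, w.rate, w.samples.astype(np.float32))
    elif dtype == "pcm16":
        clipped = np.clip(w.samples, -1.0, 1.0)
        wavfile.write(path, w.rate, np.round(clipped * 32767.0).astype(np.int16))
    else:
        raise ValueError(f"unknown dtype {dtype!r}; use 'float32' or 'pcm16'")


def load_manifest(path, rate_check: bool = True) -> SyllableCorpus:
    """Load a corpus from a plain-text manifest (rows: path[,label]).

    Paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    items, labels = [], []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].lstrip().startswith("#"):
                continue
            items.append(read_wav(path.parent / row[0].strip()))
            labels.append(row[1].strip() if len(row) > 1 else "")
    return SyllableCorpus(items, labels)


# -------------------------------------------------------------------------
# standardization
# -------------------------------------------------------------------------

def fix_length(w: Waveform, target: int = STANDARD_LENGTH) -> Waveform:
    """Zero-pad (at the end) or truncate (keeping the head) to ``target``."""
    if target <= 0:
        raise ValueError("target length must be positive")
    if len(w) == 0:
        raise ValueError("cannot length-standardize an empty waveform")
    s = w.samples
    if s.size >= target:
        out = s[:target].copy()
    else:
        out = np.concatenate([s, np.zeros(target - s.size)])
    return Waveform(out, w.rate)


def normalize_corpus(c: SyllableCorpus) -> SyllableCorpus:
    """Scale all items by the single corpus-wide peak so amplitudes lie in [-1, 1].

    A shared scale preserves relative syllable loudness, which per-item
    normalization would destroy.
    """
    peak = max((np.abs(w.samples).max() if len(w) else 0.0) for w in c.items)
    if peak == 0:
        return c
    items = [Waveform(w.samples / peak, w.rate) for w in c.items]
    return SyllableCorpus(items, c.labels, c.split_seed)


def split_corpus(
    c: SyllableCorpus, train_frac: float = 0.9, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform shuffle split into disjoint train/test index sets.

    The train count is round-half-up of ``train_frac * N``; the remainder
    goes to the test set.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    n = len(c)
    if n == 0:
        raise ValueError("cannot split an empty corpus")
    if seed is None:
        seed = c.split_seed
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(train_frac * n + 0.5))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])
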