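"""Spike-train summaries, sparseness, and receptive-field feature statistics.

Responses are summarized as peristimulus time histograms (trial-averaged
rates, 50-ms bins by default), per-syllable responses (mean PSTH inside
the syllable's presentation window), and responsiveness classes: a
response is "strong" if it exceeds 50% of the unit's maximum response
across both stimulus conditions, "weak" above 25%, otherwise "none".

Selectivity is quantified by the Vinje–Gallant sparseness

    S = (1 - (Σ r_i / n)² / Σ(r_i² / n)) / (1 - 1/n),

which is 0 for equal rates (dense code) and 1 for a one-hot response
(maximally sparse).  The lifetime variant feeds one unit's responses
across syllables; the population variant feeds all units' responses to
one syllable.

Receptive-field features from two stimulus conditions are compared by
matching each feature in one set with the maximally correlated feature
in the other, against a null built by random permutation of a feature's
entries; modulation power spectra (2-D Fourier power of time-frequency
patches) support the same matched comparison, and their UMAP embedding
is a thin delegated call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class Raster:
    """Spike counts (trials x bins) aligned to a stimulus track."""

    counts: np.ndarray
    bin_ms: float

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] < 1:
            raise ValueError("raster must be (trials, bins) with >= 1 trial")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be nonnegative")
        if self.bin_ms <= 0:
            raise ValueError("bin width must be positive")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass
class SparsenessResult:
    value: float
    variant: str  # "lifetime" | "population"
    n: int


def exclude_units(units, min_trials: int = 10):
    """Drop units recorded for fewer than ``min_trials`` stimulus trials.

    ``units`` maps unit ids to trial counts, Rasters, or anything with
    ``n_trials``; a plain sequence of counts is also accepted.  Returns
    the retained ids (or indices).
    """
    def trials_of(u):
        if isinstance(u, Raster):
            return u.n_trials
        if hasattr(u, "n_trials"):
            return u.n_trials
        return int(u)

    if isinstance(units, dict):
        return [k for k, u in units.items() if trials_of(u) >= min_trials]
    return [i for i, u in enumerate(units) if trials_of(u) >= min_trials]


def compute_psth(r: Raster, bin_ms: float = 50.0) -> np.ndarray:
    """Trial-averaged rate in spikes/s, rebinned to ``bin_ms`` bins.

    ``bin_ms`` must be an integer multiple of the raster resolution;
    trailing bins that do not fill a whole PSTH bin are dropped.
    """
    factor = bin_ms / r.bin_ms
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"PSTH bin width {bin_ms} ms is not a multiple of the raster bin {r.bin_ms} ms"
        )
    factor = int(round(factor))
    n_out = r.n_bins // factor
    counts = r.counts[:, : n_out * factor].reshape(r.n_trials, n_out, factor)
    return counts.sum(axis=2).mean(axis=0) / (bin_ms / 1000.0)


def syllable_response(
    psth: np.ndarray,
    onsets,
    offsets,
    psth_bin_ms: float = 50.0,
    rate_hz: float = 250_000.0,
) -> np.ndarray:
    """Mean PSTH over each syllable's [onset, offset) window.

    Onsets/offsets are sample indices on the stimulus waveform (a
    StimulusTrack's tables can be passed directly); a bin at the window
    edge counts if at least half of it is covered.
    """
    if hasattr(onsets, "onsets"):  # a StimulusTrack
        track = onsets
        onsets, offsets = track.onsets, track.offsets
    psth = np.asarray(psth, dtype=np.float64)
    bin_samples = psth_bin_ms / 1000.0 * rate_hz
    out = np.empty(len(onsets))
    for i, (a, b) in enumerate(zip(onsets, offsets)):
        lo = int(np.round(a / bin_samples))
        hi = int(np.round(b / bin_samples))
        hi = max(hi, lo + 1)
        if lo >= psth.size:
            raise ValueError(f"syllable {i} window lies outside the PSTH")
        out[i] = psth[lo:min(hi, psth.size)].mean()
    return out


def classify_responses(resp_a: np.ndarray, resp_b: np.ndarray):
    """Label each syllable per condition as strong (> 50% of the joint
    maximum), weak (> 25%), or none.

    The threshold reference is the maximum response across *both*
    conditions, so the labels are invariant to a common rescaling.
    Returns (labels_a, labels_b).
    """
    resp_a = np.asarray(resp_a, dtype=np.float64)
    resp_b = np.asarray(resp_b, dtype=np.float64)
    if resp_a.shape != resp_b.shape:
        raise ValueError("response vectors must have equal length")
    peak = max(resp_a.max(initial=0.0), resp_b.max(initial=0.0))
    if peak <= 0:
        none = np.array(["none"] * resp_a.size)
        return none, none.copy()

    def label(v):
        return np.where(v > 0.5 * peak, "strong", np.where(v > 0.25 * peak, "weak", "none"))

    return label(resp_a), label(resp_b)


def sparseness(rates, variant: str = "lifetime") -> SparsenessResult:
    """Vinje–Gallant sparseness of a nonnegative rate vector."""
    r = np.asarray(rates, dtype=np.float64)
    n = r.size
    if n < 2:
        raise ValueError("sparseness needs at least 2 rates")
    if np.any(r < 0):
        raise ValueError("rates must be nonnegative")
    if np.all(r == 0):
        raise ValueError("sparseness undefined for an all-zero rate vector")
    if variant not in ("lifetime", "population"):
        raise ValueError("variant must be 'lifetime' or 'population'")
    r = r / r.max()  # scale-invariant; guards against under/overflow of r**2
    s = (1.0 - (r.sum() / n) ** 2 / (r ** 2).sum() * n) / (1.0 - 1.0 / n)
    return SparsenessResult(float(s), variant, n)


# -------------------------------------------------------------------------
# receptive-field feature comparison
# -------------------------------------------------------------------------

def _flat(feature) -> np.ndarray:
    if hasattr(feature, "vector"):
        feature = feature.vector
    return np.asarray(feature, dtype=np.float64).ravel()


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def match_features(f_nat, f_rec):
    """For each feature in ``f_nat``, the maximally correlated feature in ``f_rec``.

    The correlation maximized is the signed Pearson r; matches are chosen
    independently per feature, so one reconstructed feature may be reused.
    Returns a list of (i, j, r) triples.
    """
    nat = [_flat(f) for f in f_nat]
    rec = [_flat(f) for f in f_rec]
    if not nat or not rec:
        raise ValueError("both feature sets must be nonempty")
    dim = nat[0].size
    if any(v.size != dim for v in nat + rec):
        raise ValueError("all features must share one shape")
    out = []
    for i, fi in enumerate(nat):
        rs = [_pearson(fi, fj) for fj in rec]
        j = int(np.argmax(rs))
        out.append((i, j, rs[j]))
    return out


def permutation_null(feature_a, feature_b, rng, n_draws: int = 1, permutation=None):
    """Null correlations from randomly permuting one feature's entries.

    With ``n_draws`` > 1 an array of draws (the null distribution) is
    returned; ``permutation`` forces a specific permutation (testing).
    """
    a = _flat(feature_a)
    b = _flat(feature_b)
    if a.size != b.size:
        raise ValueError("features must share one shape")
    if permutation is not None:
        return _pearson(a, b[np.asarray(permutation)])
    draws = np.array([_pearson(a, b[rng.permutation(b.size)]) for _ in range(n_draws)])
    return float(draws[0]) if n_draws == 1 else draws


def modulation_power_spectrum(
    feature: np.ndarray,
    bin_s: float | None = None,
    band_khz: float | None = None,
):
    """Zero-centered 2-D Fourier power of a (frequency x time) patch.

    Returns (power, temporal_mod_hz, spectral_mod_cyc_per_khz); the axis
    arrays are None unless the bin duration (s) and band spacing (kHz)
    are given.
    """
    feature = np.asarray(feature, dtype=np.float64)
    if feature.ndim != 2 or min(feature.shape) < 2:
        raise ValueError("feature must be a 2-D matrix, at least 2x2")
    power = np.abs(np.fft.fftshift(np.fft.fft2(feature))) ** 2
    n_freq, n_time = feature.shape
    temporal = spectral = None
    if bin_s is not None:
        temporal = np.fft.fftshift(np.fft.fftfreq(n_time, d=bin_s))
    if band_khz is not None:
        spectral = np.fft.fftshift(np.fft.fftfreq(n_freq, d=band_khz))
    return power, temporal, spectral


def compare_paired(values_a, values_b, test: str = "wilcoxon"):
    """Paired two-condition comparison with medians and IQRs.

    Delegates to the Wilcoxon matched-pairs signed-rank test or the
    paired t test.  Identical conditions have no paired differences; the
    Wilcoxon statistic is then undefined and p is reported as 1.0 with a
    warning.  Returns a dict with statistic, pvalue, medians and IQRs.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired comparison needs equal-length samples, n >= 2")
    if test == "wilcoxon":
        if np.all(a == b):
            warnings.warn("all paired differences are zero; reporting p = 1")
            statistic, pvalue = np.nan, 1.0
        else:
            res = stats.wilcoxon(a, b)
            statistic, pvalue = float(res.statistic), float(res.pvalue)
    elif test == "paired_t":
        res = stats.ttest_rel(a, b)
        statistic, pvalue = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError("test must be 'wilcoxon' or 'paired_t'")
    q1a, med_a, q3a = np.percentile(a, [25, 50, 75])
    q1b, med_b, q3b = np.percentile(b, [25, 50, 75])
    return {
        "test": test,
        "statistic": statistic,
        "pvalue": pvalue,
        "median_a": float(med_a),
        "median_b": float(med_b),
        "iqr_a": float(q3a - q1a),
        "iqr_b": float(q3b - q1b),
        "n": int(a.size),
    }


def umap_project(
    matrices,
    n_neighbors: int = 256,
    min_dist: float = 0.0,
    n_components: int = 2,
    metric: str = "euclidean",
    seed: int | None = None,
) -> np.ndarray:
    """UMAP embedding of flattened matrices (delegated to umap-learn)."""
    import umap  # deferred: heavy import

    data = np.stack([_flat(m) for m in matrices])
    reducer = umap.UMAP(
        n_neighbors=min(n_neighbors, data.shape[0] - 1),
        min_dist=min_dist,
        n_components=n_components,
        metric=metric,
        random_state=seed,
    )
    return reducer.fit_transform(data)
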