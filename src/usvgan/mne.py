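"""Maximum-noise-entropy (MNE) receptive-field model.

The model gives the per-bin spike probability as a logistic function of
a quadratic form in the stimulus vector s:

    P(spike | s) = 1 / (1 + exp(a + s·h + sᵀ J s)),

with scalar offset a, linear kernel h, and symmetric quadratic kernel J.
This is the minimal (maximum-entropy) model consistent with the observed
mean rate, spike-triggered average, and spike-triggered covariance; here
the parameters are found by maximizing the Bernoulli likelihood of the
binarized response with full-batch Adam, which yields the same
constrained solution.  Bins are split 80/20 into train/test at random
without replacement, and a slice of the training bins is held out for
early stopping.  Eigenvectors of J are the model's receptive-field
features; because the exponent enters with a positive sign, directions
with negative eigenvalues *increase* spike probability and are labeled
excitatory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class StimulusDesign:
    """Per-time-bin stimulus vectors (rows), typically lagged spectrogram patches."""

    matrix: np.ndarray
    bin_ms: float = 5.0
    n_freq: int | None = None
    n_lags: int | None = None
    freqs_hz: np.ndarray | None = None
    lags_ms: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D (bins x dimensions)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("design matrix contains non-finite entries")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    @property
    def feature_shape(self) -> tuple[int, int] | None:
        if self.n_freq and self.n_lags:
            return (self.n_freq, self.n_lags)
        return None


def design_from_spectrogram(
    power: np.ndarray,
    n_lags: int = 20,
    bin_ms: float = 5.0,
    zscore: bool = True,
    freqs_hz: np.ndarray | None = None,
) -> StimulusDesign:
    """Build lagged stimulus vectors from an (n_freq, n_bins) spectrogram.

    Row t is the flattened patch covering the ``n_lags`` bins ending at
    t (earlier bins zero-padded), so the receptive field spans
    ``n_lags * bin_ms`` ms of stimulus history.  Per-dimension z-scoring
    (the default) puts the quadratic and linear terms on one scale.
    """
    power = np.asarray(power, dtype=np.float64)
    n_freq, n_bins = power.shape
    padded = np.concatenate([np.zeros((n_freq, n_lags - 1)), power], axis=1)
    rows = np.stack(
        [padded[:, t:t + n_lags].ravel() for t in range(n_bins)]
    )
    if zscore:
        sd = rows.std(axis=0)
        sd[sd == 0] = 1.0
        rows = (rows - rows.mean(axis=0)) / sd
    lags = np.arange(n_lags - 1, -1, -1) * bin_ms
    return StimulusDesign(rows, bin_ms, n_freq, n_lags, freqs_hz, lags)


@dataclass
class MNEParams:
    a: float
    h: np.ndarray
    J: np.ndarray

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=np.float64).ravel()
        self.J = np.asarray(self.J, dtype=np.float64)
        d = self.h.size
        if self.J.shape != (d, d):
            raise ValueError("J must be square and match h's dimension")
        if not np.allclose(self.J, self.J.T, atol=1e-8 * max(1.0, np.abs(self.J).max())):
            raise ValueError("J must be symmetric")
        if not (np.isfinite(self.a) and np.all(np.isfinite(self.h)) and np.all(np.isfinite(self.J))):
            raise ValueError("parameters must be finite")

    @property
    def dim(self) -> int:
        return self.h.size

    def concatenated(self) -> np.ndarray:
        return np.concatenate([[self.a], self.h, self.J.ravel()])


def _exponent(p: MNEParams, s: np.ndarray) -> np.ndarray:
    s = np.atleast_2d(np.asarray(s, dtype=np.float64))
    if s.shape[1] != p.dim:
        raise ValueError(f"stimulus dimension {s.shape[1]} != parameter dimension {p.dim}")
    return p.a + s @ p.h + np.einsum("ti,ij,tj->t", s, p.J, s)


def spike_probability(p: MNEParams, s: np.ndarray) -> np.ndarray | float:
    """P(spike | s) = 1 / (1 + exp(a + s·h + sᵀJs)); works on one vector or many rows."""
    arg = _exponent(p, s)
    with np.errstate(over="ignore"):
        prob = 1.0 / (1.0 + np.exp(arg))
    return float(prob[0]) if np.asarray(s).ndim == 1 else prob


def _softplus(x):
    return np.logaddexp(0.0, x)


def _nll_and_grad(theta, X, y, d):
    a, h = theta[0], theta[1:1 + d]
    J = theta[1 + d:].reshape(d, d)
    arg = a + X @ h + np.einsum("ti,ij,tj->t", X, J, X)
    n = X.shape[0]
    nll = (_softplus(arg) - (1.0 - y) * arg).mean()
    p = 1.0 / (1.0 + np.exp(np.clip(arg, -500, 500)))
    w = (y - p) / n                      # d nll / d arg, averaged
    ga = w.sum()
    gh = X.T @ w
    gJ = X.T @ (w[:, None] * X)
    gJ = 0.5 * (gJ + gJ.T)
    return nll, np.concatenate([[ga], gh, gJ.ravel()])


@dataclass
class MNEFitConfig:
    train_frac: float = 0.8
    learning_rate: float = 0.05
    max_iter: int = 3000
    eval_every: int = 10
    patience: int = 5
    holdout_frac: float = 0.1
    seed: int = 0


@dataclass
class MNEFitResult:
    params: MNEParams
    train_idx: np.ndarray
    test_idx: np.ndarray
    test_correlation: float | None = None
    expected_ceiling: float | None = None
    loss_trajectory: list[float] = field(default_factory=list)


def fit_mne(
    design: StimulusDesign,
    spikes: np.ndarray,
    config: MNEFitConfig | None = None,
) -> MNEFitResult:
    """Fit (a, h, J) by penalized-free logistic likelihood ascent.

    ``spikes`` is a per-bin count vector (n_bins,) or a raster
    (trials, n_bins); with a raster, every (trial, bin) sample enters the
    likelihood while the train/test split stays at the level of bins.
    Bins with at least one spike count as spike = 1 in the Bernoulli
    likelihood.  Deterministic under ``config.seed``.
    """
    config = config or MNEFitConfig()
    spikes = np.asarray(spikes)
    raster = spikes if spikes.ndim == 2 else spikes[None, :]
    if raster.shape[1] != design.n_bins:
        raise ValueError("spike bins must match design rows")
    if raster.sum() == 0:
        raise ValueError("degenerate fit: no spikes in the recording")

    rng = np.random.default_rng(config.seed)
    n_bins, d = design.n_bins, design.dim
    perm = rng.permutation(n_bins)
    n_train = int(round(config.train_frac * n_bins))
    train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])

    n_hold = max(1, int(round(config.holdout_frac * n_train)))
    hold_idx = train_idx[rng.permutation(n_train)[:n_hold]]
    fit_idx = np.setdiff1d(train_idx, hold_idx)

    def stack(idx):
        X = np.repeat(design.matrix[idx], raster.shape[0], axis=0)
        y = (raster[:, idx] >= 1).astype(np.float64).T.ravel()
        return X, y

    X_fit, y_fit = stack(fit_idx)
    X_hold, y_hold = stack(hold_idx)
    if y_fit.sum() == 0:
        raise ValueError("degenerate fit: no spikes in the training partition")

    # intercept-only calibration: initial predicted rate = observed mean rate
    p0 = min(max(y_fit.mean(), 1e-6), 1 - 1e-6)
    theta = np.zeros(1 + d + d * d)
    theta[0] = np.log((1.0 - p0) / p0)

    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    b1, b2, eps = 0.9, 0.999, 1e-8
    best = (np.inf, theta.copy())
    worse = 0
    traj = []
    for it in range(1, config.max_iter + 1):
        nll, g = _nll_and_grad(theta, X_fit, y_fit, d)
        if not np.isfinite(nll):
            raise RuntimeError("MNE fit diverged: non-finite training loss")
        traj.append(nll)
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        theta = theta - config.learning_rate * (m / (1 - b1 ** it)) / (
            np.sqrt(v / (1 - b2 ** it)) + eps
        )
        # keep J exactly symmetric
        J = theta[1 + d:].reshape(d, d)
        theta[1 + d:] = (0.5 * (J + J.T)).ravel()
        if it % config.eval_every == 0:
            hold_nll, _ = _nll_and_grad(theta, X_hold, y_hold, d)
            if hold_nll < best[0]:
                best = (hold_nll, theta.copy())
                worse = 0
            else:
                worse += 1
                if worse >= config.patience:
                    break
    theta = best[1] if np.isfinite(best[0]) else theta
    params = MNEParams(theta[0], theta[1:1 + d], theta[1 + d:].reshape(d, d))
    result = MNEFitResult(params, train_idx, test_idx, loss_trajectory=traj)
    result.test_correlation = predict_and_score(result, design, spikes, test_idx)
    if raster.shape[0] >= 2:
        result.expected_ceiling = expected_correlation(raster[:, test_idx])
    return result


def predict_and_score(
    result_or_params, design: StimulusDesign, spikes: np.ndarray, idx=None
) -> float:
    """Pearson r between predicted spike probability and observed response.

    The observed response is the raw count (trial-averaged for rasters).
    Constant predictions make the correlation undefined; a warning is
    issued and 0 returned.
    """
    params = getattr(result_or_params, "params", result_or_params)
    if idx is None:
        idx = getattr(result_or_params, "test_idx", np.arange(design.n_bins))
    spikes = np.asarray(spikes, dtype=np.float64)
    rate = spikes.mean(axis=0) if spikes.ndim == 2 else spikes
    pred = spike_probability(params, design.matrix[idx])
    obs = rate[idx]
    if pred.std() == 0 or obs.std() == 0:
        warnings.warn("constant predictions or responses: correlation undefined, reporting 0")
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1])


def expected_correlation(raster: np.ndarray, n_trials: int | None = None) -> float:
    """Split-half ceiling on achievable prediction correlation.

    Trials are split into interleaved halves, each half is averaged into
    a rate series, and the half-to-half correlation r is mapped through

        r_ceiling² = 2 / (1 + sqrt(1 / r²)) = 2 / (1 + 1/r)   (r > 0),

    the expected correlation between the true rate and the full M-trial
    average under independent trial noise.  Returns the positive root
    (0 when the halves are uncorrelated or anticorrelated).
    """
    raster = np.asarray(raster, dtype=np.float64)
    if raster.ndim != 2 or raster.shape[0] < 2:
        raise ValueError("need a raster with at least 2 trials")
    if n_trials is not None:
        raster = raster[:n_trials]
    half_a = raster[0::2].mean(axis=0)
    half_b = raster[1::2].mean(axis=0)
    if half_a.std() == 0 or half_b.std() == 0:
        raise ValueError("constant half-mean rates: split-half correlation undefined")
    r = float(np.corrcoef(half_a, half_b)[0, 1])
    if r <= 0:
        return 0.0
    r2 = 2.0 / (1.0 + 1.0 / r)
    return float(np.sqrt(min(r2, 1.0)))


@dataclass
class RFFeature:
    """An eigenvector of J interpreted as a receptive-field component."""

    vector: np.ndarray
    eigenvalue: float
    lambda_norm: float
    polarity: str  # "excitatory" | "inhibitory"

    def as_patch(self, shape: tuple[int, int]) -> np.ndarray:
        return self.vector.reshape(shape)


def extract_features(
    params: MNEParams,
    top_k: int | None = None,
    negative_is_excitatory: bool = True,
) -> list[RFFeature]:
    """Eigen-features of J ordered by |eigenvalue| descending.

    lambda_norm is the eigenvalue divided by the total |eigenvalue| mass,
    so the absolute normalized weights sum to 1.  Under the model's sign
    convention a negative eigenvalue raises spike probability, hence the
    default excitatory label for negative eigenvalues.
    """
    eigvals, eigvecs = np.linalg.eigh(params.J)
    total = np.abs(eigvals).sum()
    if total == 0:
        return []
    order = np.argsort(-np.abs(eigvals))
    feats = []
    for i in order[: top_k if top_k else len(order)]:
        lam = float(eigvals[i])
        excit = lam < 0 if negative_is_excitatory else lam > 0
        feats.append(
            RFFeature(
                vector=eigvecs[:, i].copy(),
                eigenvalue=lam,
                lambda_norm=lam / total,
                polarity="excitatory" if excit else "inhibitory",
            )
        )
    return feats
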