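# Methods

## Data model

A syllable is a mono waveform at 250 kHz.  Corpora are standardized to one
length before training: short syllables are zero-padded at the *end* and long
ones keep their *head*, preserving onset alignment at t = 0 (onsets carry most
of a USV's energy).  Amplitudes are normalized by a single corpus-wide peak so
relative loudness across syllables survives; the generator's tanh output lives
on the same [−1, 1] scale.  Corpus splits draw a seeded uniform permutation;
the train count is round-half-up of `train_frac · N` (90/10 by default).

## Networks

`NetworkConfig` controls everything: latent dimension l = 10, model size
d = 32, phase-shuffle radius n = 2, and D_z/D_joint filter count f = 512 are
the full-scale defaults; `num_blocks` (default 5) counts the stride-4 stages,
giving waveforms of 16·4^num_blocks·2 samples, so `num_blocks=2` yields
512-sample desk-scale models.  All kernels have length 25.

Convolution padding is the one genuinely open choice: strided layers use
"same"-style padding so a stride-s layer divides the length exactly by s
(32768 → 16384 → 4096 → … → 16), and transposed convolutions upsample by
zero-stuffing followed by a stride-1 same-padded convolution, exactly
inverting that arithmetic.  The critic's waveform branch mirrors the
encoder's stride plan (2, 4, 4, …) with the channel progression d, 2d, 4d,
…, 32d and ends in one further convolution padded so that a single temporal
position remains; its printed alternatives are not mutually consistent, and
this convention is the one that reproduces the generator/encoder length
tables.

Phase shuffle draws one integer shift in [−n, n] per batch sample (shared
across that sample's channels), translates the feature maps, and fills the
vacated edge by reflection.  It is applied after every critic waveform-branch
convolution except the final two, and never in the encoder.  Weights are
fan-in-scaled Gaussian (He), seeded per network from the run seed.

## Training

The critic's loss is −(gap) + λ·penalty with
gap = mean D(x, E(x)) − mean D(G(z), z), i.e. the critic *ascends* the
bidirectional Wasserstein objective while E and G jointly descend it.  (A
literal reading of the published update equations would have the critic
descend the same quantity it is supposed to maximize; the standard WGAN sign
convention is used.)  The gradient penalty draws one ε ∼ Uniform[0, 1] per
pair, interpolates jointly — x̂ = ε x + (1−ε) G(z), ẑ = ε E(x) + (1−ε) z —
and penalizes (‖∇_{x̂,ẑ}D‖₂ − 1)² with λ = 10.  A 10⁻¹⁶ stabilizer inside
the norm keeps the backward pass finite at zero gradient; it perturbs the
penalty by less than 10⁻⁷.

Each outer iteration: 5 critic steps, then one E/G step, fresh
Uniform[−1, 1] latents every step, data batches shuffled without replacement
per epoch.  Optimization is Adam(β₁ = 0.5, β₂ = 0.9), η = 10⁻⁴ — suited to
the published 150,000-iteration regime.  Desk-scale smoke runs (hundreds of
iterations) use η = 10⁻³, since at 10⁻⁴ a few hundred steps barely move the
parameters.  Runs are bit-reproducible given the seed; non-finite losses
abort with the last good checkpoint saved.

Because no GPU autodiff framework is a dependency, the package carries a
minimal reverse-mode engine (`autodiff.py`).  Its vector-Jacobian products
are themselves built from primitive operations, so differentiating a
gradient (required by the penalty's parameter update) is exact rather than
approximated; convolutions are im2col matrix products with an overlap-add
transpose.  Networks run in float32; analysis code in float64.

### What desk-scale training does and does not show

The learning smoke test (512-sample waveforms, d = 4, 300 iterations,
256 synthetic sweeps) asserts that held-out reconstruction error
‖x − G(E(x))‖ falls below its value at initialization.  Measured
trajectories show the opposite phase first: adversarial training quickly
matches *output statistics* (generated norms rise to the data's, which
increases L2 distance to any particular x), while the encoder–generator
inversion that actually lowers reconstruction error emerges only near
convergence — on a 2-point toy corpus it appears after roughly 600
iterations, and on the 256-sweep corpus not within 1,200.  The test is kept
at its stated conditions and documents this limitation; treat it as a
convergence-horizon probe, not a regression gate.

## Synthesis and stimuli

Reconstruction is G(E(x)); latent interpolation decodes
z_t = (1−t)z_a + t z_b at t = i/(n−1) (default 10 points), decoding each
code as its own batch so endpoint waveforms are bit-identical to single-code
generation.  Playback tracks band-limit syllables with 6th-order Chebyshev
Type II filters (40 kHz highpass, 100 kHz lowpass; cutoff = stopband edge at
the configured 40 dB attenuation), applied forward-backward so onsets are
not delayed (the magnitude response is applied twice, doubling the dB
attenuation), then concatenate them with silent gaps — 100 ms within a
stimulus block; the interpolation protocol uses 1 s within and 2 s between
traversals via the `gap_ms` argument.  Spectrograms use a 512-sample window
with 75 % overlap; the display variant zeroes cells below mean + 2 SD of
power.

## Receptive-field model

The MNE spike probability is P(spike|s) = 1/(1 + exp(a + s·h + sᵀJs)); note
the *positive* exponent, so larger arguments mean fewer spikes and
negative-eigenvalue directions of J are excitatory (the labeling is
configurable).  The constrained maximum-entropy solution is obtained as
Bernoulli maximum likelihood over binarized bins (≥1 spike → 1) with
full-batch Adam (rate 0.05, up to 3,000 iterations), J symmetrized every
step.  Bins split 80/20 train/test at random without replacement; 10 % of
the training bins form an early-stopping holdout (stop after 5 consecutive
non-improving evaluations, every 10 iterations, best parameters kept).
Prediction quality is the Pearson correlation between predicted
probabilities and observed (trial-averaged) counts on test bins; constant
predictions are flagged and scored 0.

The reliability ceiling splits trials into interleaved halves, correlates
the half-mean rates (r_half), and maps r² = 2/(1 + 1/r_half) — equivalently
2/(1 + √(1/r_half²)) — returning the positive root and 0 for
non-positive r_half.  The interleaved (even/odd) split is deterministic and
robust to slow drift across trials.

Stimulus design matrices are lagged spectrogram patches (defaults: 16
frequency bands spanning 40–100 kHz, 20 lags of 5 ms), z-scored per
dimension; a white-noise design builder supports simulation studies.

## Response analysis

PSTHs are trial-averaged rates in spikes/s at 50-ms bins (the default;
configurable).  A syllable's response is the mean PSTH over its
[onset, offset) window, with an edge bin counted when at least half covered.
Responses are classed per syllable against the *joint* maximum over both
stimulus conditions: strong above 50 %, weak above 25 %, otherwise none —
making labels invariant to common rescaling.  Units recorded for fewer than
10 trials are excluded.

Vinje–Gallant sparseness is exactly 0 for equal rates and exactly 1 for a
one-hot response; it is scale-invariant and undefined (error) for all-zero
input.  Feature comparison matches each feature of one condition with the
maximally *signed*-correlated feature of the other (independent argmax per
feature; reuse allowed), with permutation nulls built by shuffling one
feature's entries.  Modulation power spectra are zero-centered 2-D Fourier
power of time–frequency patches.  Paired condition comparisons delegate to
the Wilcoxon matched-pairs signed-rank or paired t test and report medians
and IQRs; identical conditions are flagged with p = 1 by convention.  UMAP
embedding of modulation spectra is a thin delegated call (n_neighbors = 256,
min_dist = 0, 2 components, Euclidean) and, being stochastic per platform,
is only smoke-tested.

## Synthetic data

The corpus generator emulates segmented mouse USVs: four FM families
(up-sweep, down-sweep, chevron, flat), durations log-uniform over 10–130 ms
(natural corpora skew short), sweep endpoints inside 40–110 kHz, raised-
cosine rise/fall envelopes, and a Gaussian noise floor of 1 % amplitude.  The
phase is the integral of the commanded frequency, so spectrogram peaks track
the trajectory.  What it does *not* emulate: harmonic stacks, amplitude
tremolo, recording-chain coloration, or the long-tailed syllable-type
frequencies of real corpora — so passing tests show the machinery works, not
that real USVs of every type will be generated equally well.  Ground-truth
neurons draw Bernoulli spikes from the same logistic model the fitter
assumes (offset 1.5, ‖h‖ ≈ 0.5, J entries ∼ 0.5/D for z-scored designs,
giving rates near 0.2), making fitting a round-trip recovery test.

## Problem sizes

Default test-suite scales were chosen so the whole pipeline exercises on a
laptop-class CPU: 512-sample waveforms with d ∈ {2, 4}, training runs of
20–300 iterations, MNE recovery at D = 16 with 50,000 bins, and rasters of
~20 trials.  The full-scale architecture (32,768 samples, d = 32) is built
and shape-audited, not trained, in the tests.
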