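# Methods

`neurotraj` analyzes multimodal recordings from a structured live-interaction
paradigm: 30-second blocks in which a partner watches a short valenced movie
(4 s), makes direct or diverted eye contact (5 s), repeats the movie/gaze pair,
and rests behind an opaque smart glass (12 s). Each subject contributes 24
blocks (6 per valence × gaze condition) of simultaneous EEG (32 channels,
256 Hz → 7680 samples/block), fNIRS HbDiff (134 channels, 8.13 Hz → 244
samples) and OpenFace-style facial action units (17 AUs on the fNIRS clock).
The analysis learns latent trajectories per block with a recurrent
autoencoder, summarizes them geometrically (curvature at the four task-switch
times: 4, 9, 13, 18 s) and topologically (truncated path signatures), and
evaluates patient/control classification and severity regression under
leave-one-subject-out (LOSO) cross-validation.

## Recurrent encoder–decoder

The encoder is a stack of LSTM layers (3 by default) with latent width 128,
run over one block of one modality:

    h_t = ENC(x_{t−1}, h_{t−1}),  t = 1..τ,  x_0 = 0.

The printed one-step input lag is kept as stated (`h_t` depends only on the
strict past), which the causality tests pin down; for every downstream
property the shift is immaterial. The final embedding `h_τ` initializes the
hidden **and** cell states of all decoder layers, and the decoder generates
the output modality autoregressively with `y_0 = 0`:

    y_t = DEC(y_{t−1}, h_τ),  t = 1..τ′.

Training uses teacher forcing (ground-truth `y*_{t−1}` as the decoder input),
an RMSE loss over all time steps and channels of the batch, and Adam with
l2 regularization applied to weight matrices (not biases). Learning rate and
weight decay are grid-searched (`{1e−2, 1e−3, 1e−4} × {0, 1e−5, 1e−4}` by
default) on a held-out block split inside the training subjects. The whole
model is implemented in float64 numpy with explicit backpropagation through
time — gradients are validated against central finite differences in the test
suite — so a fixed seed reproduces training bit-for-bit on any platform.
Truncated BPTT is not used; full sequences at the lengths the pipeline feeds
the model (≤ 244 steps after EEG decimation, below) are tractable on one CPU
with small batches (`batch_size` is the memory knob).

**Unimodal vs joint models.** With input modality = output modality the model
is a reconstruction autoencoder; with different modalities it learns a
cross-modal translation and its latents form a joint representation of the
pair. The translation direction is configurable. The package default for
joint pairs puts **fNIRS on the encoder side** (`fnirs→eeg`,
`fnirs→faceau`): the hemodynamic response to the gaze segments persists to
the end of the block, so `h_τ` retains condition- and group-relevant
amplitude information, whereas an EEG encoder must carry switch-locked
transients across the 12-s rest (96 decimated steps) under a teacher-forced
objective that gives it little incentive to do so. In our desk-scale
experiments the EEG-encoder direction produced markedly less informative
final embeddings, and we made the fNIRS-encoder direction the default.

**EEG preprocessing.** EEG is band-passed into delta (0.5–3 Hz), theta
(4–7 Hz) or alpha (8–13 Hz) with a 4th-order Butterworth applied
forward–backward (zero phase, so switch-locked transients are not delayed),
after 1-s reflect padding. One autoencoder is trained per band. In the
pipeline, band-passed EEG is then decimated before the autoencoder; the
default factor 32 (256 → 8 Hz, 240 samples/block, Nyquist 4 Hz) is
alias-free for the delta band, which is also where the synthetic class
effect lives, so delta is the default band; theta and alpha runs should use
`eeg_downsample` of 16 and 8 respectively to keep their passbands below the
decimated Nyquist. Channels are
z-scored per block (never per session), so no statistic crosses subject
boundaries.

## Path signatures

For a latent trajectory `h(t) ∈ R^d`, each component is standardized to mean
0 and standard deviation 1 across time points (population convention, i.e.
divide by τ; constant components are zeroed and flagged), the time interval
is affinely rescaled to [0, 1], and the truncated signature of the
piecewise-linear path is computed exactly: each linear segment contributes
its tensor exponential (Δ^⊗k / k!) and segments chain by Chen's identity.
Each level `S^k` (a d^k tensor) is then divided by its Euclidean norm
(all-zero levels stay zero), and levels 1..N are flattened in lexicographic
order. Depth defaults to N = 2 (d + d² features; 16 512 at d = 128), which
keeps the 4-layer MLP head tractable; N = 4 is reasonable for d ≤ 8 paths.
Signatures are computed on the full latent trajectory, not on the 3-D
embedding. Time rescaling is a no-op for the exact signature (which is
reparameterization-invariant, as the tests verify) but is retained for
pipeline fidelity and matters if the optional time-augmentation flag
(append rescaled time as an extra coordinate; off by default) is enabled.

## Temporal diffusion embedding

Curvature is computed on a 3-D embedding of the latent trajectory, produced
by a diffusion-based manifold embedding that combines feature-space
proximity with temporal autocorrelation:

1. an adaptive-bandwidth alpha-decay kernel on latent-space distances
   (bandwidth = 3 × the distance to the 5th nearest neighbour, decay
   exponent 2, symmetrized);
2. a temporal kernel `exp(−lag²/2w²)` whose width `w` is the lag at which
   the trajectory's mean channel autocorrelation first drops below 1/e;
3. the two row-stochastic operators are mixed 3:1 (feature:temporal),
   diffused for t steps with t auto-selected at the knee of the von Neumann
   entropy of the operator spectrum (capped at 20), and the rows of the
   log-potential `−log(P^t + ε)` are embedded by classical MDS.

Every step is deterministic (eigenvector signs are fixed by making each
component's largest-magnitude entry positive), so identical inputs give
identical coordinates; the `seed` field in `EmbeddingParams` is surfaced for
config completeness only. The kernel mixing weight and bandwidth scale were
chosen so that a noisy trajectory confined to a 3-D affine subspace of
R^128 is reproduced with Spearman distance-rank fidelity > 0.8 while the
embedded path remains temporally smooth; both contracts are pinned by tests.

## Curvature by local circle fitting

At each point `p` of the embedded curve, the neighborhood covering 8% of the
curve length (fraction configurable) is sampled symmetrically around `p`,
centered on its mean, and SVD yields the two in-plane directions; the
neighborhood is projected onto that plane and a circle is fitted by
algebraic (Kåsa) least squares. Curvature is κ = 1/r. Conventions for the
cases the recipe leaves open:

* at curve ends the symmetric window shrinks (min(p, τ−1−p, k/2) per side);
  points with fewer than 4 neighbors are excluded from the profile;
* collinear neighborhoods (second singular value ≈ 0) and fitted radii
  beyond 10⁶ × the trajectory diameter give κ = 0, avoiding float blow-up on
  straight segments;
* the four switch-time curvatures are read at sample indices
  `floor(t_switch × rate)` (block-local time, t = 0 at block onset, sample i
  covering [i/rate, (i+1)/rate)); an unsupported index falls back to the
  nearest supported point with a warning.

Against closed forms, the fitted κ is exact to ~1% on circles of any radius
and orientation and within 5% of R/(R²+c²) on a helix at the default
neighborhood fraction. Group contrasts (patient vs control within condition,
direct vs diverted gaze within group, positive vs negative valence within
group) use two-sided Mann–Whitney U tests (exact null for small samples).

## Evaluation protocol

Classification heads: a 2-layer MLP on final embeddings (hidden 64), a
4-layer MLP on signatures (512/128/32), a 3-layer MLP on switch-curvature
4-vectors (32/16), all ReLU + softmax with cross-entropy (scikit-learn),
plus RBF-SVM and stand-alone MLP baselines on flattened, downsampled raw
blocks. Hidden widths are package defaults, config-exposed. Every head is
evaluated LOSO: one fold per subject, classifier retrained per fold with a
fold-local seed, per-block patient probabilities returned. Block-level
accuracy is the primary metric; subject-majority-vote accuracy is reported
as secondary. The train/test disjointness of every fold is asserted, not
sampled. A block-level random split is provided only as a cautionary
comparison: when subjects carry idiosyncratic signal it is optimistically
biased, which the tests reproduce directionally.

Severity prediction averages the 24 block probabilities of each patient
(clinical scores are never used in training) and correlates the predictions
with GAF and PANSS scores min–max normalized to [0, 1]; Pearson is primary,
Spearman reported for robustness. Controls are excluded from the
correlation; fewer than 3 scored patients or degenerate variance yields NA
with a warning.

## Synthetic cohorts

The generator emulates the study structure — 19 control-like and 14
patient-like subjects by default, 24 blocks each, native rates and channel
counts — with planted effects in the directions the analysis is designed to
detect:

* **EEG**: per-channel sinusoids with random phases and per-band amplitudes
  (delta 1.0, theta 0.8, alpha 0.6 — a rough 1/f ordering), Gaussian noise
  (sd 0.5), and a Gaussian transient (σ = 0.2 s, ≈0.5 s FWHM) at each switch
  time with amplitude `amp[group] × 1.3^(direct gaze) × 1.3^(negative
  valence)`; patient amplitude 2.5 vs control 1.0, per-subject lognormal
  jitter (σ = 0.15).
* **fNIRS**: a double-gamma HRF (peak ≈ 6 s, undershoot ≈ 16 s, ratio 1/6)
  convolved with a boxcar over the gaze segments and scaled by the same
  effective amplitude, mixed (coupling 0.4) with the low-passed,
  mean-removed EEG amplitude envelope resampled to 8.13 Hz, plus noise
  (sd 0.3).
* **faceAU**: activations elevated during movie segments, Gaussian-smoothed,
  rectified nonnegative, plus noise (sd 0.2).
* per-subject channel gains (sd 0.15) plant the subject-idiosyncratic signal
  that makes random block splits optimistic;
* synthetic GAF decreases (slope −18 × severity_link per unit amplitude from
  a baseline of 85) and PANSS-positive increases (+6 from 7) linearly in the
  subject's realized amplitude with Gaussian jitter; PANSS-negative gets
  only a weak link, mirroring its weak empirical association.

Every draw comes from a per-subject generator seeded by (master seed,
CRC32(subject id)), so cohorts are reproducible subject-by-subject. What the
generator does **not** emulate: volume conduction and realistic EEG forward
physics, physiological noise structure (cardiac/respiratory bands, motion),
optode-distance-dependent fNIRS sensitivity, non-stationarity across blocks,
or missing data. Passing tests therefore demonstrate that the pipeline
recovers effects of this planted form at these SNRs — not performance on
real recordings.

## Verification experiment designs

Three design choices in the verification experiments deserve explanation:

* **Cross-modal pairing control.** Whether a translation model has learned
  anything pair-specific is measured by training on matched vs permuted
  block pairings and comparing held-out RMSE with the decoder running free
  from `h_τ` alone. Teacher-forced RMSE is the training objective but a
  poor probe: for a smooth, delayed target like the fNIRS hemodynamic ramp,
  the previous ground-truth sample predicts the next one so well that
  pairing information barely moves the score. The control therefore uses
  the EEG→faceAU pair with targets on their raw amplitude scale — the
  shared per-block effect amplitude is expressed in the AU level from block
  onset, so a latent that carries it lowers free-running RMSE and a
  permuted-pairing model cannot.
* **Amplitude sweep (curvature monotonicity).** The planted patient
  transient amplitude is varied (1.0 → 2.5 → 4.0) while the trained joint
  model is held fixed and all other per-subject random draws are kept
  identical, making the sweep a paired comparison of the planted effect's
  downstream footprint. Retraining the model at every amplitude level
  confounds the comparison with training variability and is not done.
* **Permutation null.** Chance-level classification is measured as the mean
  LOSO accuracy over 8 balanced label permutations. Because all 24 blocks
  of a subject share a label, permutation accuracy is quantized at the
  subject level (not block-binomial); the mean over permutations
  concentrates near 0.5 with a standard error of roughly 0.09 at 8
  subjects, and is asserted within ±0.2.

## Problem sizes used in tests and the acceptance script

Cohorts of 4+4 to 5+8 subjects, latent width 8–16, 2–3 LSTM layers, 4–10
epochs, and delta-band EEG decimated to 8 Hz are the package's desk-scale
defaults for verification runs; they keep every property measurable while a
full-scale configuration (19+14 subjects, latent 128, 3+3 layers) remains
the `PipelineConfig` default. The planted-easy verification condition
(patient transient amplitude 4.0 vs 1.0, reduced noise, coupling 0.5) is the
separability-ceiling case used where a property needs headroom (e.g. block
accuracy > 0.9).

## Known limitations

* Teacher forcing lets the decoder lean on the fed-back target sequence, so
  the information that survives into `h_τ` depends on the translation
  direction (see above); scheduled sampling is deliberately not implemented.
* The embedding is O(τ²) in memory/time; full-rate EEG trajectories
  (τ = 7680) should be decimated before embedding (the pipeline always
  embeds at ≤ 244 points).
* The Kåsa circle fit is biased toward smaller radii for very noisy, widely
  scattered neighborhoods; at the 8% neighborhood fraction used here the
  bias is far below the 1% oracle tolerance.
* Severity correlations on small synthetic cohorts are sign-stable but
  magnitude-noisy; only their sign is asserted.
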