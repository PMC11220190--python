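# Methods

This note documents the model, the synthetic data it is exercised on, the
numerical choices, and the limits of what the test suite demonstrates.

## Model and objective

The segmenter is a 2-D U-Net: an encoder of `depth` pooling stages
(DoubleConv blocks of conv3×3–BN–ReLU ×2, widths doubling from `base_width`)
and `n_decoders` independent decoders (bilinear 2× upsampling, skip
concatenation, DoubleConv per level, 1×1 head to two-class logits with a
channel softmax). The encoder is shared; decoder 0 is the primary decoder
and the only one run at inference. Each auxiliary decoder i ≥ 1 sees the
bottleneck FA perturbed by elementwise Gaussian noise ε_i ~ N(μ_i, σ_i²),
resampled every forward pass from a run-level seeded stream. Skip
connections are never perturbed: the perturbation is defined on FA alone, so
the auxiliary branches disagree through their bottleneck input and their
independent weights, which is exactly the diversity the consistency loss
consumes. "Gaussian noise with mean 1 added" is read literally as additive
N(1, σ²); a multiplicative mode (`FA ⊙ ε`) is provided as a configuration
option since mean-1 noise is conventionally multiplicative, and the mode in
force is recorded in the resolved run config.

Supervised loss (labeled crops, primary decoder only): pixel-mean
cross-entropy plus soft (un-thresholded) Dice averaged over the two classes.
Unsupervised loss (unlabeled crops): every decoder's tumor probability is
sharpened with temperature T (default 0.5) and thresholded at 0.5 into a
hard pseudo-label; the multi-consistency loss is the literal **sum** over
all n(n−1) ordered decoder pairs of CE + Dice between decoder i's map and
decoder j's hard label, with no pair averaging — the small warm-up amplitude
absorbs the scale. Pseudo-labels are plain arrays, so no gradient can flow
through the target side by construction. Total loss: λ·L_s + β(t)·L_u with
λ = 0.5 and β(t) = 0.001·exp(−5(1 − t/t_max)²), which rises monotonically to
0.001 at the final iteration.

Two deliberate conventions, both configurable:

* **Tie-break.** A sharpened probability of exactly 0.5 maps to class 0
  (normal). Deterministic, and favors the majority background class.
* **Hard vs soft targets.** Pairwise targets default to the hard labels
  P_H; a `soft` mode uses the two-channel soft label (1−P_S, P_S) instead.
  In the binary case the hard path is provably T-invariant — sharpening is
  strictly monotone, so argmax∘sharpen = argmax (asserted over a 101×4 grid
  in the tests) — which means temperature can only influence training
  through the soft path. Both readings are therefore kept available.

## Training procedure

Batches pair one random square crop from a labeled scene with one from an
unlabeled scene. An epoch is one pass over the unlabeled pool (each
unlabeled scene exactly once, in a fresh permutation), while the labeled
pool cycles with reshuffling; with no unlabeled scenes the loop degrades to
supervised-only training. Optimization is SGD with classical momentum
(lr 0.01, momentum 0.9), no learning-rate decay, 100 epochs by default
(`max_iterations` can fix the horizon directly). Three seeded PCG64 streams
separate the sources of randomness — weight initialization, feature noise,
data order — so an ablation can change exactly one. Once per `val_every`
epochs the primary decoder is scored on the labeled pool and the best
checkpoint is kept alongside the final one.

Full scenes are segmented by overlapping tiles (50% overlap by default),
averaging per-pixel tumor probabilities over covering tiles before
thresholding at 0.5. Tiling interacts with two global operations: batch-norm
statistics and convolution zero-padding make a tile's prediction differ
slightly near its borders from a whole-image pass, so tiled and single-pass
probabilities agree approximately, not bitwise; the tests bound this gap.

## Preprocessing

PCA is fitted once on pixel spectra pooled across **all** training scenes,
labeled and unlabeled (transductive convention), after per-band
standardization (bands span different intensity scales), then frozen and
applied to every scene including test scenes; default k = 6 components. At
most 100,000 pixels are used (seeded subsample). Component signs follow the
largest-|entry|-positive convention so fits are reproducible; a
zero-variance band has its scale clamped to 1 with a logged warning rather
than failing.

## Synthetic data

The generator emulates the structure of microscopic hyperspectral pathology
data at desk scale — the default is 64×64 scenes with 16 bands uniformly
spanning 550–1000 nm, 80 scenes (66 train / 14 test), tumor fraction in
[0.15, 0.45] — standing in for 1024×1280×60-band acquisitions. Class
spectra are sums of ≤ 3 Gaussian bumps over wavelength with distinct bump
positions per class; spectral smoothness and between-class contrast are the
only spectral properties the method relies on, so measured endmembers are
not required. A scene is

    cube[p, b] = spectrum(class(p), b) · illum(p) + ε_pix(p, b) + offset(b)

with per-scene amplitude jitter of the bumps (σ_spec = 0.02), a smooth
multiplicative illumination field (±10%), i.i.d. pixel noise
(σ_pix = 0.08) and a shared per-band offset (σ_band = 0.04) that gives PCA
correlated band noise to remove. Tumor morphology alternates between
smooth-field blobs and connected annuli ("rings" whose opening never
breaks); both are produced with an exact pixel count via order statistics,
so measured tumor fractions always respect the configured range. Everything
is a pure function of (seed, scene_index) through PCG64, hence bit-identical
across runs and platforms. In the exact noiseless limit all four
perturbation amplitudes (σ_pix, σ_band, σ_spec and the illumination
amplitude) must be zero; then every pixel equals its class mean spectrum.

What the generator does **not** model: histology texture, stain variation,
spatially correlated class-dependent noise, label noise, or the extreme
class imbalance and boundary ambiguity of real pathology. Passing tests
therefore demonstrate that the machinery is correct and that the
semi-supervised signal helps on a learnable spectral-contrast task — not
that the method reaches any particular accuracy on real tissue.

## Numerical choices

* Cross-entropy probabilities clipped to [1e-7, 1−1e-7]; gradients vanish
  where the clip is active.
* Dice smoothing ε = 1e-5 in numerator and denominator, mean over the two
  classes. An absent class's Dice term is then ~1−ε/|den| rather than
  exactly 1, a ~5e-5 effect the oracle tests account for.
* Degenerate evaluation cases are defined, not errors: an absent truth
  class's recall is 1 unless pixels were falsely assigned to it (then 0);
  Dice with no tumor anywhere is 1; all are logged.
* Bilinear upsampling uses half-pixel (align_corners=False) sampling
  expressed as a cached interpolation matrix; its backward pass is the exact
  adjoint (asserted via ⟨Ux, y⟩ = ⟨x, Uᵀy⟩).
* He-normal initialization; BN momentum 0.1, eps 1e-5, batch statistics over
  (N, H, W).
* All backward passes are validated against central finite differences at
  float32-appropriate tolerances.

## Problem sizes used in the automated checks

The behavioral checks run at sizes chosen to keep a full suite run at a few
minutes on one CPU core: the overfit-capacity check trains a depth-3,
width-8 network on 2 labeled 64×64 scenes for 200 iterations (Dice ≥ 0.95);
the semi-supervised directional check trains the 3-decoder model and the
single-decoder supervised baseline for 10 epochs (600 iterations) with
depth 3, width 8, crop 32 on the default 80-scene dataset at 10% labeling,
over 3 seeds, comparing median pooled test Dice (the consistency model must
not trail the baseline by more than 0.01 — in practice it leads on every
seed). These budgets are far below the default 100-epoch schedule; they are
chosen as the smallest sizes at which the respective properties are stable.

## Known limitations

* Batch norm with batch size 1 is effectively instance normalization during
  training; running statistics still converge in practice at these sizes.
* The NumPy stack targets desk-scale problems; it is single-threaded apart
  from BLAS and has no GPU path.
* With hard pairwise targets, temperature T cannot affect training (see
  above); any T sensitivity requires the soft mode.
* The semi-supervised margin on synthetic scenes is small because the task
  is nearly spectrally separable — the baseline already performs well; the
  check is directional by design.
* ENVI support covers the common microscopy cases (uint16/float32, BSQ/BIL/
  BIP, single header+raw pair); exotic header fields are ignored.
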