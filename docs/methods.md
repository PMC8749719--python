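# Methods

## Overview

This package implements an adversarial infrared/visible face-image fusion
model together with the two evaluation layers that justify it: a six-metric
fusion-quality suite and a PCA-LDA nearest-neighbor face-recognition
verification pipeline with k-fold cross-validation.  Everything is
exercisable end-to-end on synthetic paired face phantoms, so the package
carries its own data model.

## Fusion model

The generator is an autoencoder mapping a 2-channel stack (visible,
infrared) to a single fused image.  The encoder is a densely connected
stack of five size-preserving 3x3 convolution layers (stride 1, padding 1):
layer k consumes the concatenation of the raw input and all previous layer
outputs, each layer contributing 16 feature maps, so the concatenated
widths grow 2, 18, 34, 50, 66 and the final encoder feature has 82
channels.  The decoder narrows 82 -> 64 -> 32 -> 16 -> 8 -> 1 with the same
size-preserving convolutions.  Hidden activations are LeakyReLU (slope
0.2); the output is a sigmoid, so fused pixels live in [0, 1].  Since no
layer changes spatial size, the generator runs at any input size >= 8x8.

The discriminator scores whether an image looks like a real visible image:
three stride-2 3x3 convolutions (16, 32, 64 channels) with batch
normalization and LeakyReLU, then one linear unit with a sigmoid.  The
linear head fixes the discriminator's input size; it is a configuration
field and training infers it from the data.  Published experiments in this
problem setting use 128x128 crops; the desk-scale runs here use 32x32,
which changes only the discriminator head (the generator is fully
convolutional).

Weights are He-initialized (fan-in, LeakyReLU gain) from seeded generators;
two builds from the same seed are bit-identical.

No GPU framework is used: the networks run on a small reverse-mode
autodiff core over numpy (`ftsgan.autodiff`) whose convolutions are
im2col-lowered onto BLAS matrix products.  Training uses float32; the
public loss and metric APIs compute in float64.

## Loss functions

The generator objective is `L_G = L_Ga + (1 - L_Gb) + L_Gc` with

* `L_Ga = E[ln(1 - D(G(v,i)))]` — the original (non-saturating in neither
  sense; the classical minimax form) adversarial term, natural log;
* `L_Gb = (1.0 * SSIM(G, v) + 0.7 * SSIM(G, i)) / 1.7` — a weighted
  structural-similarity reward.  The printed form of this term applies a
  "SSIM norm" to the weighted residual `1.7 G - v - 0.7 i`, which is not a
  well-formed one-argument SSIM; we read it as the weighted similarity
  above (weights 1 and 0.7 for visible and infrared, renormalized), which
  matches the stated intent of keeping more visible detail.  The
  alternative reading — `SSIM(G, (v + 0.7 i)/1.7)` — is available behind
  the `ssim_blend` flag.  Both give `L_Gb = 1` when `G = v = i`.
* `L_Gc = 0.5 ||G - i||_F + 0.7 ||G - v||_F + 0.7 ||G - v||_TV` — the
  intensity/gradient content term with the published coefficients.

The discriminator keeps the original GAN objective
`L_D = E[-ln D(v)] + E[-ln(1 - D(G(v,i)))]`.

Numerical conventions:

* SSIM uses a Gaussian 11x11 window (sigma 1.5), stabilizers
  `C1 = (0.01 R)^2`, `C2 = (0.03 R)^2` with dynamic range `R = 1`, and
  averages over valid windows only.  The implementation agrees with
  `skimage.metrics.structural_similarity(gaussian_weights=True, sigma=1.5,
  use_sample_covariance=False)` to machine precision, which the tests
  assert as an independent cross-check.
* The Frobenius distance is divided by `sqrt(M N)` and the anisotropic L1
  total variation by `M N`, making the content term resolution-independent
  so it cannot swamp the logarithmic adversarial term at larger image
  sizes.
* TV is the anisotropic L1 variant (sum of absolute forward differences),
  the standard choice for edge-preserving fusion penalties.
* Discriminator probabilities are clamped to `[1e-7, 1 - 1e-7]` inside the
  loss ops so saturated sigmoids cannot produce infinities; the public
  loss API additionally rejects scores outside (0, 1).

## Training procedure

Per epoch, mini-batches (default 16, seeded shuffle, remainder kept) drive
one discriminator pass (real = visible images, fake = detached fused
images) and one generator pass, both updated by Adamax (the infinity-norm
Adam variant), default learning rate 1e-3.  Running minima `L_MIN` of each
player's epoch loss are tracked; a player whose loss has not come within a
fixed margin (default 5 loss units, configurable because it is clearly
data-scale dependent) of its running minimum during the last 5 epochs is
granted up to 4 extra passes that epoch.  This is a terminating reading of
the published "repeat training until close to L_MIN" balancing rule, whose
printed form is ambiguous (both players' minima share one symbol and the
repeat condition is stated with the inequality reversed).

Every `eval_every` epochs (default 20) the generator is scored on a
holdout (or the training set) with the six fusion metrics; with
`keep_checkpoints=True` the generator weights at each checkpoint are
retained and `restore_checkpoint` rebuilds any of them.  Checkpoint
selection by fusion quality matters in practice: as adversarial training
converges, the unsquared-norm content term drives the fused image toward
the more heavily weighted visible source, and mid-training checkpoints
with the highest QABF (the metric that explicitly rewards carrying
information from *both* sources) give the most useful fusions.  The
end-to-end pipeline therefore selects the best-QABF checkpoint rather than
the last epoch.

Everything derives from one seed and reruns are bit-identical.  Because
epochs are processed with an identical per-epoch randomness stream, a
2-epoch run equals the first two epochs of a 200-epoch run, which is how
the tests verify reproducibility cheaply.

## Fusion-quality metrics

Six scores, all on the internal [0, 1] scale: entropy of the 256-bin
gray-level histogram (bits, bounded by 8); population standard deviation;
mean gradient (mean magnitude of backward differences, averaged over the
(M-1)(N-1) interior); spatial frequency (root of mean squared row and
column differences with 1/(MN) normalization); PSNR in dB against the
visible image by default (the discriminator's reference; the reference is
a flag) with `MAX = 1` and an infinite sentinel for identical images; and
QABF, the windowed fusion-quality index.

QABF internals are underdetermined in the literature that prints only the
combining formula, so the package fixes the standard construction: the
per-window quality `Q0` is the universal image quality index
`4 cov mu_a mu_f / ((var_a + var_f)(mu_a^2 + mu_f^2))`; the saliency
weight `lambda(w)` is the local-variance share of the first source; `W` is
all 8x8 windows at stride 1.  Degenerate windows follow fixed conventions
(both-constant windows: `Q0 = 1` iff means equal and nonzero, else 0;
vanished saliency: `lambda = 0.5`), making every value deterministic and
loop-oracle-testable.

## Synthetic face phantoms

The generator emulates an aligned visible/thermal face gallery whose
identity signal is split across modalities — the regime in which fusing
can beat either channel alone:

* geometry (face ellipse, eye/mouth placement) renders in the visible
  channel; the thermal silhouette deliberately uses shared, generic axes
  (thermal body outlines are blurry and carry little identity);
* fine oriented skin texture, hard-edged eyes and mouth: visible only
  (high spatial frequency);
* a 4-hotspot thermal layout (centers, widths, peaks): infrared only
  (smooth, distinct histogram).

Poses are small rigid jitters (rotation <= 2.5 degrees, translation <= 1.5
px) applied identically to both channels, so pairs stay aligned.  Each
modality carries its own realistic nuisance: the visible channel a
per-pose illumination factor U(0.65, 1.0) and pixel noise sigma 0.02; the
infrared channel stronger pixel noise (sigma 0.05), a per-pose gain/offset
thermal drift, and a physiological drift of the hotspot pattern itself.
These magnitudes were chosen once so that, under the recognition pipeline
below, each single modality plateaus in the 80-90% range while a fused
image that carries both signals scores higher — the qualitative effect the
fusion model exists to produce.  The phantoms are analytic functions
evaluated on transformed coordinates (no interpolation), so everything is
deterministic in the seed.

What the phantoms do *not* model: photorealistic faces, expression
taxonomies, eyeglass reflections, occlusions, or sensor-specific artifacts.
Passing tests on phantoms therefore demonstrates the pipeline's mechanics
and the direction of the fusion benefit, not absolute accuracy levels on
real thermal/visible data.

## Recognition pipeline

Images are flattened to vectors; PCA (scikit-learn, full SVD) reduces to
the dimension explaining 95% of training variance, capped at
`n_train - n_classes` so the within-class scatter stays invertible; LDA is
solved as the generalized symmetric eigenproblem `S_b w = lambda S_w w`
(scipy), keeping at most C-1 directions, with a singular `S_w` diagnosed
explicitly (advice: reduce the PCA dimension).  Probes take the label of
the Euclidean nearest neighbor among projected training images (ties to
the lowest gallery index).

Folds are pose-index-ordered: each subject's 12 poses split into 6 folds
of 2 (general k is supported; at least 2 images per subject per fold are
required).  Cross-validation fits the full PCA→LDA cascade per fold on the
other k-1 folds.  Fold exclusion (the published tables drop fold 1, whose
images are flagged as poor-quality side faces) is an explicit argument;
retained-fold averages are rounded to two decimals and fused-minus-visible
deltas to one, matching the published table convention.

## Problem sizes

Desk-scale defaults keep the full pipeline inside a small CPU budget while
preserving every mechanism: 32x32 phantoms; 10 subjects x 12 poses for
recognition experiments; fusion training on 60 pairs (the first six poses
of every subject) for 60 epochs at learning rate 5e-4 with checkpoint
evaluation every 5 epochs and best-QABF checkpoint selection; 200-epoch
smoke runs on 20 pairs for loss-descent checks.  These sizes are the
package's own study conditions; at 128x128 and hundreds of epochs only
wall-clock time changes.

## Known limitations

* Adversarial training on tiny datasets is noisy; individual late-epoch
  models can regress toward the visible source (see checkpoint selection
  above).  The pipeline's guarantees are directional (fused >= visible),
  not fixed-magnitude.
* The recognition pipeline is the classical linear cascade; it is
  deliberately not a deep face recognizer, mirroring the verification
  design it reproduces.
* PSNR against the visible source is a convention; against the infrared
  source the ranking of fusion models can differ.
* The printed "1 x 2 x 128 x 128" first-layer shape of the published
  architecture is internally inconsistent with dense growth; the channel
  bookkeeping used here (16 maps per layer, 82-channel dense feature) is a
  documented convention honoring the stated connectivity.
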