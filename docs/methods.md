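# Methods

## Problem and model

Tongue image quality assessment is a binary decision — is a captured
tongue photograph clinically usable? — that depends on properties of the
tongue region (sharpness, exposure, full extension), not of the whole
frame.  The package trains a multi-task network in which tongue
segmentation acts as an auxiliary task for the quality classifier:

* **Shared encoder.** `encoder_depth` stages of two 3x3 convolutions +
  ReLU followed by 2x2 max-pooling, widths doubling per stage from
  `base_channels`, then a two-convolution bottleneck.  The spatial side
  must be divisible by `2^encoder_depth`.
* **Segmentation branch.** U-Net decoder: bilinear 2x upsampling (fixed
  half-pixel interpolation matrices; the gradient is the exact transpose
  map), concatenation with the matching encoder stage, two convolutions;
  a 1x1 convolution and per-pixel 2-way softmax produce
  background/tongue probabilities at input resolution.  Channel dropout
  (rate 0.5) is applied to the bottleneck *on the decoder path only*: it
  regularizes the segmentation subnetwork and drives MC-dropout
  uncertainty, while the classifier reads the undropped shared features.
  (Placing the dropout on the shared trunk also destabilized joint
  classification at desk scale.)
* **Classification branch.** `cls_blocks` ResNet-style residual blocks
  (two 3x3 convolutions + identity skip, no normalization layers at these
  widths) on the bottleneck, global average pooling, one fully connected
  layer, 2-way softmax (low, high).

The encoder can optionally start from a user-supplied checkpoint
(`pretrained`); no weights are downloaded, and all shipped experiments
train from He-initialized weights.

## Losses

With per-pixel tongue probability ŷ and binary mask y:

* `L_CE`: one-hot two-channel cross-entropy, **mean** over pixels and
  batch (mean keeps the scale independent of resolution and batch size;
  this choice also changes the absolute loss magnitudes that σ sees, so
  converged σ values are comparable only within this convention).
* `L_Dice = 1 - (2 Σ yŷ + ε) / (Σ ŷ² + Σ y² + ε)` with ε = 1e-6, summed
  globally over the tongue channel; empty-vs-empty counts as perfect.
* `L_Seg = L_CE + L_Dice`, both components logged.
* `L_Cla`: binary cross-entropy on the high-quality probability, batch
  mean.  Probabilities are clamped to [1e-7, 1-1e-7] everywhere, so all
  losses are finite even at saturation.

Multi-task objectives: `L_total = L_Cla + L_Seg` (equal) or the adaptive
form `Σ_i [L_i/(2σ_i²) + log(1+σ_i²)]` with the nonnegative regularizer.
For fixed L > 0 the unique positive stationary σ solves 2σ⁴ = L(1+σ²),
i.e. σ² = (L + √(L²+8L))/4; smaller task losses pull σ below 1 and hence
the effective weight 1/(2σ²) above 1.  σ positivity is enforced
structurally: σ = 1e-3 + softplus(u) with u unconstrained, initialized so
σ = 1 exactly.

## Training

Adam; learning rate 1e-4, weight decay 5e-4, batch size 4 at clinical
scale (the "paper" profile).  The encoder is frozen for the first
`freeze_epochs` (10 of 50 at clinical scale) while decoder and classifier
train, then everything trains at the same learning rate without resetting
optimizer state.  The σ pair is optimized jointly but with its own
learning rate (`sigma_lr`, default 1e-2) and no weight decay: the scalars
are O(1) quantities whose useful dynamic range (≈0.4–1.2) would take
thousands of steps to traverse at the network learning rate, and decaying
them would bias the objective toward σ = 0.  Model selection keeps the
epoch with the best validation accuracy (classification-bearing arms) or
best validation DSC (segmentation-only); augmentation (shared random
translation ±10% and rotation ±15°, image bilinear / mask nearest) is
applied to training batches only.  All randomness — shuffling, dropout,
augmentation — flows from the run seed, and the test suite pins BLAS to
one thread so logged trajectories are bit-reproducible across machines.

Desk-scale profile (the sizes used by the tests and the reproduction
script, chosen as this package's standard small-compute condition):
64x64 scenes, encoder_depth 3, base_channels 6, 12 epochs (3 frozen),
learning rate 3e-4, batch 4, no ImageNet normalization.  The higher
learning rate compensates for the 4x shorter schedule; at 1e-4 the desk
runs end mid-convergence.

## Synthetic benchmark

The generator emulates the structure of clinical tongue scenes, not their
appearance:

* **Geometry.** An ellipse with a smoothed lower tip (axis ratio 0.6–1.2,
  tip bump 10–30%), area 10–60% of the frame, rasterized by the
  pixel-center rule so the mask is exact.
* **Photometry.** Tongue: pinkish tint with mean luminance (RGB mean)
  drawn from [0.42, 0.62] plus fine texture (amplitude 0.035).
  Background: skin-toned value noise whose luminance ([0.15, 0.45]),
  texture amplitude ([0.03, 0.12]), hue jitter and directional lighting
  gradient (≤0.15) vary *independently* of the tongue — whole-frame
  statistics are deliberately unreliable, so quality judgements require
  attending to the tongue region, mirroring the clinical motivation for
  the segmentation auxiliary task.
* **Defects** (drawn uniformly for low-quality scenes): Gaussian blur
  σ ∈ [1.5, 4] px; exposure scaling with factor ∈ [1.6, 2.4] (over) or
  [0.3, 0.6] (under), applied through a feathered tongue-centered profile
  (full factor on the tongue surface, 25% floor far away) because
  exposure errors hit the lit subject hardest; partial extension keeps
  the top 35–65% of the mask area with a flat cut and backfills the
  removed region with the stored background layer.  Severity ranges are
  package choices — clinical severities are not quantified anywhere — and
  are configurable in `SceneParams`.
* **Determinism.** Every image derives a counter-based sub-seed from the
  dataset seed, so single scenes regenerate independently.

A rule-based heuristic (mean tongue luminance thresholds 0.38/0.66,
tongue-region Laplacian variance ≥ 2e-3, bottom-mask-row width < 55% of
the maximum row width) classifies a default 200-scene set with ≥ 95%
accuracy.  This certifies separability — the benchmark is learnable by
the small test-scale networks — and nothing more.

What passing on this benchmark does **not** show: robustness to real
tissue appearance (coating, fissures, papillae), camera color profiles,
annotation noise, or defect severities outside the configured ranges.
Accuracy levels here are not comparable to clinical numbers.

## Metrics

Classification (positive class = high quality): accuracy, precision,
recall, F1, pooled over images.  Segmentation (positive class = tongue):
DSC, Jaccard, MIoU = mean of tongue and background IoU, and
frequency-weighted IoU, computed per image and reported mean ± population
sd (a dataset-pooled variant sits behind `pooled_segmentation=True`).
Conventions, flagged in reports: zero-denominator precision/recall/F1 are
0; an absent class contributes IoU 1 to MIoU (its FWIoU weight is 0);
classification ties resolve to high quality.

## Numerical choices

float32 throughout; convolutions evaluated channels-last as one GEMM
against all kernel taps plus shifted slice-sums (no im2col gathers);
max-pool routes the gradient to a single argmax per window; Dice/CE
guards as above; Adam ε = 1e-8.  Divergence (non-finite loss) aborts with
the offending epoch and component named rather than continuing.

## Known limitations

* The ablation at desk scale has seed-to-seed accuracy spread of several
  points on a 47-image test split; orderings are only meaningful as means
  over seeds.
* Converged σ values depend on the loss-reduction convention and dataset;
  they are logged for inspection, never asserted against external values.
* The engine is CPU-only and sized for desk-scale experiments; the
  "paper" profile (224x224, width 64) is defined and correct but slow on
  one core.
* Grad-CAM taps the encoder bottleneck (configurable in code); other tap
  points give coarser or finer maps.  The uncertainty statistic is
  predictive entropy in bits (range [0, 1] by construction); a scaled
  variance alternative is available behind a flag.
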