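# Methods

## Problem and data model

A quantitative-phase image (QPI) records, per pixel, the optical
path-length delay of transmitted light in arbitrary phase units.  For a
single yeast cell the phase ordering is background ≈ 0 < cytosol <
lipid droplet, because droplets have the highest refractive index of
the cytosolic structures.  `dropseg` treats droplet localization as
binary semantic segmentation: every pixel is lipid (1) or non-lipid
(0).  Inputs are single-band 32-bit float TIFFs; masks are 8-bit
single-band TIFFs stored as {0, 255} on disk and {0, 1} in memory.

## Preprocessing

Images are min-max rescaled per image to 8 bits, `v ↦ round(255·(v −
min)/(max − min))` with round-half-up (deterministic across platforms).
A constant image has no signal and maps to all 0.  Per-image
normalization is the default because phase offsets drift between
acquisitions; the observed (min, max) is recorded with every normalized
image so a global policy can be layered on top if a calibrated rig
makes absolute phase comparable across images.  For the convolutional
network, images are centre-padded with zeros to a square canvas
(default 256), odd remainders to the right/bottom; zero is the natural
fill because background phase is ≈ 0.  The pad record makes the
operation exactly invertible.

## The filter bank (k = 80)

Pixel classification needs a per-pixel feature vector.  The default
bank has exactly 80 layers, the first being the retained normalized
image, over a geometric sigma ladder σ ∈ {0.3, 0.7, 1.0, 1.6, 2.5,
3.5, 5.0, 7.5, 10.0} (pixels):

| family | parameters | layers |
|---|---|---|
| identity (retained image) | — | 1 |
| Gaussian smoothing | 9 σ | 9 |
| difference of Gaussians | 8 consecutive σ pairs | 8 |
| Laplacian of Gaussian | 9 σ | 9 |
| Sobel magnitude after smoothing | 9 σ | 9 |
| Gaussian gradient magnitude | 9 σ | 9 |
| structure-tensor eigenvalues (large, small) | 9 σ × 2 | 18 |
| median smoothing | windows {3,5,…,31} | 9 |
| intensity-quantile threshold maps | q ∈ {0.1,…,0.8} | 8 |

All convolutions reflect at the image border (half-sample symmetric),
avoiding spurious edge responses.  The Laplacian-of-Gaussian family is
implemented as the discrete 3×3 Laplacian of the Gaussian-smoothed
image rather than the analytic second-derivative kernel: the discrete
stencil is exactly zero-sum, so constant regions respond exactly 0 at
every σ, including σ < 0.5 where a truncated analytic kernel is badly
sampled.  Features are computed on the 8-bit image and stored as
float32.  Banks serialize to YAML; a content hash (`bank_id`) travels
with every feature stack and trained model so that features from a
different bank are rejected at classification time.

Flattening maps a set of (stack, mask) pairs to one (n × k) matrix with
n = Σ wᵢ·hᵢ rows in image order, row-major within each image — exactly
invertible given the image shapes.

## Classical per-pixel classifiers

Five backends with fixed reference hyperparameters: random forest (100
trees), XGBoost (100 trees, max depth 4, subsample 0.5), SVM
(polynomial kernel, degree 3, gamma "scale", max 1000 iterations,
5000 MB kernel cache), MLP (hidden layers 50 and 25, ReLU, Adam, max
1000 iterations, halt after 50 without improvement), and LDA (SVD
solver).  Thread counts are advisory caps (≤ 25, bounded by available
CPUs).  All stochastic learners take an explicit seed (default 0).  No
class reweighting is applied: droplet pixels are a small minority and
the consequences of that imbalance are part of what the evaluation
suite measures.

Score maps are posterior probabilities where the backend provides them
(trees, MLP, LDA); SVM decision values pass through a logistic
squashing so every method exposes a uniform [0, 1] score for ROC
analysis.  Binary output uses each method's native rule (probability
≥ 0.5 / non-negative decision value).  Feature importance is exposed
for the tree ensembles only, normalized to sum to 1; linear and kernel
models raise an unsupported-operation error rather than faking a
ranking.  Non-convergence inside the iteration caps (SVM, MLP) is
recorded in the training summary, not fatal.

## The convolutional segmenter

The U-Net dialect: encoder of four blocks of two 3×3 same-padded
biased ReLU convolutions at widths 64/128/256/512, each followed by
2×2 max pooling, with dropout 0.5 after the 512-level convolutions;
two 3×3 convolutions at 1024 plus dropout 0.5 in the bottleneck; a
decoder of four stages of non-learned 2×2 nearest upsampling, a 2×2
ReLU convolution at the stage width, concatenation with the matching
encoder map (the dropout-modified map at the 512 level), and two 3×3
convolutions; then a 3×3 two-filter ReLU convolution and a 1×1
convolution whose sigmoid output is the per-pixel probability.  This
dialect totals exactly 31,031,685 trainable parameters, counted as
Σ (k_h·k_w·c_in + 1)·c_out over convolutions; pooling, upsampling,
dropout and concatenation contribute none, so the count is invariant
to canvas size.

The network is implemented directly in NumPy: im2col/col2im
convolutions (zero "same" padding, odd remainder bottom/right as usual
for even kernels), max-pool gradients routed to the first maximum,
inverted dropout active only during training, He-normal weight
initialization, and a numerically stable binary cross-entropy on
logits (`softplus(z) − y·z`) with the sigmoid applied on top for
probabilities.  Backpropagation is verified in the test suite against
float64 central finite differences (biases randomized slightly off
zero there, because zero-initialized biases feeding dead-ReLU regions
sit exactly on the ReLU kink where the one-sided derivative differs).

Training knobs (the underlying study names none): Adam at learning
rate 1e-3 — the optimizer's standard default, which converges well
within the short desk-scale epoch budgets; 1e-4 is a reasonable
conservative alternative for long full-scale runs — batch size 2,
shuffled each epoch from the run seed.  Batches stream through the
model, so peak memory is set by the batch, not the dataset.  Two runs
with the same seed are bit-identical (weight init, shuffles and
dropout masks all derive from it).  At inference the probability map
is cut at 0.7 with a ≥ rule and un-padded to the original image size.
A desk-scale configuration (widths/8 = 8/16/32/64, bottleneck 128,
canvas 64) is first-class (`reduced_config()`) so the full train /
segment path runs on one CPU in minutes.

## Evaluation

Pixelwise confusion counts feed the six scores: accuracy, balanced
accuracy ((TP/P + TN/N)/2), precision, recall, Dice/F1 =
2TP/(2TP+FP+FN), Jaccard = TP/(TP+FP+FN).  A score with a zero
denominator (e.g. precision when nothing is predicted positive and no
positives exist) is genuinely uninterpretable; it is reported as NaN,
flagged, and excluded from cross-fold averages with the exclusion
counted — never coerced to 0 or 1.  ROC curves sweep all distinct
thresholds; AUC uses the Mann–Whitney convention (ties count ½).  The
harness averages per-image scores (pooled pixel counts are also
emitted per fold for anyone preferring pooled scoring).

Protocols: contiguous unshuffled k-fold cross-validation (default
k = 5; uneven folds put the larger folds first) and a
training-set-size sweep that draws seeded subsets from a pool and
reports the median per-image Dice on one fixed, disjoint test set.

## Synthetic scenes

Each scene: one elliptical cell (random semi-axes, orientation and
small centre jitter) at phase 1 on a background of 0, with 0–6
non-overlapping circular droplets (radius 2–5 px) at a higher phase,
drawn to fit entirely inside the cell; masks are rasterized from the
geometry before noise, so ground truth is exact.  Additive Gaussian
noise (and optional blur) perturbs the image only.  Presets: *easy* —
droplet phase 3, noise sd 0.1, no blur (contrast far above the noise
floor, as in a well-focused high-lipid-content cell); *hard* — droplet
phase 1.6, noise sd 0.35, blur sd 1.0 (droplet-minus-cytosol contrast
below 2 noise sd, stressing the classifiers).  Desk-scale experiment
sizes default to 150 training / 60 test images at 64×64, standing in
for full-scale protocols of thousands of 256×256 images, which remain
configurable.

What the generator does *not* emulate: real phase noise statistics
(speckle, halo artifacts of phase reconstruction), intra-cell texture,
droplet clusters and partial occlusion, out-of-focus light, apoptotic
or budding morphologies, and multi-cell crowding.  Passing tests on
these scenes therefore demonstrate that the pipeline's mechanics are
correct and that each learner can recover a known generative rule —
not that any particular accuracy will transfer to real microscope
data.

## Numerical choices and degenerate inputs

Round-half-up quantization; constant images normalize to all 0;
threshold comparisons are ≥ everywhere (phase baseline, probability
cutoff) so boundary behaviour is exact; odd pad remainders go
right/bottom; empty stacks, ragged z-stacks, single-class training
labels, bank mismatches, oversized images and zero-pixel comparisons
are all rejected with specific errors rather than silently handled.

## Known limitations

- The NumPy network trains at desk scale only; full-scale 256×256
  training at 1000 epochs is out of reach without GPU acceleration
  (the configuration remains expressible).
- SVM on large pixel matrices is impractically slow (cubic in the
  sample count) and is exercised on small matrices only; with its
  iteration cap it may also predict heavy false positives — the
  behaviour the evaluation metrics are designed to expose.
- Per-image min-max normalization ties feature scales to each image's
  dynamic range; calibrated cross-image phase comparisons would need a
  global normalization policy.
- Object-level (per-droplet) metrics, boundary-distance metrics, data
  augmentation and learned feature selection are out of scope.
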