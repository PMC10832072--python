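# Methods

This note records the model, the choices that were genuinely open, the
numerical conventions, and what the synthetic experiments do and do not
demonstrate.

## The augmentation model

A mosaic training image is a 2×2 tiling of representative patches from four
source images: one drawn (with replacement) from each of the K = 3 classes,
plus one from a uniformly random class, so every mosaic contains every
class. Its label is the vector of exact fractional areas each class covers.

*Split point.* The cut $(f_x, f_y)$ is uniform on $(0,1)^2$ conditioned on
$\max(f_xf_y,\,(1{-}f_x)f_y,\,f_x(1{-}f_y),\,(1{-}f_x)(1{-}f_y)) > 1/2$,
drawn by rejection sampling (acceptance measure $2-2\ln 2 \approx 0.6137$;
the 1,000-try cap is unreachable in practice). The constraint guarantees a
dominant class per mosaic. Splits whose pixel rounding
$(\mathrm{round}(f_x S), \mathrm{round}(f_y S))$ would produce an empty
quadrant on an $S$-pixel canvas are resampled; this can only happen at
extreme splits on small canvases.

*Quadrant assignment.* The class receiving the dominant quadrant is drawn
from the `oversample_allocation` probability vector — uniform by default;
`inverse_frequency_allocation` implements the by-area oversampling of
minority classes used in the end-to-end comparison. The remaining three
slots are shuffled uniformly over the remaining quadrants.

*Soft labels* use the exact products of split fractions, not rounded pixel
counts: rounding-free, always summing to 1, and equal to the pixel count in
the large-canvas limit (the tests verify agreement with 1000×1000 pixel
counting within 2×10⁻³).

*Representative regions.* Grad-CAM at the designated layer (the backbone's
last convolution — the standard choice), target class = the image's
ground-truth label (labels are known at augmentation time), channel weights
= spatially averaged gradients, ReLU on the weighted sum, bilinear
upsampling to image size, min–max normalization. A constant map normalizes
to zero and yields an all-true Otsu mask, i.e. the whole image is treated
as representative — this keeps the pipeline total instead of dropping
images. Otsu uses a 256-bin histogram; pixels strictly above the threshold
are representative. Connected components are 8-connected (diagonal lesion
fragments merge); ties on component size go to the first component in
raster-scan order. All coordinates are 0-based half-open so boxes compose
with numpy slicing. Region boxes are cached per source image id — Grad-CAM
is the expensive step and must not be recomputed per mosaic.

## Training protocol

Stage 1 trains on the original images with inverse-frequency class weights
$w_c = n/(K n_c)$ (the product $w_c n_c$ is constant, so each class
contributes equally to the expected loss) and the full augmentation policy:
zoom 0.8–1.0, horizontal/vertical flips, rotation ±30°, shifts ±10% of the
side, nearest-pixel boundary fill, composed into a single bilinear affine
resampling. Training runs in two phases mirroring the transfer-learning
protocol: the dense head alone at `learning_rate`, then the whole network
at the lower `fine_tune_learning_rate` (the config enforces
fine-tune < base). The best-validation-accuracy checkpoint is returned;
accuracy is the headline metric, so it drives checkpoint selection.

Stage 2 trains on the concatenation of original one-hot samples (stage-1
policy) and mosaic soft-label samples (flips and ±5° rotation only — enough
to keep the network off the cross-shaped seam between patches), uniformly
shuffled into mixed batches. Two contested choices are exposed as
configuration rather than silently resolved:

- `stage2_init`: `pretrained_base` (default) restarts from the base
  initialization; `stage1_weights` continues from stage 1. The protocol
  descriptions support both readings.
- `stage2_class_weight`: off by default — the mosaic dataset already
  embodies an oversampling effect through patch resampling and dominant-
  quadrant allocation, so stacking loss weights on top is not the baseline
  configuration.

Prediction consumes real images only and takes the argmax of the
probability vector; ties break to the lowest class index.

The backbone is a compact numpy CNN (3×3 same-padding convolutions as nine
shifted matmuls, ReLU, 2×2 max pooling, global average pooling, dense
softmax head, Adam) with a fully explicit backward pass — the gradient of a
class logit with respect to any conv layer's activations, which Grad-CAM
needs, comes from the same code path and is finite-difference-verified in
the tests. "Pretrained base" means a fixed, seed-determined He
initialization shared by all fits; large-scale pretraining is out of scope
at this problem size, but the two-phase schedule and the re-initialization
semantics of the curriculum are preserved. Any model exposing
`cam_data(image, target_class) -> (activations, gradients)` can replace it.

Defaults: channels (16, 32, 64, 64), 2 head epochs at 10⁻², 20 fine-tuning
epochs at 3×10⁻³, batch 32. These were sized so that the balanced synthetic
task is reliably learned to ≥ 0.9 validation accuracy within 20 epochs —
the separability floor the synthetic generator is contracted to provide.
All randomness (generator, splits, augmentation draws, weight init, mosaic
building) is seed-threaded; BLAS-level nondeterminism is the only tolerated
variation.

## Dataset splitting

The test partition is drawn first and stratified so that per-class
proportions reflect the full dataset: each class contributes
$\lfloor n_c \cdot \text{test\_frac} \rfloor$ images (at least one when the
class can spare one). With 1,810 images at 372/141/1297 and a 10% test
fraction this gives the 37 + 14 + 129 = 180-image test set of the reference
protocol — per-class flooring, not largest-remainder to a rounded total,
which would give 181. The remainder is split 70/30 into train/validation by
largest-remainder allocation across classes, which uses every image exactly
once.

## The synthetic generator

The generator emulates the *structure* of small-lesion clinical
photographs, not their appearance: an elliptical object on a dark surround
(so Grad-CAM has a meaningful foreground), exactly one class motif per
image — dark irregular blob (class 0), bright ring (class 1), speckle field
(class 2) — with diameter 14–30% of the image side, random contrast
(motifs blend at strength 0.6–1.0, so faint presentations exist), Gaussian
pixel noise (σ = 8), and a 30% chance the lesion touches an image border
(the situation that defeats random cropping and motivates saliency-aware
patches). Class counts follow the imbalance ratio with largest-remainder
rounding; default ratio 372 : 141 : 1297, default size 96 px.

What passing tests show: the pipeline is mechanically correct, the mosaic
labels are exact, and on lesion-like imbalanced data the curriculum
recovers minority-class performance that plain weight balancing misses.
What they do not show: performance on real photographs — the motifs are far
simpler than clinical appearance variation, there is exactly one lesion per
image, and the class-conditional backgrounds are identical by construction.

## Scaled-down experiment sizes

The end-to-end comparison runs at 500 images (372:141:1297 ratio → class
counts 103/39/358), 32-px images, the default tiny CNN, 240 mosaics
(1,200 scaled by the train-split size), dominant quadrant allocated by
inverse class frequency, five seeds in the test suite and three replicates
in the acceptance script. At this scale one replicate takes about a minute
on one CPU. The minority class holds only ~3 test images per replicate, so
its F1 is strongly quantized; the acceptance property is therefore the
ordinal one — mosaic-curriculum minority F1 ≥ weight-balancing minority F1
in a majority of seeds — rather than a numeric target.

## Numerical conventions

- Soft-label rows must sum to 1 within 10⁻⁹; predicted probabilities are
  clamped at 10⁻¹² inside the loss (with a warning) so zero predictions
  stay finite.
- Zero-denominator precision/recall/F1 report 0 with a warning, never NaN,
  so degenerate small test sets still produce complete reports.
- Metrics are kept at full precision internally; display rounds scores to
  4 decimals and rates to 1, matching the reference tables.
- Weighted averages default to evaluation-set class counts; the weighting
  population is a documented parameter (`weight_counts`) because whole-
  dataset and test-set proportions agree at print precision in the
  reference grid.
- Patch and CAM rescaling is bilinear; augmentation fill is nearest-pixel.
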