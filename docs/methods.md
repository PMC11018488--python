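# Methods

## Problem and approach

Litchi trees flower in panicles — branched clusters bearing hundreds of
small male flowers, each a radial burst of 7–9 slender filaments.
Counting flowers per panicle from photographs supports flowering-rate
estimation and phenotyping, but individual flowers are far too small
and dense for detection-style counting.  This package implements a
density-map regression pipeline for the single-panicle setting:

1. each annotated flower centre (the convergence point of the
   filaments) is blurred into a Gaussian bump, producing a density map
   whose spatial integral equals the flower count;
2. a convolutional network (FlowerNet) regresses that density map from
   the RGB image while a second output branch classifies each cell as
   flower foreground or background (multitask learning);
3. at prediction time the binarised foreground mask gates the density
   map elementwise, suppressing spurious density in background regions,
   and the gated map's sum is the count;
4. a univariate linear calibration y = a·x + b maps the image-derived
   count to the true (manually counted) per-panicle count, since a
   single view never shows every flower.

Upstream panicle isolation (instance segmentation) is out of scope: an
externally produced binary panicle mask can be supplied and is applied
by zeroing the background and cropping to the padded bounding box.

## Label generation

Density maps use a fixed isotropic Gaussian, σ = 4 px by default.  Each
bump is truncated at radius 4σ and renormalised to unit mass within the
in-image support, so the map's sum equals the point count exactly
(to ~1e-12 in float64) even for flowers at the border.  Truncation is
also what makes the foreground mask meaningful: the mask is defined as
the set of strictly positive density pixels, which for a truncated bump
is a disc of radius 4σ rather than the whole image.  The mask is then
grown by binary morphological dilation with a square structuring
element (3×3 by default; 1×1 disables growth, 5×5 is the coarser
alternative) because a fixed-σ Gaussian support underestimates the
spatial extent of a real flower.  Outside-image pixels count as
background during dilation.

For training at output stride s, the density map is block-summed over
s×s cells (count-preserving) and the mask is block-maxed; bottom/right
zero padding makes the label grid ⌈H/s⌉×⌈W/s⌉, matching the network's
ceil-mode downsampling.

## Network

* **Backbone**: the first 13 convolutional layers of VGG16 (3×3 convs,
  ReLU, 2×2 max pooling), tapped before each downsampling step at C2
  (128 ch, stride 2), C3 (256, 4), C4 (512, 8), C5 (512, 16).  Inputs
  are RGB normalised to [0, 1]; the minimum input side is 32 px so C5
  is non-empty.
* **Fusion**: each tap passes a 1×1 convolution to `fusion_channels`
  (256 by default, 128 as the ablation alternative); level C*k* is
  brought to C2's resolution by k−2 repetitions of (3×3 conv → ReLU →
  nearest-neighbour ×2 upsample); the aligned maps are summed, then
  refined by a 3×3 and a 1×1 convolution.  Odd spatial sizes are
  handled by cropping the upsampled map to the target shape.
* **Head (DMN)**: two branches share the fused stride-2 map and
  downsample to `output_stride` (8 by default, i.e. two stages).  A
  conv-pool stage is 3×3 conv → ReLU → 2×2 max pool; an MP stage is an
  MP module followed by 3×3 conv → ReLU.  The MP module downsamples via
  two parallel paths — (2×2 max pool → 1×1 conv to C/2) and (1×1 conv
  to C/2 → stride-2 3×3 conv) — concatenated back to C channels.  The
  mask branch (conv-pool flavour by default) ends in a 1×1 conv and a
  sigmoid; the density branch (MP flavour by default) ends in a 1×1
  conv and a ReLU, which enforces non-negativity.  Branch widths are
  128 then 64 (then 32 for deeper strides); the exact interior widths
  are a design choice of this package.
* **Gating**: the mask probability is binarised at 0.5 and multiplied
  elementwise into the density map; masked-out cells are exactly zero.

Ablation switches expose the four fusion/mask-branch variants and the
four head-downsampling variants as runnable configurations.

The network runs on a small numpy layer engine written for this
package (im2col convolution over BLAS matmul, ceil-mode 2×2 max
pooling, nearest upsampling, explicit cached backward passes, Adam).
Max-pool ties propagate the gradient to every tied input — a
deterministic, symmetric subgradient choice.  All tensors are float32;
losses and density integrals are accumulated in float64.

## Objective

Per image, the mask loss sums binary cross-entropy over pixels
(probabilities clamped to [1e-7, 1−1e-7]); the regression loss is the
squared Euclidean distance between predicted and target density maps.
Both are averaged over the batch and combined as L = L_mask +
α·L_regression with α = 8.  A "literal" linear mask-loss variant
−Σ[gt·p + (1−gt)(1−p)] is kept selectable because the original printed
formulation omits logarithms while calling the term a cross-entropy;
the log form is the default, and which form the original authors
actually trained with cannot be determined from the text.  Pixel sums
are not normalised by pixel count, matching the printed reductions.

## Training and evaluation

Training divides each sample into a 3×3 grid of blocks (column widths
floor(W/3) with the remainder on the last column, and likewise rows;
points on a boundary belong to the half-open lower-index block).
Weights start i.i.d. uniform on [−0.05, 0.05] with zero biases, and
Adam (lr 1e-4, batch 4, seeded shuffling) descends the combined loss.
Evaluation feeds complete images through mask-gated prediction and
reports MAE and RMSE over per-image (labeled, predicted) counts.
Fixed seeds make init, shuffling, synthesis and hence whole runs
bit-reproducible on one device.

## Synthetic scenes

The generator emulates the features the pipeline depends on: a
textured background (base hue + smoothed low-frequency blotches + fine
grain), an elliptical panicle region that doubles as the instance
mask, and flowers rendered as 7–9 radiating filament strokes with
brighter anther dots, centres rejection-sampled inside the panicle
under a minimum pairwise spacing (default 6 px at 256×256).  Default
per-scene counts are drawn from [40, 200].  It does not emulate
occlusion by leaves, perspective, specular lighting, bud/bloom stage
mixtures, or multiple panicles per image — so passing tests demonstrate
the pipeline's mechanics and optimisation behaviour, not field
accuracy on real orchard imagery.

## Desk-scale study conditions

The training-behaviour checks run entirely on one CPU, which sets the
problem sizes: 8 synthetic scenes at 96×96 (the smallest size whose
3×3 blocks meet the backbone's 32-px minimum), per-scene counts in
[10, 25] with 5-px spacing (the 256×256 flower density scaled by
area), 60 epochs, batch 4, lr 1e-4, fixed seeds.  Under these
conditions the combined loss falls by well over 90%, and the mean
relative count error on the training scenes drops below 15% when
counts are measured with the same 9-block protocol the network is
trained on (tile, predict per block, sum) — an overfit-recovery check
that validates gradients, labels and gating end-to-end.

Whole-image inference behaves differently at this miniature scale, and
deliberately so: the backbone's receptive field (~200 px for the
13-layer VGG stack) far exceeds a 32×32 training block, so block
training teaches features that partly depend on the zero padding
surrounding each block, and whole 96×96 images — whose interiors
replace that padding with real context — yield systematically inflated
densities.  The acceptance script reports both numbers
(`overfit_mean_rel_count_error_pct` for the block protocol,
`overfit_fullimage_rel_count_error_pct` for whole images) so the gap
is visible rather than hidden.  At deployment scale the gap closes on
its own: blocks of a 1024×768 image are ~341×256, padding is a small
fraction of each receptive field, and whole-image testing is the
normal protocol (as `evaluate_model` implements).  These runs say
nothing about generalisation; the published benchmark accuracy
(MAE 47.71 / RMSE 61.78 on 337 orchard images) requires the original
dataset and GPU-scale training and is explicitly not reproduced here.

## Calibration and verification

Calibration is ordinary least squares of manual counts on image-derived
counts.  The package ships the two published lines — y = 51.27003 +
1.50501·x for network-predicted counts (FF, R² = 0.81) and
y = 35.53595 + 1.503735·x for image-annotated counts (FL, R² = 0.88) —
with the FF line as default; refitting on user data overrides them.
Fit quality uses Pearson r (with a two-sided t-test p-value reported
informationally) and R² = 1 − SS_res/SS_tot, which is allowed to go
negative for arbitrary predictions.  The verification report computes,
per sample, the absolute difference and the accuracy rate
P = (1 − |FH − FM|/FH)·100 (cells rounded half-up to 2 dp), plus MAE,
RMSE and the average of per-sample P.  On the shipped 10-panicle
verification pairs this reproduces every printed cell, MAE 49.9, RMSE
59.57 and average accuracy 85.59%.  (The source text elsewhere quotes
MAE 49.4; recomputation from the printed pairs gives 49.9, so the
table value is the consistent one.)  The average accuracy is the mean
of per-sample P — the only reading that reproduces the printed 85.59.

## Numerical choices and edge cases

* Patch tiling is exact (patches reassemble the image bit-for-bit) and
  point-conserving under half-open intervals.
* `split_dataset` draws a seeded permutation; the train size is the
  nearest integer to n·fraction (337 at 268/337 → 268/69).
* Zero-variance inputs to Pearson/R², constant-x fits, all-zero
  panicle masks, empty training or test sets, even-sized structuring
  elements, and sub-32-px network inputs all raise ValueError rather
  than returning degenerate values.
* The mask binarisation threshold (0.5) is a free parameter of
  prediction, not of training.
* Checkpoints are single `.npz` files holding every weight plus the
  embedded JSON config; save→load round-trips to bitwise-identical
  outputs.

## Known limitations

* Pure-numpy training is practical only at desk scale (tens of small
  images); there is no GPU path.
* The synthetic scenes are deliberately simple (see above); no
  occlusion, no multi-panicle layouts by default.
* Uniform init with fixed scale 0.05 follows the stated initialisation
  scheme but is not variance-preserving across the 13-layer backbone;
  Adam's per-parameter scaling compensates at desk scale.
* The literal (log-free) mask loss is linear in p and therefore has a
  constant subgradient; it is provided for fidelity, not recommended
  for training.
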