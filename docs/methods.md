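# Methods

This note documents the models, defaults and numerical choices behind
`orchardfusion`, and what the synthetic experiments do and do not show.

## Segmentation network

**Architecture.** DeepLabv3+ encoder–decoder. The backbone is a small
residual encoder (stem stride 2 plus three residual stages, total output
stride 16; widths `w, 2w, 4w, 4w` with `w` set by the `backbone` identifier,
default `tiny16`, i.e. `w = 16`). The stride-4 output of the first residual
stage is the low-level skip path. ASPP applies a 1×1 branch, dilated 3×3
branches at rates (6, 12, 18) and global image pooling, concatenated and
projected. The decoder projects the low-level path with a 1×1 conv,
upsamples the ASPP output ×4 bilinearly, concatenates, refines with two 3×3
convs (as in the original decoder) and classifies per pixel; logits are
upsampled ×4 to input resolution. The published figure does not pin down
whether the backbone-end attention sits before or after ASPP; the default is
backbone → CBAM → ASPP, switchable via `cbam_position`.

**Attention blocks.** CBAM gates channels with
`σ(MLP(avgpool) + MLP(maxpool))` (shared two-layer bias-free MLP, reduction
16) and then positions with `σ(conv7×7([mean_c; max_c]))`. ECA gates
channels with a bias-free 1-D convolution over the global-average channel
descriptor; kernel size `k = |log₂C/γ + b/γ|` rounded up to odd (γ = 2,
b = 1). Two deliberate points:

* The ECA channel convolution uses **edge-replicate padding** rather than
  zero padding. With zero padding the two edge channels see artificial
  zeros, so even a channel-constant descriptor would receive unequal gains;
  replicate padding preserves the channel symmetry the gate is meant to
  have and changes nothing else material.
* The CBAM channel gate is *not* channel-symmetric: the shared MLP mixes
  channels through arbitrary learned weights, so a channel-constant input
  does not in general produce uniform channel gains. What symmetry does
  force — and what the tests assert — is that with a constant input plane
  the average- and max-pooled descriptors coincide (gain
  `= σ(2·MLP(c·1))`), and the spatial gate is uniform away from its
  convolution border.

**Training.** Pixel-wise cross-entropy with uniform class weights (the
source protocol names no loss; this is the standard choice for the
architecture family). Optimisers: SGD with momentum 0.9 at the published
learning rate 0.01 is the default; Adam is available and is what the
desk-scale overfit runs use (Adam at lr 0.01, batch 4, ≤200 steps), since
the capability being checked there is that the training loop can drive the
full dual-attention model to mIoU ≥ 0.9 on eight 128×128 scenes within a
small step budget on a CPU. The reproduction script additionally appends a
100-step fine-tune at lr 0.003: the 200-step result varies with the scene
and initialisation seeds (thin branches converge last), and the short
low-rate phase settles those boundaries for every seed probed. No data augmentation. A `val_fraction` slice
(default 10 %) of the training scenes supplies the validation loss curve;
the tiny-overfit runs set it to 0. All shuffling and initialisation is
seeded; runs are deterministic up to floating-point reduction order.

**Metrics.** PA, mean per-class recall (AccClass), per-class IoU and mIoU
all derive from one confusion matrix. AccClass is interpreted as mean
per-class *recall* (the usual reading); classes absent from both truth and
prediction are excluded from the mIoU mean to avoid 0/0. Prediction is the
per-pixel argmax with ties broken toward the lowest label id.

**Engine.** The network runs on a small reverse-mode autodiff engine
(`orchardfusion.nn`) written on numpy: broadcast arithmetic, im2col
convolution with stride/dilation, batch norm, bilinear resampling, axis
reductions and softmax cross-entropy, each with a hand-derived backward
pass verified against central finite differences at 1e-7–1e-8.

## Synthetic orchard

The generator stands in for field data that was never deposited. It is a
first-class, tested component, not a fixture.

* **Scenes.** White backdrop (intensity ≈ 250 with mild noise), recursive
  branch skeleton drawn as capsules (distance-to-segment rasterisation),
  elliptical leaf blobs added until a target coverage (default 0.30), and
  disc flowers/fruits (default radius ≈ 9 px at 128², 12 organs).
  Compositing order branch < leaf < flower/fruit; the label histogram is
  taken *after* compositing, so `true_counts` is exact by construction.
  Flowering scenes carry no fruit label and vice versa; a single unified
  5-label space serves both stages, matching a jointly trained model.
* **Reflectance.** Band means are affine in a latent plot vigor
  `v ∈ [0,1]`: B = 0.10 − 0.03 v, G = 0.16 + 0.10 v, R = 0.30 − 0.18 v,
  NIR = 0.35 + 0.45 v (healthy canopies reflect more NIR/green, absorb more
  red). Spatially correlated noise is a Gaussian-filtered white field
  (σ = 3 px) rescaled to a target standard deviation (default 0.02);
  noise 0 reproduces the analytic means exactly. Values are clipped to
  [0, 1], which the noise-free means never touch.
* **Plots.** SPAD values are affine in vigor (s1 = 34 + 12 v, s2 = 32 +
  13 v, ±0.8 noise); structural ratios are logistic in vigor; the four
  screened indices are computed from the band-mean model plus small noise.
  Yield is `intercept + β·x + N(0, noise_sd)` over the ten fused features,
  with default β spreading signal across all three feature groups, chosen
  once to give plot yields of roughly 100–400 kg, and default noise 5 kg.
  The source study reports no field-variable distributions, so these
  defaults are stated here as configuration, not claimed to match any
  orchard. Because all features share one latent driver, the generator
  reproduces the strong positive cross-correlations the screening stage is
  designed to exercise.

What passing tests therefore show: the pipeline's arithmetic is exact, its
stages compose, models recover a known generative law, and the fused
feature set dominates single-source sets *on data faithful to the fusion
hypothesis*. What they cannot show: performance on real orchards —
occlusion, annotation error, illumination variation, sensor calibration and
inter-orchard heterogeneity are all absent from the generator.

## Structure extraction

Tiling pads partial edge tiles (`pad_white` default, reflect and
drop-partial available); padded pixels are labelled background and excluded
from counts via each tile's valid extent. The background filter replaces
the field protocol's manual screening: a tile is dropped when the fraction
of pixels with all channels ≥ 240 is ≥ 99 % (both thresholds configurable).
Counts are pooled over tiles before ratios are formed (proportions are
computed from total pixel counts, not per tile). Zero-numerator ratios
return 0; zero denominators raise. Plot-level aggregation is the mean of
per-tree ratios over the photographed trees (the aggregation rule is not
stated at source; mean-of-ratios is the default).

## Vegetation indices

Visible indices operate on chromatic coordinates computed *first*
(normalisation-first ordering), which buys exact invariance to positive
scaling of the raw digital numbers. GNDVI is implemented with the blue band
exactly as the source table prints it — `(NIR − B)/(NIR + B)` — even though
the literature usually uses green; the green variant sits behind
`green_gndvi=True`. Four further indices that appear only in the screening
table (ExGR, RGBVI, GRVI, RVI) are provided behind `extended=True` with
standard literature definitions and excluded from the default feature sets.
Undefined denominators yield nodata (NaN) for that index only. The zonal
statistic is the mean over valid pixels whose centres fall inside the plot
polygon (pixel count reported alongside); no canopy masking is applied by
default.

## Fusion models

Hyperparameters are not published, so the defaults are: KNN k = 5 (uniform
weights); PLS components selected by 5-fold CV on the training split over
1..min(p, 5) (a fixed component count can be passed instead — the
noise-free coefficient-recovery checks use `n_components = p`, where PLS
coincides with OLS); RF 500 trees; SVM with RBF kernel and C/γ/ε
grid-searched by 5-fold CV on the training split. KNN/PLS/SVM see
z-scored features (scaler fit on the training split only); RF is unscaled.
The 7:3 split shuffles with a seed and rounds the training share half-up
(80 → 56/24); replication across seeds is how uncertainty is assessed.
Pearson screening uses per-group absolute thresholds (SPAD and
multispectral 0.6, structural 0.7, best-1 visible) plus an explicit
exclude list, because a bare threshold does not uniquely yield the
canonical ten-feature fused set: GNDVI clears 0.6 yet belongs to no
published feature set, so it is excluded as a documented override rather
than a guessed rule.

## Shapley attribution

Exact enumeration over all 2^p coalitions (p ≤ 15 enforced; p = 10 here
gives 1024 coalitions). The value function marginalises absent features
over a background set — here the training split — and efficiency, symmetry
and the null-player property hold to ~1e-13, so these values serve as a
gold standard rather than an approximation. The original analysis used a
SHAP library without stating the explainer or background; exact enumeration
with the training background is this package's stated substitute.

## Pipeline

Stages (simulate, segtrain, structure, indices, fuse, explain) read and
write only their declared artifacts in open formats (paired PNGs with an
indexed-palette mask, multiband float TIFF, GeoJSON, CSV, JSON). Child
seeds derive from the run seed through a CRC-based mix, so re-running a
configuration reproduces every artifact byte-for-byte; the run report is
identical across runs except its timing section. The default `run-all`
path substitutes ground-truth masks for network predictions
(`use_true_masks`), which exercises every stage downstream of segmentation
without GPU-scale training; `--with-segtrain` enables the trained-network
route. Desk-scale problem sizes used throughout the examples and scripts —
eight 128² scenes for the overfit demonstration, 80 plots with 192² scenes
and 48×64 rasters for the fused study — were chosen so the whole study runs
in minutes on one CPU.

## Known limitations

* The backbone is deliberately small; published field-scale accuracies
  (mIoU ≈ 0.9 on real imagery after 300 GPU epochs) are out of scope and
  not claimed.
* Branch pixels are the hardest class at desk scale (thin capsules at
  output stride 4 upsampled ×4), mirroring the lowest per-class IoU being
  branches in the field study.
* The synthetic reflectance model has no soil background, shadows or
  atmospheric effects, so index screening behaviour on real orthomosaics
  may differ.
* Exact Shapley cost grows as 2^p; beyond 15 features a sampling
  approximation (not included) is required.
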