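# Methods

This note documents the models, procedures and numerical choices behind
hairbench, in the spirit of a methods appendix: what is computed, under
which assumptions, with which defaults, and what the synthetic experiments
do and do not demonstrate.

## Hair-mask generation

A strand is a cubic Bézier curve with four control points drawn uniformly
on a margin-extended canvas (margin 15% per side, so hairs may enter or
leave the field of view). The curve is sampled at 100 parameter values and
treated as a polyline.

**Arc-length law.** Hair "length" is interpreted as polyline arc length
(end-to-end extent would be systematically shorter for curved strands; the
choice is configurable in spirit by resampling). Rather than rejection
sampling, the control polygon is rescaled about its centroid to a target
length drawn uniformly from [100, 900] px. Uniform scaling of control
points scales the whole curve, so the target is met exactly, termination is
guaranteed and the length marginal is exactly uniform.

**Rasterization.** The stroke value at a pixel is
clip(thickness/2 + 1/2 − d, 0, 1), where d is the distance from the pixel
center to the polyline — a signed-distance anti-aliasing with a 1 px
falloff. For an axis-aligned edge this equals the exact fractional pixel
coverage (the test suite checks this against supersampling); for oblique
edges it is the usual resolution-independent approximation. Strands merge
into the canvas by pointwise maximum, so overlaps saturate at 1 instead of
adding; a strand crossing itself does not brighten. Coordinates are
(row, col), 0-based, pixel centers at integers.

**Blur and resolution.** Strand geometry lives on a 1024×1024 working
canvas so the 100–900 px length range stays meaningful (900 px exceeds the
256 px output diagonal), and the thickness range 1–4 px refers to working
pixels. Each strand is blurred with a Gaussian (σ = 0.8 px, zero padding —
hair ends at the field edge) and block-averaged down to the 256×256 output;
for non-integer scale factors bilinear resampling is used instead. σ = 0.8
keeps the thinnest (1 px) hairs above the binarization threshold after
downscaling: their peak mask value lands around 0.25–0.4, hence the low
default binarization threshold of 0.1 for defining the hair-pixel set. The
combined mask is the pointwise maximum over the per-strand blurred layers,
which makes the layer decomposition exact: a strand layer is zero wherever
the combined mask is zero.

`MaskGenConfig.scaled_to(canvas)` rescales this geometry to other output
sizes, keeping the 4× supersampling factor and scaling the length range by
canvas/256, so scaled-down experiments keep the same apparent hair width
and relative length.

## Hair appearance and compositing

The photorealistic texture stage is deliberately procedural (no learned
texture model): the package's contract is the geometry, color and contrast
of the occluder, not cuticle-level realism. The hair color is the mean RGB
of base-image pixels at or below the 10th luminance percentile (hair tends
to be among the darkest structures); if that color sits closer than
`min_contrast` (default 0.15, Rec. 601 luminance) to the image's median
luminance it is darkened until the gap holds, guaranteeing hair–skin
contrast even on dark skin tones or uniformly bright images. Each strand
may receive an independent ±0.05 RGB jitter. Blending is plain alpha
compositing with the soft mask as opacity,
hairy = (1 − m)·clean + m·color, evaluated only where the strand layer is
positive — so the clean image is bit-exact outside the mask support.

## Synthetic skin fixture

The built-in clean-image generator renders a skin-tone background (five
presets from light to dark), low-frequency multiplicative shading, and one
elliptical lesion whose radius is modulated by a 5-term random Fourier
series (border irregularity 0.15), filled with darker brown pigment plus
fine and blotchy noise, with a ~1.5 px soft edge. It is intentionally
minimal: it provides lesions that are darker, textured and irregular —
enough to make inpainting non-trivial and contrast enforcement meaningful —
but it does not emulate dermoscopic optics, pigment networks, or hair
already present in real photographs. Passing tests on these fixtures
demonstrates the pipeline's mechanics and the learning dynamics, not
clinical-grade removal quality on real dermoscopy.

## Dataset assembly

One mask per clean image; density classes low/medium/high at 1–5 / 6–20 /
21–40 hairs; under the uniform 1–40 count these bins carry 12.5 / 37.5 /
50% of samples. The train/test split takes ceil(0.8·N) samples for
training — 1064 → 852/212, which is the only rounding consistent with a
training set of 852 — by seeded shuffle over *clean-image* ids, so several
variants of the same clean image can never straddle the split. Everything
is serialized as 8-bit PNG plus a CSV manifest; 8-bit quantization means
on-disk pairs can differ by one gray level where the soft mask was below
half a level.

## Inpainting network

U-Net-like encoder–decoder, depth 4 and 16 base channels by default
(doubling per level), 3×3 convolutions with ReLU, 2×2 max pooling, 2×2
stride-2 transposed convolutions, skip connections by channel
concatenation, final 1×1 convolution with sigmoid so outputs live in
[0, 1]. The model predicts the full image rather than a residual or mask.
He-initialized from a seed; everything is float64 numpy. The network,
losses and Adam run on a small reverse-mode autodiff engine written for
this package (tape-based, with dense/transposed convolution, pooling,
concatenation and fixed-kernel depthwise convolution); its backward passes
are verified against central finite differences at relative tolerance 1e-3,
including end-to-end through the full composite loss.

## Composite loss

* L_hair: mean squared error over hair pixels (all channels); defined as 0
  for an empty hair set.
* L_non-hair: MSE over the complement; 0 for an empty complement.
* L_normalized: the hair-region squared-error *sum* divided by the total
  pixel count, i.e. L_hair scaled by |hair|/|all| — the simplest reading of
  "hair error relative to the entire image" that is distinct from L_hair;
  with its small default weight (0.3) it acts as a mild global
  regularizer. This formalization is a design choice, not a quoted
  formula.
* L_SSIM = 1 − SSIM, computed with the same differentiable SSIM used for
  evaluation (11×11 Gaussian window, σ = 1.5, K₁ = 0.01, K₂ = 0.03,
  dynamic range 1, channel mean).
* L_TV: anisotropic total variation, the mean |difference| over all
  horizontally and vertically adjacent pixel pairs, averaged over channels
  — absolute rather than squared differences to respect edges.

Hair/non-hair partitions use the soft mask binarized at 0.1. Weight
presets: uniform (1,1,1,1,1), initial (0.5,0.5,0.2,0.2,0.2), tuned
(2.5,3.5,0.3,1,0.5).

## Training loop

One iteration = one Adam step (β₁ = 0.9, β₂ = 0.999, ε = 1e-8, lr 1e-4) on
one mini-batch (default 4) drawn from a seeded shuffle of the training
split only. "Iterations" therefore count optimizer steps, not epochs. No
learning-rate schedule and no early stopping. lr = 0 is accepted as a
degenerate diagnostic mode (components reported, parameters untouched).
The run aborts with a diagnostic on a non-finite loss. The per-iteration
component record is the loss history; its totals are recomputed as the
weighted sum on serialization, so the history is consistent by
construction.

## Metrics

SSIM uses Gaussian-weighted local moments computed in valid mode (the
border where the 11×11 window does not fit is cropped before averaging) —
numerically identical to the gaussian-weighted, population-covariance
variant of the scikit-image reference. MS-SSIM follows the standard
construction: contrast-structure means on a dyadic pyramid (2×2 mean
pooling, odd trailing row/column dropped), the full SSIM at the coarsest
scale, exponents from the conventional 5-scale weight vector
(0.0448, 0.2856, 0.3001, 0.2363, 0.1333) truncated to the feasible number
of scales and renormalized to sum to 1; one scale reduces exactly to SSIM.
Negative means are clamped at 1e-8 before exponentiation (fractional
powers of negative values are undefined; on [0,1] imagery the clamp is
essentially never active).

Near-mask precision/recall: a pixel is "predicted hair" if the removal
changed it by at least 0.02 in any channel; precision is the fraction of
predicted pixels within the true mask dilated by a disc of radius 5 px (so
predictions *near* the mask count as correct, and precision is
non-decreasing in the radius), recall the fraction of undilated true hair
pixels predicted; F1 is the harmonic mean, 0 when both are 0, with
explicit flags for empty truth or no predictions. Radius and threshold are
config-surfaced and reported.

## Dullrazor baseline

Per channel, grayscale closing with 9 px line structuring elements at
0°/45°/90°/135° (scikit-image grey morphology, reflect boundary); the
detection response is the maximum of (closed − original) over orientations
and channels, thresholded at 0.1; components under 10 px are discarded.
Each hair pixel is replaced by distance-weighted linear interpolation
between the two nearest non-hair pixels along the normal of its locally
dominant orientation (the orientation whose closing responded most),
falling back to the nearest non-hair pixel, then a 5×5 median filter
smooths the replaced pixels only. All parameters are configurable; they
follow the original description where stated and common reimplementation
practice elsewhere.

## Scaled experiment sizes

The desk-scale experiments used by the test suite and the acceptance
script run at 64×64 with `scaled_to` mask geometry: training uses 16
synthetic pairs, a depth-3/16-channel model, 200 tuned-weight Adam steps
(batch 4, lr 1e-4); removal improvement is measured on 8 held-out pairs;
the hair-count sweep uses k = 1..20 with 2 images per seed over 5 seeds;
the Dullrazor comparison uses 4 clean images × 2 variants with ≥ 10 hairs.
These sizes were chosen so the whole suite runs in minutes on one CPU
while still exhibiting the qualitative phenomena of interest (loss decay,
SSIM recovery, coverage monotonicity).

## Known limitations

* MSE/MAE are reported raw (ideal value 0). One published summary table
  lists MSE/MAE with "ideal value 1.0", implying an unexplained
  similarity-style rescaling; no guess at that transformation is made
  here.
* The procedural compositor does not reproduce learned hair texture
  (shine, depth-of-field, crossing-order occlusion); conclusions about
  removal quality transfer to real dermoscopy only qualitatively.
* The synthetic-skin fixture is not a lesion simulator; Fitzpatrick-type
  statistics of curated clinical datasets are properties of those datasets
  and are not modeled.
* Full determinism holds per platform (BLAS reduction order can differ
  across builds); all randomness flows from explicit seeds.
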