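# Methods

This note documents the models, defaults and numerical choices behind
`meiboseg`, and what the synthetic-phantom experiments do and do not
demonstrate about real infrared meibography.

## Segmentation model

The segmenter is a plain U-Net: `depth` encoder levels of two 3×3
convolutions + ReLU followed by 2×2 max pooling, a bottleneck block,
and a mirrored decoder using nearest-neighbour upsampling with skip
concatenation, ending in a 1×1 convolution producing a single logit
map; gland probability is its sigmoid. Channel width doubles per
level from `base_channels`. The network, its backpropagation and the
Adam optimizer are implemented directly in NumPy, which keeps training
of small models practical on one CPU and makes every arithmetic step
inspectable; gradients are verified against directional finite
differences in the test suite.

The objective is the sum of two terms with complementary behaviour:

- pixel-averaged weighted binary cross-entropy
  `CE = −(1/|Ω|) Σ w(x)[g log p + (1−g) log(1−p)]`, the standard
  negative log-likelihood (per-pixel weights default to 1; predictions
  are clipped to [1e−7, 1−1e−7]);
- soft Dice loss with squared denominator,
  `Dice = 1 − (2Σpg + s)/(Σg² + Σp² + s)` with smoothing `s = 1`,
  which directly targets overlap and is insensitive to the
  foreground/background imbalance typical of gland masks. The
  smoothing constant defines the empty-vs-empty case as a perfect
  score (loss 0) and keeps the gradient finite on empty masks.

Both terms are averaged (CE over pixels, Dice over the batch
globally) so magnitudes are resolution-independent; averaging is a
monotone rescale of the summed forms and does not move the optima.
Total loss is their unweighted sum.

Choices worth making explicit:

- **Single sigmoid output head** rather than a two-channel softmax:
  the task is binary and the loss formulas operate on one `g`/`p`
  field per pixel.
- **Binarization threshold 0.5** by default, exposed as
  `binarize_threshold`; thresholding is monotone, so sweeping it only
  shrinks or grows the foreground.
- **Resizing**: images are resized bilinearly to `input_size` for the
  forward pass and probability maps are resized back to the native
  resolution, so morphometry always runs at the input image's own
  scale; masks use nearest-neighbour to stay binary.
- **Determinism**: a single `random_state` seeds weight initialization
  (He normal) and epoch shuffling; inference has no stochastic
  component at all, so re-running a trained model is bitwise
  reproducible — the package's repeatability statistics (DSC, kappa,
  ICC all exactly 1.0 between two runs) are a property of the design,
  not an empirical accident.
- **Transfer hooks**: `fit(..., pretrain_data=...)` first trains
  `pretrain_epochs` on an auxiliary image/mask set, then continues on
  the target set (history records both stages). Naming a pretrained
  `encoder` without locally supplied weights raises immediately;
  nothing is ever downloaded.
- **k-fold protocol**: `kfold_split` shuffles ids with a seed and
  partitions them into k validation folds whose sizes differ by at
  most one (628 ids, k = 5 → validation folds 126/126/126/125/125 and
  502 training ids opposite each 126-fold).

Default training schedule: Adam at learning rate 1e−3, batch size 5.
The studies in `scripts/acceptance.py` and the tests train a depth-2,
8-channel network at 64×64 input on 30 phantom pairs for 15 epochs —
sizes chosen so a full study runs in well under a minute on one CPU
while still leaving a wide margin over the held-out Dice ≥ 0.8 bar
(typically ≈ 0.89 at native 256×256 resolution).

## Morphometry

A binary mask is decomposed into glands as its 8-connected foreground
components (diagonal contact does not split a gland); components under
`min_area` = 10 px are discarded as speckle. Glands are numbered left
to right by centroid column.

- **Width**: at each row the inclusive span `X₁ − X₀ + 1` between the
  leftmost and rightmost gland pixel, averaged over the gland's rows.
  The inclusive convention makes a one-pixel-wide gland have width 1
  rather than 0. Rows with interior gaps still use the extremal
  columns.
- **Centerline**: Lee thinning (`skimage.morphology.skeletonize`,
  `method="lee"`), which on straight bars yields an exactly straight
  one-pixel line (Zhang thinning leaves diagonal spurs at bar tips
  that would break exact straightness). If the skeleton branches, the
  gland axis is the longest weighted geodesic between two skeleton
  endpoints (Dijkstra on the pixel graph, axial steps 1 and diagonal
  steps √2), ordered top to bottom.
- **End correction**: thinning erodes roughly half a gland-width from
  each extremity. The axis is therefore prolonged from both ends
  along the local tangent (estimated from the last 8 path pixels) in
  unit steps until it leaves the gland, so the measured length covers
  the gland's full extent.
- **Arc length**: the raw chain length of a digitized curve (1 per
  axial, √2 per diagonal step) systematically overestimates the true
  arc length — up to ~6–8% for lines at intermediate slopes — which
  alone would exceed the package's 5% recovery tolerance for length
  and tortuosity. Measured length therefore uses the polyline through
  every 5th path pixel (`resample_step = 5`, endpoints always kept).
  Sub-sampling cancels the staircase inflation while the residual
  corner-cutting error stays below ~0.5% at the curvatures glands
  exhibit; for perfectly straight or diagonal paths it is exact, and
  the resampled polyline is never shorter than its chord, preserving
  τ ≥ 1. Setting `resample_step = 1` restores the raw chain length.
- **Tortuosity**: τ = arc length / chord (distance between the axis
  endpoints), guarded to 1.0 when the chord is under one pixel.
- **Length**: the axis arc length by default; `length_mode="extent"`
  instead reports the vertical extent `Y_max − Y_min`, the other
  common clinical reading.

All coordinates are 0-based (row, col) with rows increasing downward;
every measurement is in pixels at the processed resolution — no
physical calibration (mm per pixel) is attempted.

## Statistics

Gland pixels are the positive class. Precision, recall and F1 follow
the usual confusion-count definitions; ratios with vanishing
denominators are reported as NaN (undefined), never silently as 0,
so they drop out of per-image averages instead of corrupting them.
Metrics are computed per image and averaged by default (pixel-pooled
mode available). The Dice coefficient of two binary masks is
algebraically identical to F1 of the same counts, which the tests
verify to 1e−12. ROC AUC uses the rank (Mann–Whitney) statistic with
midrank ties — exactly the threshold-sweep trapezoid area, but O(n
log n).

Bland–Altman analysis reports the mean and SD (n−1) of paired
differences, limits of agreement at mean ± 1.96 SD, t-based 95%
confidence intervals (se(mean) = SD/√n, se(LoA) = SD·√(3/n)), the
fraction of differences inside the limits, and a two-sided paired
t-test. Under Gaussian differences the limits contain ≈95% of points,
verified by Monte-Carlo simulation in the tests.

Test–retest reliability compares two mask sources image by image:
Dice similarity and Cohen's kappa on pixels (mean ± SD over images)
and the intraclass correlation of per-image gland counts. The ICC is
the two-way random-effects, absolute-agreement, single-measurement
form ICC(2,1) from the two-rater ANOVA decomposition — chosen because
absolute agreement (not mere consistency) is what repeatability
claims require; ICC(3,1) is available as an option. Identical count
series are reported as ICC 1.0 by convention even when their variance
is zero (the ANOVA form is 0/0 there).

## Phantom generator

The generator emulates the geometry and the main artifact catalogue
of infrared meibography: `gland_count` (default 10) vertically
oriented strips with sinusoidal centerlines
`x(y) = anchor + A·sin(2π(y − top)/λ + φ)`, packed left to right with
≥ 2 px horizontal clearance between strip envelopes so glands are
separated objects by construction. Defaults (256×256 canvas):
half-width 3–6 px (strip width 7–13 px), amplitude 0–4 px, wavelength
80–200 px, upper-eyelid length 110–190 px (lower 60–120 px — lower
glands are shorter). These ranges give gently sinuous glands and are
jointly satisfiable: the worst-case packing demand of the defaults
(244 px) always fits the canvas, so generation never fails for any
seed. Strips are rasterized as physical width 2·half_width + 1
centered on the centerline (|x − c| < half_width + 0.5), making every
occupied row exactly 2·half_width + 1 px wide regardless of sub-pixel
centerline position — the analytic width oracle is exact by
construction.

Images render glands bright (intensity 200) on dark background (50),
then apply artifacts in a fixed order: multiplicative linear
illumination gradient (strength 0.25), Gaussian defocus blur
(σ = 1 px), saturated specular discs (2 spots, radius 3–8 px),
additive Gaussian noise (σ = 6 grey levels), clipped to 8 bits.
Every stage draws from a generator seeded by the config seed, so the
same seed reproduces a phantom bitwise.

The expected morphometry is computed from the generative parameters
only — arc length by adaptive quadrature of √(1 + x′(y)²), width
2·half_width + 1, tortuosity arc/chord — never from rendered pixels,
so it is an independent oracle for the mask-based measurements.

What the phantoms do **not** emulate: gland dropout and atrophy,
touching or branching glands, eyelid margin and eyelash structures,
non-rigid curvature of the everted lid, device-specific optics, and
intensity statistics of real infrared sensors. Passing the recovery
and learnability checks therefore demonstrates the correctness of the
measurement chain and the trainability of the model on well-posed
input, not clinical-grade accuracy on patient images, which would
require real annotated data.

## Known limitations

- The NumPy network is practical only at small scales; it exists for
  verifiable correctness and CPU reproducibility, not throughput.
  The architecture hooks accept locally supplied pretrained encoder
  weights but the package intentionally never downloads any.
- Skeleton-based length depends on the end-correction heuristic; on
  blob-like (non-elongated) components the "main axis" is not a
  meaningful concept and tortuosity defaults toward 1.
- Bland–Altman confidence intervals use the standard normal-theory
  formulas; heavy-tailed difference distributions will be
  under-covered.
- All morphometrics are in pixels; comparing against studies that
  report calibrated units requires a mm-per-pixel factor the package
  does not estimate.
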