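# Methods

This note documents the models and procedures implemented in `histonet`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open.

## Tissue classes and rendering

The label schema is fixed: ids 0–7 are TUM, MST, NEC, BLC, VAC, MUS, TAR,
BGR.  The six *main* classes (TUM…MUS) constitute tissue; TAR and BGR are
excluded from all relative measures.  Rendered maps use red TUM, blue MST,
yellow NEC, green BLC, cyan VAC, magenta MUS, black TAR, white BGR.  All
eight display colors are corners of the RGB unit cube, which makes the
variance-mixture arithmetic below exact.

## Stain handling

**Reinhard normalization** operates in the Ruderman ℓαβ space implemented
explicitly (RGB → LMS mixing matrix → log10 → ℓαβ rotation).  LMS values are
floored at 1e-4 before the logarithm so black pixels stay finite; the
round-trip error this introduces is below 1e-3 per channel.  Per channel the
transform is x ↦ (x − μ_src)·(σ_tgt/σ_src) + μ_tgt; channels with
σ_src < 1e-6 are shifted only (scale 1), which keeps near-constant tiles
stable.  Statistics should be computed over foreground pixels
(`inference.foreground_mask`) so slide background does not dominate.
Matching a *representable* target is exact up to clipping; targets outside
the RGB gamut are clipped and then no longer reproduce their statistics —
tests therefore use targets taken from real images.

**Stain augmentation** shifts a whole patch along the principal components
of the RGB scatter of the training data.  The shift per component is drawn
uniform(−m, +m) in units of that component's standard deviation; the uniform
law and the default magnitude m = 0.5 are our choice (no distribution is
canonical here), exposed in `TrainConfig`.

**CD45 two-stain decomposition** converts pixels to optical density
(−log10((255·I + 1)/256)) and extracts the two leading principal components
of the OD second-moment matrix *about zero* — stain concentrations are
non-negative, so zero absorbance is the natural origin, and the leading
component then tracks the dominant stain rather than the noise.  PCA leaves
component identity and sign arbitrary; both are fixed deterministically by
cosine similarity to the classical Ruifrok reference OD vectors for
hematoxylin (0.650, 0.704, 0.286) and DAB (0.268, 0.570, 0.776): each
component is assigned to the reference it matches best and oriented towards
it.  (A rule based on the larger *blue-channel weight* would label the DAB
component as counterstain — in OD space DAB, not hematoxylin, carries the
larger blue weight — so the reference-vector rule is used instead.)  The
returned maps are the non-negative projections; on single-stain patches the
off-stain map is pure noise, small relative to the decomposition's scale.

## The segmentation network

Topology (all configurable via `NetConfig`): `levels` stages of a *reduce*
block — 3×3 convolution with stride 2, Alpha-Dropout, SELU — followed by
`blocks_per_level` residual *bottleneck* blocks (1×1 compress by
`bottleneck_factor`, SELU, 3×3, SELU, 1×1 expand, residual add, SELU).
The semantic head compresses each level to `compression_widths[l]` channels
with a 1×1 convolution, bilinearly upsamples every level to input
resolution, concatenates and applies a 1×1 classifier with per-pixel
softmax.  The distribution head global-average-pools the deepest features
into a single affine layer with softmax — the simplest design consistent
with a head branching off the last encoder level.  There is no
batch normalization anywhere: SELU plus L2 weight decay is relied on to keep
activations bounded.  Weights use LeCun-normal initialization, the
convention for self-normalizing nets, from a seeded generator so identical
configs rebuild identical models.

Defaults are levels = 4, base_width = 32 (doubling per level),
bottleneck_factor = 4, blocks_per_level = 2, compression_widths
(8, 12, 16, 24), dropout 0.1.  The synthetic benchmark uses a deliberately
small instance (levels = 2, base_width = 8, widths (6, 8), dropout 0.05,
~3k parameters) so training stays in the tens of seconds on one CPU core.

**Loss.**  L = L_CCE + L_DDL + L_MSE with unit weights (the sum is written
unweighted).  CCE uses natural log with probabilities clamped to
[1e-7, 1].  The dice-distance loss is 1 − mean over *present* classes of
(2·Σpt + ε)/(Σp + Σt + ε), ε = 1e-6, aggregated over the whole batch;
averaging over classes rather than pixels counters the strong class
imbalance of histology annotations.  The MSE term compares the distribution
head with the normalized class histogram of the annotation.  No
class-reweighting is applied.

**Training.**  Adam (β = 0.9/0.999) with learning rate 5e-4 and *coupled*
L2 weight decay 1e-6 added to the raw gradient.  Per iteration each sample
receives a random 90°-multiple rotation, flips, integer translation
(periodic roll, exact for labels — no interpolation artifacts) and a seeded
stain shift along the principal color components of the training set.
Dropout is active during training.  A non-finite loss aborts with
`TrainingDivergedError`.  The per-epoch history (loss terms and pixelwise
macro F1) is evaluated deterministically on the full training set after
each epoch.

The layer kit (`histonet.layers`) is a purpose-built CPU implementation:
im2col convolutions, interpolation-matrix bilinear resampling (so the
adjoint used in backprop is exact), explicit backward passes per layer.  It
was verified against central finite differences (relative error ~1e-4 at
float32).

## Whole-image inference

Foreground selection is Otsu on luminance (tissue darker than background)
plus removal of connected components under 64 px — an explicit, testable
stand-in for scanner-specific foreground detectors.  Mosaics are tiled on a
grid with 25% overlap: stride = round(patch·(1 − overlap)), starts at
stride multiples, the final box clamped to the image border.  Each tile is
predicted `n_samples = 5` times with dropout active (sample k seeded
seed + k); mean and per-class variance (ddof 0) are kept.  Tiles merge under
separable triangular windows — strictly positive, flattened to their peak on
sides touching the image border, then normalized per pixel so the weights
form an exact partition of unity; merged means therefore stay on the
simplex.  The merged variance is the same convex combination of tile
variances (a blend of within-tile variances; cross-tile disagreement is not
added).

The variance image is rendered as Σ_i color_i · var_i, normalized by the
image-wide maximum channel value.  Variance (not standard deviation) is
rendered, and only channel *ratios* of this image are thresholded
downstream, so the per-image normalization constant cancels.  An equal
variance split between BLC (green) and NEC (yellow) gives pixel color
(0.5, 1, 0): r = Vr/Vg = 0.5, Vb = 0, exactly.

## BLC–NEC correction

Selection rule: Vg > 0 (Vg = 0 pixels are never selected — the ratio is
undefined and "light green" requires green), r = Vr/Vg ∈ (0.35, 0.7),
Vb ≤ 0.1.  "Close to zero" for Vb is qualitative in origin; 0.1 on the
normalized rendering is our quantification.  The boolean selection is
blurred with a Gaussian (σ = 5 px) and thresholded at 0.5, which realizes a
smooth blend on a categorical map: the tissue map itself cannot be
interpolated, so the smoothing must act on the mask.  Selected pixels are
set to NEC; no other transition is ever produced, so the NEC count is
non-decreasing and pixels farther than ~3σ from any selected pixel are
untouched.  The blur-then-threshold step moves the region boundary by at
most a few σ, which is why fixture tests compare up to a 3σ boundary band.

## Meta-features

f_i^abs is a pixel count at processing resolution (no µm² conversion;
2 µm/px can be recorded as metadata).  A sums the six main classes only.
f_i^rel = f_i^abs/A is defined for main classes; TAR/BGR are reported
absolute-only, and A = 0 yields NaN ("undefined") rather than an error.
Δf subtracts the same measure of the model's isotype arm and applies to
absolute and relative features, to A and to the CD45 fraction; an isotype
against itself gives exactly zero.  The CD45-positive fraction counts
positive-stain pixels over counterstain pixels, both via per-channel Otsu
thresholds (overridable) on the two-stain decomposition; counterstain
normalization (rather than total tissue pixels) is the reading adopted.
The decision stage's default feature combination is abs_TUM, rel_TUM,
rel_MST, d_rel_NEC, d_cd45, d_area.

## Decision support

Per cross-validation fold, features are min-max scaled with training-fold
statistics only (constant columns → 0, applied values clipped to [0, 1]).
Folds are stratified (per-fold class proportions within one sample of the
global ones); if the rarest class has fewer members than folds, the fold
count adapts down with a warning.  Rows are canonically sorted before the
seeded fold construction so results are row-order invariant.  Classifier
panel: majority-class "educated guess" (implemented as sklearn's prior
dummy — the definition is otherwise open), Gaussian Naive Bayes, linear and
RBF SVM (C = 1, γ = scale), logistic regression (L2, C = 1), and k-NN
(default 5, Manhattan; k is capped at the training-fold size on very small
cohorts).  AUC-ROC uses continuous scores — posterior for NB/LR, decision
function for SVMs, distance-weighted vote fraction for k-NN — and folds
whose test part holds one class are flagged and excluded from the AUC mean.
Naive-Bayes 2-D posterior surfaces assume Gaussian class likelihoods.

## Texture baseline

Feature vector (26 entries): RGB mean/std/skew; GLCM contrast, correlation,
energy, homogeneity at 32 grey levels, distance 1, angles 0°/90°/45°/135°,
symmetric and normed, averaged over angles; uniform LBP histogram (P = 8,
R = 1, 10 bins); Tamura coarseness (best dyadic window up to 32 px by
horizontal/vertical average differences), contrast (σ/kurtosis^¼) and
directionality (energy of the magnitude-weighted gradient-orientation
histogram, 16 bins).  All operator parameters are our fixed choices — none
are canonical.  The vector is deterministic and invariant under quarter
rotations except Tamura coarseness, whose even averaging windows are not
symmetric about a pixel (near-invariant in practice).  Features are
standardized before the SVM.  Patch ground truth is the class at the patch
center, sampled class-balanced (capped by the rarest class).

## Synthetic data: what it emulates and what it does not

Tissue tiles give each class a distinct base color (pulled toward its
display color) plus a class-specific sinusoidal texture (period 4–14.5 px,
rotating orientation, amplitude 0.08) and i.i.d. Gaussian pixel noise
(σ = 0.05).  This preserves what the pipeline needs — learnable class
signatures, exact labels, boundary-rich geometry from rectangles and discs —
but is *not* histology: no nuclei, no stain co-variation, no scanner
artifacts, no inter-slide stain shift.  Passing tests therefore demonstrate
the correctness and trainability of the machinery, not field performance on
real slides.

CD45 patches are a blue field with brown blobs from a smoothed, thresholded
noise field (exact planted positive count) and a white unstained margin
(15%), so counterstain thresholding has a true background to separate.
Cohort tissue maps plant *exact* per-class pixel counts by rank-partitioning
a smoothed noise field, with background as the outer margin of a noisy
radial field; planted compositions are therefore recovered exactly by the
meta-feature stage, isolating the decision stage from segmentation error.
The planted responder effect (defaults: −0.20 relative tumor, +0.15
relative necrosis, ×(1 − 0.25) tissue area, +0.10 CD45, against mild
opposite drifts for non-responders, per-sample noise σ ≈ 0.03–0.05) encodes
the qualitative responder signature — smaller absolute tumor area, larger
relative necrosis, shrinking overall area — at an effect size chosen to
represent a clearly separable screen; `effect` scales it continuously down
to zero (no signal, chance-level classification).

## Problem sizes and numerical choices

The benchmark trains the small network on 24 mosaics of 96×96 px for 60
epochs (batch 4) and tests on 8 held-out mosaics — about 40 s on one CPU
core — reaching pixelwise macro F1 ≈ 0.95 versus ≈ 0.89 for the texture
baseline evaluated at 12 px patch granularity on the same mosaics.  The
baseline is scored pixelwise after broadcasting each patch label, because
patch-granularity prediction is precisely the structural limitation of
classical patchwise pipelines that per-pixel semantic prediction removes;
the comparison asserts ordering only.  Decision-support checks use 17
models (68 samples, 51 treated rows) with 48×48 tissue maps.  Ties in the
per-pixel argmax resolve to the lowest class id.  All randomness flows
through explicit integer seeds; stochastic inference derives sample k's
dropout mask from seed + k.

## Known limitations

* The NumPy layer kit is single-threaded per op and float32; it is meant
  for small models and mosaics, not gigapixel slides or GPU-scale training.
* Merged variance underestimates total predictive uncertainty at tile seams
  (cross-tile disagreement is blended, not added).
* The CD45 decomposition assumes exactly two stains and breaks down under
  heavy stain co-localization; no per-cell counting is attempted.
* Reported performance numbers are on synthetic data and should not be read
  as estimates for real H&E/CD45 material.
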