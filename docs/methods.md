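# Methods

## Problem and scope

High-grade serous ovarian carcinoma presents on CT chiefly at two sites
with very different morphology: bulky pelvic/ovarian masses (few connected
components) and omental deposits (many small components embedded in the
low-attenuation omental fat).  The package implements the full automated
segmentation pipeline for these two sites — preprocessing, network,
training recipe, sliding-window inference with test-time augmentation,
and the evaluation/statistics battery — plus a synthetic phantom module
that stands in for the (proprietary) clinical cohorts.

## Phantom generator

Each phantom is a 3-D grid (default 24 × 96 × 96 voxels at
5.0 × 0.7 × 0.7 mm — the median slice thickness and a typical in-plane
spacing of abdominal CT) containing:

* **soft-tissue background** at 40 HU,
* a **fat band** (anterior 10–42 % of the y extent) at −100 HU,
* **class-1 lesions**: 1–4 ellipsoids with 9–15 mm semi-axes placed in the
  posterior soft tissue ("pelvic"),
* **class-2 lesions**: 3–10 ellipsoids with 4–8 mm semi-axes centred
  inside the fat band ("omental"),
* lesion intensity 60 HU.

Every tissue carries voxelwise Gaussian heterogeneity (±15 HU soft
tissue/fat, ±10 HU lesion) plus additive acquisition noise (10 HU,
configurable).  The heterogeneity is deliberately voxelwise (spatially
white): with a *correlated* texture field at lesion scale, texture bumps
are indistinguishable from true lesions even in principle, and the ground
truth is unrecoverable from the image — an ill-posed benchmark.  With
white heterogeneity the lesion/soft-tissue contrast (20 HU against ~18 HU
voxel noise) is roughly a d′≈1 voxelwise problem that becomes reliably
separable under the spatial averaging a CNN performs, which mirrors the
clinically described difficulty ordering: trivial fat/lesion contrast,
subtle tissue/lesion contrast.

Ellipsoids are placed by rejection sampling with a separation margin
(sum of max semi-axes + 10 mm) so components cannot merge under
26-connectivity; the per-class component count is re-verified by
connected-component labelling and always lies in the configured range.
Component-count ranges (1–4 and 3–10) bracket the clinical means
(≈2.4 bulky, ≈6.7 omental).  Lesion volumes are an order of magnitude
below clinical bulk (the grid is ~120 × 67 × 67 mm): this is a
deliberate desk-scale reduction, so absolute DSC levels are not
comparable to clinical values, only orderings and pipeline behaviour.

"Post-treatment" scans reuse the patient's pre-treatment label map after
random component deletion (p = 0.35) and one in-plane erosion, so
per-class volume is monotonically non-increasing within a patient —
which exercises the paired pre/post statistics.  Background texture and
noise are re-rendered with fresh randomness, as for a second acquisition.

**What the phantoms do not emulate:** organ anatomy, partial-volume
blur at lesion boundaries (labels and intensities share one rasterised
mask), contrast-agent timing, scanner/protocol heterogeneity, other
disease sites, and inter-rater ambiguity.  Passing the phantom
experiments therefore demonstrates that the pipeline's machinery is
correct and trainable, not that clinical-level accuracy is reached.

## Preprocessing

Volumes are resampled to a target spacing (per-axis cohort median by
default; the tiny preset uses 5.0 × 1.4 × 1.4 mm) with centre-aligned
trilinear interpolation; label maps use nearest-neighbour lookup so no
classes are invented.  Intensities are clipped to the [0.5, 99.5]
percentiles (configurable off) and Z-normalised per volume with an sd
floor of 1e-8 (constant inputs map to zeros).  Predictions are restored
to the native grid by nearest-neighbour lookup for physical volumetry.

## Network

`resnet_unet`: four stages of 1, 2, 6, 3 residual blocks (two 3³
convolutions + instance norm + leaky ReLU 0.01, identity shortcut, 1³
projection when shape changes), 32 base filters doubling per stage
(narrower in the phantom presets).  Downsampling is by stride-2
convolutions in the first block of each stage; an axis is spared while
its voxel spacing exceeds 2.5× the finest axis, so 5 mm slices are not
collapsed prematurely (the cumulative divisor is published by the model
for patch planning).  The decoder mirrors the encoder with
kernel-=-stride transposed convolutions, concatenation skips and one
residual block per level; 1³ heads at every decoder level except the
coarsest provide deep supervision (weights 2⁻ˡ, normalised), on by
default.  `baseline_unet` is the six-stage plain variant (two
conv-IN-LReLU blocks per stage, filter cap 320) under the same code path.

The layer stack (im2col convolutions, instance norm, transposed
convolutions, analytic backward passes, SGD with Nesterov momentum) is
implemented on numpy in `ovaseg._nn`; gradients are verified against
central finite differences in the test suite at 1e-7 absolute tolerance.

## Training

Loss = cross-entropy + soft-Dice over foreground classes.  Dice is
pooled over the batch ("batch Dice") and smoothed with an additive
constant of **1.0**: at small patch sizes a class absent from a batch
with near-zero predicted mass would otherwise receive an O(1/ε)
suppressive gradient that deterministically extinguishes the sparse
omental class (observed, reproducibly, with ε = 1e-5).

Patches are sampled with foreground oversampling p_fg = ⅓: with
probability p_fg an anchor voxel is drawn from a uniformly chosen
*present* foreground class (`class_balanced_sampling`, on by default),
and the patch position is uniform among positions containing that voxel
(jitter).  Both choices are stability measures that were adopted after
targeted experiments: anchoring on foreground voxels uniformly lets the
bulky class dominate ~3:1 and leaves the sparse class's training on a
knife edge (identical conditions produced omental Dice 92 or 0 depending
on schedule length), while pure centring (`jitter=False`) trains the
network on exclusively lesion-centred patch statistics and generalises
poorly to sliding-window content at 16³ patches.

Schedules: `warmup_cosine` (linear 0 → 0.02 over 2 % of steps, then
cosine to exactly 0) and `poly` (0.01·(1−t)^0.9).  The tuned recipe keeps
250 000 steps at batch 4 for full-scale settings; phantom presets use
200–2 000 steps.  Fold assignment for five-fold cross-validation is a
seeded round-robin over shuffled *patients*, so scans of one patient
never span folds; out-of-fold predictions are produced by the fold model
that never saw that patient.  Full-data mode trains m networks from
distinct initialisation seeds and averages their probability grids at
inference.  Fold, sampling and initialisation seeds are separate and
logged (line-delimited JSON: step, lr, loss).

## Augmentation

Spatial: in-plane rotation ±30°, isotropic scaling 0.7–1.4 (one combined
resampling; labels nearest-neighbour), per-axis flips p = 0.5.
Grey-value (image only): Gaussian noise sd 0–0.1, multiplicative
0.7–1.3, contrast 0.65–1.5 about the mean, Gaussian blur sd 0.5–1.5
voxels, gamma 0.7–1.5 after min–max normalisation (a constant patch is
exponentiated directly).  Magnitudes are the common conventions of
self-configuring segmentation frameworks; none are stated by the source
recipe, and all are configurable.

The **tiny preset disables rotation and scaling**: at 1.4 mm in-plane
resolution the omental deposits span only 2–4 voxels, and the boundary
label noise introduced by rotation/scaling resampling is of the same
order as the objects themselves — measured to suppress the class to
DSC 0 even at ±15°/0.9–1.1.  Flips and all grey-value transforms remain
active; full-scale presets keep the complete set.

## Inference

Windows are evenly spaced with a target step of ½ the window per axis,
first window at 0, last flush with the volume end (volumes smaller than
the window are symmetrically padded and unpadded).  Each window is
evaluated under all 8 flip combinations (batched), probabilities are
inverse-flipped, averaged, weighted by a separable Gaussian
(σ = ⅛ window per axis, normalised to max 1, strictly positive) and
accumulated; the accumulator is divided by the accumulated weights
(positive everywhere by coverage — asserted).  Ensemble members are
averaged voxelwise; argmax ties break towards the lower class index
(background first, conservative for disease volume).  Probabilities, not
raw scores, are accumulated, since score scales differ across windows.

## Evaluation and statistics

DSC, sensitivity and precision are reported on the 0–100 scale; a site's
metrics are null on scans whose ground truth lacks the site, and cohort
aggregates (mean ± sd) are restricted to site-present scans.  Volumes
are voxel count × voxel volume on the native grid, in cm³.  Component
counts use 26-connectivity by default (6/18 configurable).  Cross-site
confusion flags, per ordered site pair (a→b), whether any ground-truth
voxel of a received predicted label b.  Bland–Altman agreement uses
differences ground-truth − prediction (positive bias = under-segmentation)
with limits bias ± 1.96·sd (ddof = 1).  The paired Wilcoxon signed-rank
test drops zero differences, uses midranks for ties, and computes the
exact two-sided p (p = 2·min(tails), capped at 1) by a
generating-polynomial enumeration for n ≤ 25 — verified against full 2ⁿ
enumeration — and the tie-corrected normal approximation beyond; the
degenerate all-zero case returns p = 1 with n = 0.  Outlier slices
report the bottom-DSC-quartile's median volume and the
bottom-volume-quartile's mean DSC against the full set.

## Problem sizes and known limitations

The shipped phantom experiments use a 10-patient × 2-scan cohort
(8 training / 2 held-out patients), an 8-filter tuned-variant network,
1 000 training steps at batch 2 and 16³ patches/windows; the overfit
sanity check uses one phantom, 16 base filters, 200 steps at batch 4.
These sizes were chosen so the complete pipeline runs in minutes on a
single CPU core.  At this scale the measured held-out performance is
DSC ≈ 93 (pelvic/ovarian) and ≈ 92 (omental); the 200-step overfit run
reaches foreground DSC ≈ 93, and extending to the 2 000-step preset
ceiling yields ≈ 94.6 — the residual error is concentrated in the
boundary voxels of deposits only 1–3 slices thick under 18 HU voxel
noise, a resolution limit of the phantom geometry rather than an
optimisation failure.  Note that in the phantom the omental site is
*not* harder than the pelvic site (fat provides ~160 HU contrast);
the clinical difficulty ordering stems from factors the phantom does
not model (poor contrast, irregular shape, anatomic confounders).

Numerical notes: the network runs in float32 (float64 available for
gradient checking); end-to-end runs are bit-reproducible for a fixed
seed on one platform; checkpoints embed their network config and are
refused on shape mismatch.
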