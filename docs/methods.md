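# Methods

## Problem and pipeline

Occluding thrombi in acute ischemic stroke are small targets in a large
field of view: on non-contrast CT (NCCT) a red-blood-cell-rich clot shows
as a hyperdense artery sign (HAS), and on CT angiography (CTA) the
occlusion shows as a termination of the contrast-opacified artery.  The
toolkit segments the thrombus from a co-registered NCCT/CTA pair given one
detected occlusion point, in five stages:

1. **Preprocessing** — intensities are clipped to a fixed Hounsfield
   window per modality, (0, 100) HU for NCCT and (0, 250) HU for CTA, and
   the window is mapped linearly onto [0, 1].  The window is per modality,
   not per image, so normalized intensities are comparable across cases.
2. **Initial bounding box** — an axis-aligned box whose faces sit 15
   voxels cranial, 65 voxels caudal, and 24 voxels lateral (both lateral
   axes) of the detection point: 81 x 49 x 49 voxels before clamping at
   the grid boundary.  Axis 0 is longitudinal with increasing index
   cranial; inputs are assumed reoriented to this convention upstream.
3. **Segmentation network** — a 3-D U-Net variant predicts a thrombus
   probability per voxel inside the box; voxels with probability strictly
   above 0.5 are foreground.  Crops are zero-padded (high end of each
   axis) to the nearest multiple of 2^depth, because skip connections
   restrict acceptable input sizes; predictions are un-padded exactly.
4. **Dynamic bounding box** — two refinements run in sequence, each once.
   *Moving*: if the in-box prediction has fewer than 100 voxels, the box
   is translated by floor(2/3 of its extent) along each of the six axis
   directions and the candidate (original included) with the largest
   predicted volume wins; ties break towards the earliest candidate in a
   fixed order, making results deterministic.  *Flexible*: while any
   predicted voxel lies closer than 5 voxel steps to a box face, every
   such face grows outward by 10 voxels and the network re-runs, at most
   5 times per case (a global cap, not per face).  Moving runs first
   because it repairs a box that misses the thrombus entirely; flexible
   then repairs partial truncation.  Boxes are cropped (not shifted) at
   grid boundaries; input padding compensates.
5. **Post-processing** — morphological closing with a 3x3x3 box element
   (out-of-grid voxels treated as background) reattaches satellite
   fragments, then connected components smaller than 10 voxels are
   removed.  Components are labelled with 26-connectivity by default (a
   config switch allows 6); the size filter counts voxels on the closed
   mask.

## Network variants and fusion

All variants share a fully convolutional encoder-decoder: 3x3x3
convolutions with padding 1 and ReLU (two per block), 2x2x2 max pooling,
trilinear up-sampling with aligned corners, channel widths doubling per
level from a configurable base, and a single-logit 1x1x1 output head.
The single-logit head pairs naturally with the weighted cross-entropy
loss; binarization uses a strict `> 0.5` so an untrained all-zero head
predicts background.

* `unet2ch` — NCCT and CTA enter one encoder as two channels.
* `concat` / `add` / `weighted_sum` — one encoder per modality; encoder
  features are fused at the bottleneck and at every skip level, and the
  fused grid enters the decoder (concatenated with the up-sampled decoder
  features, as in a standard U-Net skip).  Weighted-sum fusion learns a
  scalar pair (k1, k2) per channel per site, F_i = k1 A_i + k2 B_i — a
  1x1x1 convolution across the modality pair; its pairs initialize to
  (1, 1), so at initialization it is exactly add fusion.
* `unet_ncct_only` — single-modality baseline.

Trainable-parameter counts order as
ncct-only < 2-channel < add ~ weighted-sum < concatenate for any base
width: the two-encoder variants duplicate the encoder, weighted-sum adds
exactly two scalars per fused channel over add, and concatenation doubles
the skip/bottleneck widths the decoder must consume.  Absolute counts
scale with the base width, which is deliberately small by default
(desk scale); only the ordering is meaningful.

## Numerical engine

No GPU framework is used: the networks run on a small reverse-mode
autodiff engine written on numpy.  Convolutions are lowered to matrix
multiplies via im2col; the input gradient scatters a GEMM result back
through the 27 kernel offsets; up-sampling is three 1-D aligned-corner
interpolation matrices contracted by einsum, and its backward pass is the
transpose contraction.  Every backward formula is checked against central
finite differences in the test suite.  Model parameters are float32 for
BLAS throughput; standalone loss/fusion evaluations on float64 inputs stay
float64, which is what the 1e-9 oracle comparisons in the tests rely on.
Execution is single-threaded deterministic: fixed seeds give bit-identical
histories.

## Training

Batch size 1 (one crop at a time), Adam at a fixed learning rate, and a
weighted binary cross-entropy: mean over voxels of
−[w·t·log σ(z) + (1−t)·log(1−σ(z))], where the positive-class weight `w`
counters the thrombus/background imbalance.  Mean (not sum) reduction
keeps the loss comparable across crop sizes.  Training boxes are sampled
five per case: starting from the tight box around the ground truth, each
of the six sides gets an independent uniform offset from
(−0.1 x tight extent, n x reference-box extent) with
n in {0.2, 0.3, 0.5, 0.7, 0.9}, teaching invariance to box size and
thrombus position.  Hyperparameters (lr, w) come from seeded random
search — lr log-uniform over (1e-4, 0.1) because the interval spans three
decades, w uniform over (10, 50) — scored by mean validation Dice.  The
per-epoch validation Dice decides which parameter state is kept.

## Synthetic phantoms

Clinical stroke CT cannot be redistributed, so every experiment runs on
generated dual-modality phantoms that carry exactly the image structure
the method exploits:

* a tubular vessel (radius 1.6 mm, optional low-amplitude sinusoidal
  curvature) along the longitudinal axis;
* an occluded segment with length sampled uniformly from 10-40 mm; with
  the default radius this yields cohort means near 20-35 mm length and
  150-250 mm^3 volume, the range of anterior-circulation thrombi;
* NCCT: brain background 30 +/- 3 HU, patent vessel 35 HU, thrombus
  50 +/- 8 HU (the HAS; the generator rejects configurations without a
  positive thrombus-vessel contrast, mirroring the exclusion of cases
  with no visible HAS);
* CTA: patent lumen 170 HU, the occluded segment keeps its thrombus
  attenuation — a filling defect identical voxel-for-voxel to the ground
  truth;
* distractors: blobs hyperdense on NCCT *and* bright on CTA (calcified
  patent-vessel mimics), placed off-vessel; only a dual-modality model
  can reject them, which is what makes the NCCT-only ablation meaningful;
* additive Gaussian noise per modality (2 HU NCCT, 5 HU CTA);
* a detection point at the thrombus centre displaced by a configurable
  jitter (2 mm default; tens of mm to exercise the moving-box method).

Tube cross-sections are rasterized area-matched (the N highest-coverage
voxels, N = round(pi r^2 / voxel area)); centre-inclusion rasterization
would bias realized volumes by 25-30% at millimetre radii.

What the phantoms do **not** model: anatomy (no brain, skull, or vessel
tree), partial-volume and beam-hardening physics, HAS-negative thrombi,
anisotropic spacing in the defaults, and CTA over-estimation from poor
collateral filling.  Passing tests therefore demonstrate that the
pipeline's machinery is correct and that dual-modality fusion helps when
the modalities carry the assumed complementary signal — not clinical
performance.

## Evaluation metrics

* **Dice** 2|Vgt ∩ Vp| / (|Vgt| + |Vp|); equal to the harmonic mean of
  voxel precision and recall; undefined (error) only if both masks are
  empty, which cannot happen in cohort evaluation since references are
  non-empty.  A case is *missed* when Dice = 0.
* **Surface Dice** at tolerance tau (1 mm default): surfaces are the
  centres of foreground voxels with a 6-connected background neighbour;
  the score is the fraction of the pooled surface points lying within tau
  (Euclidean mm, spacing-aware) of the other surface.  This voxel-centre
  definition differs from area-weighted surface elements; at ~1 mm
  isotropic spacing the difference is small, and brute-force all-pairs
  oracle tests pin the chosen semantics exactly.
* **HD95**: 95th percentile (linear interpolation) of the *pooled*
  directed surface distances, in mm; not calculated when the prediction
  is empty, and cohort averages skip such cases.  Pooling (rather than
  the max of two directed percentiles) is a documented convention choice.
* **Non-overlapping components**: predicted 26-connected components with
  zero reference overlap.
* **Volume agreement**: ICC(A,1) — two-way model, absolute agreement,
  single measure — computed from the two-way ANOVA decomposition (checked
  against pingouin), and Bland-Altman mean difference with
  mean ± 1.96 x sd limits of agreement (sample sd, n−1).
* Cohort means carry normal-approximation 95% CIs (mean ± 1.96 sem).

## Desk-scale experiment sizes

The bundled experiments are sized for a single CPU: 64^3 phantom grids,
training crops capped at 48 voxels per axis, a weighted-sum network with
base width 8 / depth 3 trained for 8 epochs on 50 crops (held-out Dice
reaches ~0.8), a 120-epoch single-crop overfit check, and a 10-case
moving-box ablation on 96 x 112 x 112 grids with 35 mm detection jitter
(run with the trained weighted-sum network; the test suite repeats it
with an even smaller base-4 / depth-2 network, which trains reliably at
its pinned seed but, like most very narrow networks, not at every seed).
On such jittered cohorts the moving
box recovers cases the initial box misses outright (missed rate drops
from tens of percent to near zero) while barely changing Dice on
well-detected cases — the qualitative behaviour the method was designed
for.  In the single-crop overfit check a positive weight of 5 is used:
inside a tight crop the class imbalance is mild and a large weight causes
over-segmentation.

## Known limitations

* The engine is CPU-bound; full clinical-scale training (150 epochs on
  hundreds of 81 x 49 x 49 crops) is out of its intended scope.
* Occlusion detection is an input, not a component; jitter in the phantom
  generator is the only model of detector error.
* The flexible-box edge gate is implemented as "closer than 5 voxel
  steps" to a face; a voxel at exactly 5 steps does not trigger growth.
* Registration and skull stripping are assumed done upstream; spacing is
  carried as metadata but phantoms default to 1 mm isotropic.
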