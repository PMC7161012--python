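# Methods

`boxseg3d` implements a weakly-supervised training strategy for 3D binary
tumor segmentation in CT-like volumes, where the only annotation available
for training is an axis-aligned bounding box per case. The strategy has
three stages: (1) pseudo-mask generation by CRF inference inside the box,
(2) group training of K networks on disjoint subsets with cross-prediction,
fused into refined "fusion masks" plus per-voxel confidence weights, and
(3) final training with a voxel-wise weighted cross-entropy (VWCE). A
fully-supervised baseline trained on the true masks serves as the ceiling
for comparison. Everything runs at desk scale on synthetic phantoms.

## Synthetic phantoms

Clinical CT data of renal tumors is not publicly available, so the package
ships a generator of CT-like phantoms that reproduces the properties the
method is sensitive to, without claiming anatomical realism:

- **Geometry.** The tumor is a union of `n_lobes` randomly rotated
  ellipsoids with jittered centers (jitter < half the minimum semi-axis,
  which guarantees the lobes overlap and the foreground is a single
  18-connected component). Semi-axes are drawn per lobe from
  `tumor_radius_range` (default 6–11 voxels in a 48³ volume).
- **Intensity.** Background is homogeneous organ-like tissue
  (`background_level`, default 50 HU); the tumor mean is drawn from
  `tumor_level_range` (default 150–450 HU, emulating variably enhancing
  lesions). A smooth Gaussian-filtered random field (σ = 3 voxels, SD
  `texture_amplitude` = 40 HU) models intra-tumor texture; i.i.d. Gaussian
  noise (SD `noise_sigma` = 20 HU) is added everywhere. The ranges straddle
  the standard abdominal clipping window so the −200..500 HU clip is
  exercised.
- **Determinism.** A phantom is a pure function of (spec, seed); datasets
  derive per-case seeds from a master seed via `numpy.random.SeedSequence`.

What the phantoms do *not* model: neighboring organs and vasculature,
partial-volume effects at tumor boundaries, anisotropic spacing, scanner
noise correlation, and tumors whose intensity overlaps the background
distribution. Passing trend tests on phantoms therefore shows the machinery
is implemented correctly and behaves as designed under controlled contrast;
it does not certify clinical-grade accuracy.

## Pre-processing

Intensities are clipped to a fixed window [−200, 500] HU and min-max scaled
with the *clip bounds* as X_min/X_max, so 0 and 1 mean the same HU value in
every case. Resampling is trilinear for images and nearest-neighbor for
masks. Paired augmentation applies one random crop (constrained to retain at
least one foreground voxel, since a tumor-free crop is degenerate for
box-supervised training) and independent axis flips; the same window and
flips are applied to image and mask.

## Bounding boxes

Weak annotations are derived from reference masks as the tight foreground
extent expanded by a margin `d` on every face and clipped to the volume
(`d` ∈ {0, 5, 10} voxels emulates increasingly sloppy annotation).
Coordinates are 0-based and half-open; boxes serialize to JSON with an
explicit convention tag.

## CRF pseudo-mask generation

Pseudo-masks are obtained by mean-field inference in a binary CRF over the
voxel grid. The unary is built from the box: foreground probability
`fg_prior_inside` (default 0.55) inside, `bg_clamp_eps` (default 10⁻³)
outside; with `bg_clamp_eps = 0` the outside is hard-clamped and the
pseudo-mask provably stays inside the box. The pairwise term is a mixture
of truncated Gaussian kernels with Potts compatibility — an appearance
kernel over (position, normalized intensity) and a position-only smoothness
kernel. Truncation zeroes any pair beyond Manhattan distance `D`, which
turns each mean-field update into a stack of masked convolutions over the
(2D+1)³ window; an O(N²) all-pairs implementation of the *identical* update
is kept as a test oracle and the two are asserted equal to 10⁻⁶ on
randomized small volumes.

Numerical conventions: marginals are renormalized after every iteration;
messages are normalized by each kernel's local row sum (so kernel weights
are on the scale of unary log-odds regardless of window size); the update
multiplies unary *probabilities* by `exp(−pairwise energy)`, which is
algebraically the softmax of energies and preserves hard zeros;
binarization thresholds the foreground marginal at 0.5 with ties going to
background.

Hyperparameter defaults were calibrated once on development phantoms and
then frozen: appearance kernel w = 6, θ_spatial = 5 voxels,
θ_intensity = 0.1 (normalized units); smoothness kernel w = 0.5,
θ_spatial = 1.5; D = 8; 3 iterations. Two properties of the phantom family
drove the choices. First, θ_intensity sits between the intra-class
intensity spread (noise ≈ 0.03, texture ≈ 0.06 normalized) and the minimum
tumor–background contrast (≈ 0.14), so same-tissue affinities stay near 1
while cross-tissue affinities are suppressed. Second, a *long-range*
appearance kernel (D comparable to the annotation margin) is essential:
with Potts compatibility and normalized messages, a flat label front
between two homogeneous regions receives a symmetric neighborhood vote and
does not move, so short-range kernels only round off box corners. Making D
reach across the margin band lets the hard-clamped outside-box background
vote directly on in-box background voxels, which then erode toward the
tumor boundary where the intensity term stops them. Margins larger than D
(d = 10) are consequently only partially recovered — the same qualitative
degradation with d that motivates preferring tight boxes.

The kernel weights w and bandwidths θ are *fixed* hyperparameters here.
No training signal exists for them in a from-boxes-only setting, so they
are exposed in the config rather than learned.

## Group training, fusion masks, weight maps

The training set is partitioned (seeded-random) into K subsets of
near-equal size (default K = 3); one network is trained per subset on its
pseudo-masks with class-weighted cross-entropy; each image is used to train
exactly one network. Every network then predicts every training image
(binarized at 0.5). For image m with pseudo-mask PM and predictions
P¹…P^K:

- fusion mask: FM = CRF(PM ∪ P¹ ∪ … ∪ P^K), where the union plays the same
  role the box interior played in stage 1 (foreground-prior region of the
  unary) and the CRF trims it against the image. The union counteracts the
  under-segmentation typical of networks trained on imperfect pseudo-masks.
- weight map: v = PM + P¹ + … + P^K, with v[v = 0] := K+1. Values 1..K+1
  measure foreground consensus; untouched voxels are confident background
  and get the maximum weight.

One shared CRF parameter block serves both stages by default, with an
optional `fusion_crf` override.

## Losses

For per-voxel class probabilities f and one-hot targets FM, with samples
summed over voxels and classes and averaged over the batch:

- CE: −(1/M) Σ_m Σ_c FM log f
- WCE: class term scaled by w_c (defaults 1.0 tumor / 0.2 background,
  compensating the ~20:1 class imbalance of the phantoms)
- VWCE: WCE with each voxel's term additionally multiplied by v ∈ {1..K+1}.

The per-voxel weight multiplies the individual voxel term (the only reading
consistent with a voxel-wise weight map). Logs are clamped at 10⁻⁸.
VWCE(v≡1) = WCE and WCE(w≡1) = CE exactly, which the tests assert to
10⁻¹².

## Network and training

The segmentation network is a small 3D UNet implemented directly in numpy:
per level two 3×3×3 same-convolutions with leaky ReLU (slope 0.1), 2×
max-pooling down, nearest-neighbor upsampling + skip concatenation up, and
a 1×1×1 output convolution; He-normal seeded initialization; manual
backpropagation; Adam with lr(step) = lr_init · decay_rate^(step/decay_steps)
(decay per epoch by default). The leaky slope matters: at this parameter
count a plain ReLU net frequently loses most of its capacity to dead units
before the foreground class is discovered.

Desk-scale study configuration (used by the trend tests and the acceptance
script): 48³ volumes, depth 3, 4 base channels, batch 4, 30 epochs,
lr_init 3·10⁻³ with 0.95/epoch decay. The learning rate is higher than the
1·10⁻³ default because the desk-scale network is far smaller than a
full-scale UNet and undertrains badly in the small step budget at the
default. Problem sizes (12 training + 6 test phantoms, K = 3) keep a full
three-arm comparison — weak k=3/VWCE, weak k=0/WCE ablation, and the
fully-supervised ceiling — to roughly a quarter hour on one CPU core.

## Evaluation

DSC, Hausdorff distance and average symmetric surface distance; surfaces
are foreground voxels with a background 6-neighbor; distances use the voxel
spacing and are computed by distance transforms, with an all-pairs
brute-force oracle in the tests. Conventions chosen where the metrics are
undefined: DSC(∅,∅) = 1, DSC(A,∅) = 0, HD/ASD raise on empty masks.
Post-processing keeps the largest 18-connected component (face + edge
neighbors); size ties break to the first raster-scan label.

## Known limitations

- The mean-field front-stall means margins much larger than D are not
  recovered; pseudo-mask quality at d = 10 is poor by construction.
- The numpy UNet is CPU-bound and sized for phantoms; the full-scale
  setting (128×128×64) is configurable but slow without an accelerator.
- Stage-2/3 use the same epoch budget; no augmentation is applied in the
  pipeline runs (the phantom family already randomizes geometry and
  intensity).
- Trends (weak ≤ fully-supervised, k=3 ≥ k=0) are statistical statements
  over a small fixed-seed phantom set, not guarantees per case.
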