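# Methods

This note documents the models, numerical choices and known limitations of
the package in one place. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and view conventions

Volumes are indexed `(z, y, x)` with *z* = inferior→superior,
*y* = posterior→anterior, *x* = right→left. The anterior radiograph is the
parallel projection along *y* (rows = *z*, columns = *x*); a view at angle θ
is rendered after rotating the volume about *z*, with the sign convention
fixed so that a 90° view agrees exactly with the lattice rotation
`np.rot90(volume, k=1, axes=(1, 2))`. PSNR-1/2/3 slice along *z* (axial),
*y* (coronal) and *x* (sagittal) in that order.

## Vertebral phantoms

Each phantom is a stack of elliptic-cylinder vertebral bodies along *z*,
separated by disc gaps, each body with a ~1.5-voxel cortical shell and
cortical endplates around a trabecular interior, plus an optional posterior
arch block; an integer mask labels the vertebrae 1..n voxel-exactly.
Defaults: 64³ voxels at 1 mm; 3–4 vertebrae per cohort case (the worst-case
column, 4 bodies at 11 mm plus 3 gaps at 4 mm, fits the 64-voxel extent for
every possible draw); body radii 7–13 mm with a 0.75 anterior–posterior
aspect ratio; intensities cortical 1500 / trabecular 500 / background 50 on
a Hounsfield-like [0, 2500] scale; additive Gaussian noise (σ = 20, clipped
at zero so intensities stay nonnegative). The anisotropic cross-section and
the posterior arch are the minimal features that make the anterior and
lateral views informative about different axes — exactly the asymmetry a
two-view fusion model must exploit. Per-case parameters are drawn from a
stream seeded by `(master seed, case index)`, so cohorts are reproducible
case-by-case.

What the phantoms do **not** emulate: realistic Hounsfield calibration,
trabecular texture, pathology, soft-tissue anatomy, scanner artifacts.
Passing tests therefore demonstrate that the pipeline's machinery is correct
and trainable, not that the model reaches clinical-data performance.

## DRR synthesis

Parallel-beam (orthographic) geometry, not cone-beam: it is the desk-scale
analogue of orthographic volume-rendering captures and admits closed-form
checks (a single opaque voxel projects to exactly one pixel; an axis-aligned
box projects to its exact footprint). Rotation uses trilinear interpolation
with the volume minimum as fill. Intensities are normalized by a fixed
divisor (default 2500 — see "Intensity scale" below) and mapped to opacity
by a six-point piecewise-linear transfer function, default
(0.00, 0.00), (0.10, 0.00), (0.30, 0.02), (0.55, 0.10), (0.75, 0.35),
(1.00, 0.85): soft tissue faint, bone dominant. The exact preset values of
the rendering software this emulates are not published, so the points are
fully configurable. Compositing is front-to-back emission–absorption with
emission equal to normalized intensity; a Beer–Lambert
(`1 − exp(−Σα·step)`) mode is available as `mode="attenuation"`. Ray
sampling steps default to one voxel (`step_mm = 1`); fractional steps use
linear interpolation between slices. The final image is min–max rescaled; a
constant ray image yields all-zeros with a warning rather than an error.

## Radiograph preprocessing

Eight steps: grayscale (channel mean), brightness threshold, 3×3 opening
then 5×5 closing (square structuring elements), largest 8-connected
component (ties broken topmost-leftmost), crop to its bounding box, min–max
normalization, symmetric zero-padding to square (odd remainder at
bottom/right), bilinear resize to 128² (or the configured size).

The default threshold keeps everything brighter than 2 % of the min–max
normalized dynamic range, i.e. it crops away true black background. A
histogram-adaptive Otsu cut is available (`threshold="otsu"`) but is not the
default: re-preprocessing an already-preprocessed image recomputes the
threshold on a renormalized crop, which shifts the crop box every pass
(measured mean per-pixel change ≈ 0.03–0.06, and the scale-dependent
morphology can even split a vertebral column into separate components). The
fixed low cut makes the chain idempotent on its own output to well under
10⁻² per pixel, which the pipeline relies on when preprocessed images
re-enter the chain.

## Packaging, split, augmentation

One HDF5 file per case with datasets `"ct"` (normalized to [0, 1] by the
intensity scale), `"xray1"`, `"xray2"`. The train/test split is a seeded
uniform shuffle with half-up rounding of `0.8·n` (440 cases → 352/88).
Augmentation resizes each 128² view to 150², takes a shared random 128²
crop, and optionally standardizes both views by dataset-level training
mean/sd; the CT passes through unchanged.

## Reconstruction network

**Generator.** Per view: a dense 2D encoder (each block: two 3×3
convolutions with a concatenative connection) at scales S, S/2, S/4, S/8
with channel widths c, 2c, 4c, 4c (`c = base_channels`). At scales S/8, S/4,
S/2 a "bridge" channel-matches with a 2D convolution to width 4g, 2g, g
(`g = max(c/4, 2)`), repeats the 2D map along the view's projection axis
into a pseudo-3D grid, and refines it with a 3D convolution. Each view has a
3D decoder of transposed convolutions (kernel 4, stride 2, pad 1 — exact
doubling) with skip fusion at each scale; a third stream decodes the
element-wise average of the two views' grids after rotating the lateral
grids 90° about *z* (exact lattice rotation, no interpolation). The merge
stage concatenates the three streams with the two raw-view backprojections
and their voxelwise product (the multiplicative visual hull) — a
physics-based shortcut that hands the output stage the two-view consistency
constraint directly instead of forcing it to be rediscovered by gradient
descent. ReLU activations throughout; 1-channel 3×3×3 head with sigmoid.
The head bias is initialized to −2.2 (sigmoid ≈ 0.1): CT volumes are mostly
non-bone, and a dark-prior start removes a large constant error that the
optimizer would otherwise spend its entire small-step budget on (with Adam
at lr 2·10⁻⁴ each parameter can move at most `steps × lr` ≈ 0.03 over a
150-step run).

**Discriminator.** A conditional 3D patch critic: the candidate volume is
concatenated with each radiograph replicated along its own projection axis
(anterior along *y*, lateral along *x*), then three stride-2 kernel-4 3D
convolutions (instance normalization from the second on, no dropout) and a
3×3×3 head produce a grid of real/fake scores (4³ cells at S = 32). Its
three post-activation feature maps feed the feature-matching loss.

**Losses.** Least-squares GAN:
`L_D = ½·mean((D(real)−1)²) + ½·mean(D(fake)²)`,
`L_adv = mean((D(fake)−1)²)`. Reconstruction: voxelwise MSE. Projection:
mean over the three axes of the MSE between axis-mean projections.
Feature matching: mean absolute difference of discriminator features,
averaged over layers, against features of the real volume (detached).
Identity (input consistency): MSE between each input radiograph and the
generated volume's mean projection along that view's axis; it is a soft
prior — the inputs are min–max-stretched composites, not mean projections —
and can be disabled. Default weights `w_gan = 0.1, w_recon = 10,
w_proj = 10, w_fm = 1, w_idt = 1`: isolation runs at desk scale showed that
larger feature-matching/identity weights make the generator objective chase
features of an essentially untrained discriminator and the identity term's
brightness bias, measurably slowing supervised convergence.

**Training loop.** Alternating single-sample updates (discriminator on the
detached fake, then generator on the full objective) with
Adam(2·10⁻⁴, 0.5, 0.99), no weight decay, batch size 1. The learning rate
is constant for the first `⌊E/2⌋` epochs, then decays linearly to zero at
epoch E — the schedule's exact shape is not prescribed anywhere
authoritative, so the common constant-then-linear-decay rule is used. A
non-finite loss aborts with the offending term named. Seeding covers
parameter initialization and data order. Checkpoints are numpy `.npz`
archives of the parameter arrays.

## Evaluation suite

All metrics operate on normalized [0, 1] volumes. MAE/MSE are reported both
per-axial-slice on the normalized scale (MAE0/MSE0) and over the whole
volume after multiplying by the intensity scale, so
`MAE = scale·MAE0` and `MSE = scale²·MSE0` exactly on cubic volumes.
PSNR uses peak 1.0; per-plane PSNRs average the per-slice dB values (not
pooled MSE), which is why PSNR-avg generally differs from PSNR-3D; zero-MSE
cases are capped at 100 dB so reports stay finite. SSIM is slice-averaged
2D with an 11×11 Gaussian window (σ = 1.5), K₁ = 0.01, K₂ = 0.03, dynamic
range 1, computed over fully-interior windows; it matches
`skimage.metrics.structural_similarity(gaussian_weights=True,
use_sample_covariance=False)` to machine precision and is additionally
checked against an explicit per-window loop oracle. Set-level reports are
plain means of per-pair metrics, with PSNR-avg recomputed from the averaged
per-plane values so its defining identity stays exact.

**Intensity scale 2500.** The denormalization constant is configurable with
default 2500, the value consistent with the internal ratios of published
evaluation tables for this task (whole-volume MAE ≈ 2500 × per-slice MAE0,
MSE ≈ 2500² × MSE0); the phantom intensities are placed on the same
[0, 2500] scale.

**Angle sweep.** For each angle in {90°, 85°, 80°, 75°} the lateral view of
every evaluation case is re-rendered at that angle (anterior fixed at 0°),
preprocessed, reconstructed and scored; the report has one metric column per
angle. The model argument is any callable — the trained generator, or a
stub, which is how the sweep's plumbing is tested independently of training
quality.

## Problem sizes

The test suite and the acceptance script run the study at desk scale: 64³
phantoms, 32³ training volumes, four training pairs, 38 epochs × 4 samples
= 152 generator steps, generator width `base_channels = 48` for the training
study and 4 for the single full-geometry (128³) forward pass. These sizes
were chosen so the whole study runs in minutes on one CPU core while still
exercising every code path at full fidelity; the full 128³ geometry differs
only in configuration.

## Known limitations

* Parallel-beam DRRs; no cone-beam or detector physics.
* The identity loss is a heuristic prior (projection types do not match
  exactly); it is down-weighted by default and can be disabled.
* Adversarial training at 150 steps cannot reach equilibrium; the GAN terms
  are exercised, but reconstruction quality at desk scale is driven by the
  supervised terms.
* The evaluation averages are plain means over cases; no per-vertebra or
  region-weighted statistics.
* The numpy network core is single-threaded except for BLAS-backed
  convolution contractions; it is written for clarity and desk-scale sizes,
  not for GPU-scale throughput.
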