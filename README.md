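# vert2ct

Reconstruction of 3D vertebral CT volumes from two synthetic radiographs
(anterior and lateral views), with the full surrounding workflow: vertebral
phantom generation, mask-based region-of-interest cropping, digitally
reconstructed radiograph (DRR) synthesis, radiograph preprocessing and HDF5
packaging, a two-view fusion GAN reconstructor, and a volumetric evaluation
suite including a biplanar-angle sensitivity sweep.

The package is aimed at researchers studying biplanar-X-ray-to-CT
reconstruction who want a self-contained, CPU-scale testbed: every stage runs
on procedurally generated spine phantoms, so no clinical data are required.

## The method

**Inputs.** A spine CT volume `V` (axes *z* = inferior→superior,
*y* = posterior→anterior, *x* = right→left) with a per-vertebra segmentation
mask. The CT is cropped to the tight bounding box of the labelled voxels.

**DRR synthesis.** A radiograph-like view at angle θ about *z* is rendered by
parallel rays along *y*: intensities are normalized by a fixed scale
(`v = clip(I / 2500, 0, 1)`), mapped to opacity by a six-point
piecewise-linear transfer function α(v), and composited front-to-back with
the emission–absorption rule

    C ← C + (1 − A)·α·v,   A ← A + (1 − A)·α,

followed by min–max rescaling. The anterior view is θ = 0°, the lateral view
θ = 90° (85°, 80°, 75° in the sensitivity sweep).

**Reconstruction.** The generator `G(x¹, x²)` has one dense 2D encoder per
view; at three scales the 2D feature maps are channel-matched by 2D
convolutions, expanded along the view's projection axis into pseudo-3D grids
and refined by 3D convolutions; each view has its own transposed-convolution
3D decoder, and a fusion stream combines the two by rotating the lateral
grids 90° about *z* into the anterior frame and averaging element-wise. The
merge stage additionally receives the raw radiographs backprojected along
their ray axes and their voxelwise product (the multiplicative visual hull).
A conditional 3D patch discriminator (instance normalization, no dropout)
scores volumes given the two views. Training minimizes

    L_G = w_gan·L_adv + w_recon·L_MSE + w_proj·L_proj + w_fm·L_FM + w_idt·L_idt

with least-squares GAN objectives, Adam (lr 2·10⁻⁴, β₁ = 0.5, β₂ = 0.99),
batch size 1, and a learning rate that is constant for the first half of the
epochs, then decays linearly to zero. Output volumes are 128³ voxels at 1 mm
(32³ for desk-scale runs).

**Evaluation.** Eleven statistics per ground-truth/reconstruction pair:
MAE0/MSE0 (per-slice, normalized scale), MAE/MSE (whole volume, CT scale),
cosine similarity, PSNR-1/2/3 (slice-averaged along the three anatomical
axes), PSNR-avg, PSNR-3D (whole volume), and slice-averaged Gaussian-window
SSIM.

## Worked example

Generate four phantom cases, build paired samples at 32³, train the GAN for
38 epochs (152 generator steps, a few CPU-minutes), and score one
reconstruction:

```python
from vert2ct import eval_metrics, phantom, pipeline, recon_gan

case_dirs = phantom.generate_cohort(4, seed=0, out_dir="cohort")
samples = pipeline.assemble_samples(case_dirs, size=32)

cfg = recon_gan.GanConfig(volume_size=32, base_channels=48, n_epochs=38, seed=0)
result = recon_gan.train(samples, cfg)
print(f"reconstruction loss: {result.history[0]['l_recon']:.4f} -> "
      f"{result.history[-1]['l_recon']:.4f}")

s = samples[0]
pred = result.generator.predict_volume(s.xray1, s.xray2)
report = eval_metrics.evaluate_pair(s.ct, pred)
print(eval_metrics.report_frame(report).round(3))
```

Output:

```
reconstruction loss: 0.0521 -> 0.0099
                       Value
MAE0                   0.069
MSE0                   0.010
MAE                  172.448
MSE                60775.349
Cosine Similarity      0.948
PSNR-3D               20.122
PSNR-1                20.768
PSNR-2                20.615
PSNR-3                20.295
PSNR-avg              20.559
SSIM                   0.559
```

The voxelwise MSE drops five-fold over 152 generator steps; the
reconstruction of the first training pair reaches 20.1 dB PSNR-3D (its mean
absolute voxel error is 0.069 on the normalized scale, i.e. ≈ 172 intensity
units on the [0, 2500] CT scale), and the cosine similarity of 0.95 says the
reconstructed column has the right overall shape. SSIM of 0.56 reflects that
fine shell/interior structure is only partially recovered at this tiny
training budget.

A sklearn-style estimator wraps the same model
(`vert2ct.BiplanarCTReconstructor`, with `fit(X, y)` / `predict(X)` /
`get_params`), and a CLI mirrors the pipeline stages
(`vert2ct phantoms | crop | drr | preprocess | package | split | train |
evaluate | angle-sweep | run-all`).

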