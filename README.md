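# blurkit

Tools for quantifying — and avoiding — the spatial resolution that
high-resolution fMRI data silently lose during preprocessing.

Submillimeter fMRI can resolve cortical columns and layers, but every
interpolation applied to the data (motion correction, registration
resampling, volume-to-surface projection, distortion warping) acts as an
unwanted smoothing kernel. Individually these losses look minor; combined
they can erase the very features the acquisition was designed to see.
`blurkit` is for researchers building or auditing high-resolution fMRI
pipelines who want a number — an equivalent Gaussian FWHM, per voxel or
per vertex — for the blur each stage introduces, and implementations of
the preprocessing strategies that minimize it.

## The core idea

Feed i.i.d. unit-variance white noise through a preprocessing stage. An
interpolation with weights $w_k$ reduces the temporal standard deviation
(TSTD) of the filtered noise from 1 to $\sqrt{\sum_k w_k^2}$. Calibrating
measured TSTD against explicit 3D Gaussian smoothing at known FWHM on the
same voxel grid gives a lookup table

$$\mathrm{TSTD} \mapsto \mathrm{FWHM}_{\mathrm{equiv}},\qquad
\mathrm{FWHM} = 2\sqrt{2\ln 2}\,\sigma ,$$

so *any* pipeline — including ones with no closed-form kernel — gets a
spatially resolved "error bar" on its effective resolution
(`blurkit.blur_audit`). Around this meter the package provides:

* **Low-blur resampling** — transform composition (interpolate once),
  volume upsampling before transforms, higher-order interpolants
  (`resample`, `surface.vol2surf_composed`);
* **Surface machinery** — FreeSurfer surface I/O, midpoint mesh
  refinement, equidistant intracortical surface families, radial-only
  intracortical smoothing, unique-voxel accounting (`surface`);
* **Motion** — a self-contained rigid estimator and the
  accuracy-vs-voxel-size simulation (`motion`);
* **Distortion** — Jacobian-determinant voxel-size maps of deformation
  fields (`distortion`);
* **A ground-truth benchmark** — interdigitated, non-overlapping columnar
  stripe systems on a synthetic folded cortical sheet; the Dice overlap of
  their independently mapped activations measures pipeline blur
  (`stripemap`, `synth`).

## Worked example

```python
import blurkit as bk
from blurkit.blurmetry import interior_mask

lookup = bk.build_lookup(1.0, nframes=300, seed=7, grid_dims=(48, 48, 48))
grid = bk.VoxelGrid.isotropic(48, 1.0)
for method in ("nearest", "sinc", "quintic", "cubic", "linear"):
    fm = bk.blur_audit(
        lambda v, m=method: bk.translate_volume(v, (0.5, 0.5, 0.5), m),
        grid, lookup, nframes=200, seed=3, mask_margin_mm=9.0)
    print(f"{method:8s} half-voxel shift -> {fm.mean():.2f} mm FWHM")
```

prints

```
nearest  half-voxel shift -> 0.60 mm FWHM
sinc     half-voxel shift -> 0.89 mm FWHM
quintic  half-voxel shift -> 0.95 mm FWHM
cubic    half-voxel shift -> 1.05 mm FWHM
linear   half-voxel shift -> 1.42 mm FWHM
```

A single half-voxel resampling with trilinear interpolation costs a 1-mm
acquisition about 1.4 mm of equivalent Gaussian smoothing; nearest-
neighbor stays near the lookup's plateau edge (0.5 mm on a 1-mm grid, the
smallest blur detectable at that grid spacing). The `examples/` directory
has one short script per capability — blur audits, sequential-vs-composed
projection, motion accuracy vs voxel size, the stripe-overlap benchmark,
and Jacobian voxel-size maps — each printing what it computes and what
the numbers mean.

A thin command-line layer mirrors the common operations
(`blurkit vol-info | upsample | moco | refine | vol2surf | build-lookup |
jacobian | warp`).

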