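# Methods

`blurkit` quantifies the spatial resolution that high-resolution fMRI data
lose during preprocessing, and implements the low-blur alternatives to the
steps that cause those losses. This note records the models, conventions,
parameter choices and known limitations of the implementation.

## The white-noise blur meter

Every interpolation step replaces a sample with a weighted combination of
neighboring samples. Applied to an i.i.d. unit-variance white-noise time
series, a spatial kernel with weights $w_k$ changes the temporal standard
deviation (TSTD) of each location from 1 to $\sqrt{\sum_k w_k^2} \le 1$,
while leaving structured signal largely intact. Measuring per-location
TSTD after a preprocessing stage therefore measures the blur that stage
silently applied.

To express the result in familiar units, a calibration table maps TSTD to
the full width at half maximum (FWHM) of the *equivalent explicit 3D
Gaussian kernel* on the same voxel grid: unit-variance noise is smoothed
at each tabulated FWHM (0.1–3.9 mm in 0.2-mm steps by default) and the
across-voxel mean TSTD recorded. The conversion uses
$\mathrm{FWHM} = 2\sqrt{2\ln 2}\,\sigma$.

Numerical choices:

* **Monte-Carlo size.** The tabulated value is a mean over the interior
  of a 64³ grid (≈200k voxels), so its sampling error is far below 1e-3
  already at 300 noise frames; `build_lookup` therefore defaults to a
  few hundred frames for the table, while *measured* maps use as many
  frames as the experiment specifies (per-location TSTD noise is
  $1/\sqrt{2(n-1)}$, e.g. 2.2% at 1000 frames). The across-voxel spread
  is recorded per FWHM (`tstd_sd`).
* **Borders.** All TSTD statistics exclude a border of three kernel
  standard deviations plus one voxel, because the constant fill value used
  outside the field of view deflates variance at the edge.
* **The plateau.** Kernels narrower than the voxel spacing barely mix
  neighbors, so the table is flat near 1 at small FWHM; blur below the
  *plateau edge* is undetectable on that grid. The edge is defined as the
  largest FWHM whose tabulated TSTD is within a relative 5e-4 of the
  table maximum (on a 1-mm grid this gives ≈0.5 mm; finer grids have
  smaller plateaus, which is one benefit of upsampling). Inversion is
  piecewise-linear on the monotone envelope of the table; TSTD at or above
  the plateau ceiling maps to the plateau edge, values below the table
  minimum clip to the largest tabulated FWHM and are counted in the map's
  metadata. Because measurement noise in a per-vertex TSTD can only map
  *away* from the plateau, mean FWHM estimates near the plateau carry a
  small positive bias that shrinks with the number of noise frames; blur
  bounds for low-blur pathways are therefore quoted as "FWHM above the
  plateau edge".

## Interpolants and resampling conventions

* Voxel indices are 0-based, voxel centers map through the NIfTI affine,
  world coordinates are RAS mm.
* Interpolants: `nearest` (ties toward the lower index), `linear`,
  `cubic`/`quintic` (cardinal B-splines with prefiltering, exact on-grid),
  and `sinc` (Hann-windowed, half-width 7 voxels — the common neuroimaging
  choice). All kernels are normalized to partition unity.
* Spatial transforms use constant fill 0 outside the field of view;
  upsampling clamps at the border instead so a constant volume stays
  constant. The upsampled grid keeps the field of view centered: the first
  output center is the first input center minus
  `spacing_out * (factor - 1) / 2`.
* Pure translations take a separable fast path (per-axis taps, one pass
  over all frames); general rigid maps sample through the composed
  index→world→index map. Half-voxel shifts of white noise reproduce the
  expected blur ranking: nearest < sinc < quintic < cubic < linear
  (in induced FWHM).

## Rigid motion

Motion parameters follow the radiological reporting convention: roll,
pitch, yaw in degrees about the I–S, R–L and A–P world axes, and dS, dL,
dP displacements in mm along superior, left and posterior. Rotations are
composed roll∘pitch∘yaw about a stated fixed center (the volume center in
world coordinates); angles are stored in degrees and converted internally.
The composition order and center are conventions of this package — motion
tools differ and rarely document theirs — and parameter↔matrix round-trips
are exact away from gimbal lock.

The estimator minimizes the mean squared intensity difference to the
reference frame over the six parameters, with

* a Gaussian pyramid (factor 2) and an integer-voxel translation search at
  the coarsest level, then Powell refinement (xtol 1e-4);
* presmoothing of both images at a fixed physical scale (σ = 0.8 mm).
  A fixed *voxel* scale would regularize fine grids less than coarse ones;
  more importantly, without presmoothing the interaction of image noise
  with linear interpolation creates shallow cost minima at half-voxel
  offsets;
* a physical border margin (3 mm) on the cost mask. This matters: a
  fixed-voxel margin admits fill-value contamination on fine grids and
  biases rotations by ~0.2° in the regridding experiment;
* cost evaluation on at most 120k strided voxels for bounded runtime.

The accuracy experiment replays a known trace on a smooth Gaussian-blob
phantom (36-mm field of view, 15 blobs) and re-estimates it after
regridding to 0.5/1/2/3 mm. Two modes: `resample_after_motion` regrids an
acquired 1-mm series (noise is added once on the native grid and regridded
with it), `resample_before_motion` emulates acquisition at each resolution
(white noise per frame on the target grid). Accuracy is summarized as
per-parameter RMSE over frames, pooled as the mean of the six. With
measurement noise at 0.1 (≈4% of the phantom peak), the median pooled RMSE
over 10 random sinusoidal traces is monotone non-decreasing in voxel size
in both modes; the gap between 0.5 and 1 mm is small in the regridding
mode because regridded data contain no information beyond the native grid.

## Surfaces

* Meshes are vertex/face arrays in world mm; FreeSurfer binary geometry
  and curv formats are read and written through nibabel.
* Refinement is linear midpoint subdivision — new vertices at edge
  midpoints (deduplicated via a canonical sorted-edge key, deterministic
  ordering: originals first, then edges in lexicographic order), each
  triangle split into four, geometry and original vertex positions
  unchanged. Per iteration V' = V + E and F' = 4F; mean edge length halves
  exactly on closed meshes (midsegment theorem) and to ~1% on bordered
  patches, where boundary edges enter the mean asymmetrically.
* Equidistant depth families place vertex i at depth d on the segment
  between white and pial vertex i; step 0.1 gives the conventional
  11-surface family.
* Volume-to-surface projection transforms vertices into voxel space and
  samples the volume there (nearest or trilinear). The composed variant
  folds each frame's motion transform and the anatomical registration into
  one map per frame, so the time series is interpolated exactly once.
  Under nearest-neighbor projection each vertex is a single voxel sample
  and white-noise TSTD stays at 1 (no blur); trilinear projection is a
  convex combination and strictly reduces variance except exactly at voxel
  centers, and spreads it more across the cortex.
* Unique-voxel accounting projects voxel indices with nearest-neighbor
  interpolation and counts distinct indices. The denominator — voxels
  within one voxel diagonal of the surface — is our definition (the
  quantity is reported in the field without one); it is computed from the
  surface geometry refined to a fixed edge-length target (0.4× voxel
  spacing) via a vertex k-d tree, so a mesh and its refinements share the
  same denominator up to that tolerance.
* Intracortical smoothing averages across the depth maps of a family at
  each vertex, restricted to a depth range (default the bottom 20% of the
  ribbon), uniform weights by default with a Gaussian-over-depth option.
  No tangential mixing occurs by construction.

## Distortion

Deformation fields store a world-mm displacement per voxel; the warp pulls
back through `x -> x + u(x)`. The Jacobian voxel-size map is
`det(I + du/dx)` with central differences (one-sided at borders) taken
with respect to world mm through the grid affine. Synthetic low-order
polynomial fields (degree ≤ 5, evaluated in coordinates centered on a
stated isocenter) stand in for proprietary gradient-coil models and are
parameterized to reach ±20% volume change; rigid fields give det 1 to
finite-difference accuracy, uniform scaling s gives s³.

## Activation mapping and the stripe benchmark

The GLM regressor is a boxcar convolved with a unit-area gamma HRF whose
mean lag is the hemodynamic delay (2.25 s default) and whose standard
deviation is the dispersion (1.25 s): shape = delay²/dispersion²,
scale = dispersion²/delay. The design adds an intercept and a single
linear drift; t statistics are two-sided. Fixed-effects combination is
inverse-variance weighting with summed degrees of freedom. Thresholded
maps drop connected components smaller than two vertices (edge adjacency);
Dice is 2|A∩B|/(|A|+|B|), defined as 0 (flagged) for an empty union.

The synthetic benchmark builds a folded two-boundary cortical sheet
(40 mm patch, 1-mm vertex spacing, 2-mm thickness, sinusoidal folds of
2.5 mm amplitude and 25 mm wavelength; staggered near-equilateral lattice
so mean edge length tracks the requested spacing — vertex density is
2/√3 per spacing², not 1), labels two interdigitated stripe systems
(3–4 mm stripes with an unlabeled gap fraction, disjoint by construction),
and forward-models block-design BOLD runs: baseline 100, amplitude in
percent signal change (2% default), gamma-HRF response in voxels whose
centers lie within half a thickness of a labeled mid-surface vertex,
per-frame rigid motion, then i.i.d. Gaussian noise (σ = 1 signal unit,
i.e. tSNR ≈ 100). Two independent sessions (one per stripe system, own
motion trace and noise) are preprocessed by named strategies — sequential
linear (default), composed single-interpolation, 2× upsampled, refined
mesh, intracortical smoothing — GLM-fit, thresholded and overlaid. Less
blur yields lower cross-system Dice; at p < 0.01 the median over 10 seeds
is ≈0.16 (default) vs ≈0.06 (composed) and ≈0.03 (upsampled) under these
conditions.

## What the synthetic data do not emulate

EPI physics (T2* decay, partial Fourier), physiological noise and its
temporal structure, real cortical geometry and FreeSurfer reconstruction
error, BBR registration error (registrations are exact by construction),
and vendor gradient-coil fields. Passing orderings on the phantom
therefore demonstrate the *relative* behavior of preprocessing pathways
under controlled conditions, not absolute performance on real data; the
absolute RMSE and Dice magnitudes depend on phantom contrast, noise level
and estimator and are not comparable to values measured on acquisitions.

## Problem sizes

The test suite uses 64³ grids with 300–1000 noise frames for blur
metrology, a 36³ phantom with 5-frame traces and 10 seeds for the motion
ordering, and a 24-mm sheet with 48-frame runs and 10 seeds for the Dice
ordering — sizes at which every quantity reported is stable against its
own Monte-Carlo error on a single CPU.
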