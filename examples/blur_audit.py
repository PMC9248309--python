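"""Measure the blur each interpolant induces during a half-voxel shift.

Builds a TSTD<->FWHM lookup for a 1-mm grid, then pushes white noise
through a half-voxel translation with each interpolation kernel and
converts the surviving temporal standard deviation into equivalent
Gaussian FWHM.  Lower FWHM = less inadvertent smoothing.
"""

import blurkit as bk
from blurkit.blurmetry import interior_mask

lookup = bk.build_lookup(1.0, nframes=300, seed=7, grid_dims=(48, 48, 48))
print(f"1-mm lookup: plateau edge {lookup.plateau_edge:.1f} mm "
      "(blur below this is undetectable on a 1-mm grid)")

grid = bk.VoxelGrid.isotropic(48, 1.0)
mask = interior_mask(grid, 9.0)
for method in ("nearest", "sinc", "quintic", "cubic", "linear"):
    fm = bk.blur_audit(
        lambda v, m=method: bk.translate_volume(v, (0.5, 0.5, 0.5), m),
        grid, lookup, nframes=200, seed=3, mask_margin_mm=9.0)
    print(f"  {method:8s} half-voxel shift -> {fm.mean():.2f} mm FWHM")

print("The ranking (nearest least, linear most) is why low-order "
      "interpolation during resampling costs effective resolution.")
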