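"""Motion-estimation accuracy as a function of voxel grid spacing.

Replays a known sinusoidal motion trace on a smooth phantom, regrids the
moving series to several voxel sizes, re-estimates the motion, and prints
the RMSE between estimated and true parameters.
"""

import blurkit as bk

grid = bk.VoxelGrid.isotropic(36, 1.0)
phantom = bk.make_smooth_phantom(grid, 15, seed=3)
trace = bk.make_motion_trace(5, (0.3, 0.3, 0.3, 0.5, 0.5, 0.5), seed=4,
                             center=grid.center_world)

results = bk.motion_accuracy_experiment(
    phantom, trace, (0.5, 1.0, 2.0, 3.0),
    mode="resample_after_motion", noise_sd=0.1, seed=5)

print("voxel size -> pooled RMSE (mean over 3 rotations in deg and "
      "3 displacements in mm):")
for spacing, acc in results.items():
    print(f"  {spacing:.1f} mm : {acc.pooled_rmse:.3f}")
print("Coarser grids estimate the same motion less accurately — one "
      "reason upsampling before motion correction helps.")
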