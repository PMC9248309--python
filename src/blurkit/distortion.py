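"""Deformation fields, Jacobian voxel-size maps, and warped resampling.

Geometric distortion (gradient-coil nonlinearity, susceptibility gradients)
does more than displace voxels: the local volume scale of the warp — the
Jacobian determinant of the deformation — compresses or expands the *true*
voxel size, producing spatially varying effective resolution that no
postprocessing can undo.  Fields here are synthetic low-order polynomials
standing in for vendor coil models, exercising the identical computation.

Conventions: a deformation field stores a world-mm displacement ``u`` per
voxel; the warp maps an output-space point x to the source-space point
``x + u(x)``, and images are pulled back through it.  The Jacobian map is
``det(I + du/dx)`` with gradients taken with respect to world mm (central
differences, one-sided at borders).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgcore import RigidTransform, VoxelGrid, Volume
from .resample import as_interpolant, sample_volume

__all__ = [
    "DeformationField",
    "VoxelSizeMap",
    "polynomial_field",
    "rigid_displacement_field",
    "jacobian_map",
    "voxel_size_histogram",
    "apply_deformation",
]


@dataclass
class DeformationField:
    """World-mm displacement vector per voxel, shape dims + (3,)."""

    grid: VoxelGrid
    displacement: np.ndarray

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, float)
        if self.displacement.shape != tuple(self.grid.dims) + (3,):
            raise ValueError("displacement must have shape dims + (3,)")
        if not np.isfinite(self.displacement).all():
            raise ValueError("displacement contains non-finite values")


@dataclass
class VoxelSizeMap:
    """Relative voxel volume scale (unitless Jacobian determinant)."""

    grid: VoxelGrid
    jacobian_det: np.ndarray


def polynomial_field(grid: VoxelGrid, terms, center=(0.0, 0.0, 0.0)
                     ) -> DeformationField:
    """Displacement from low-order polynomials in centered world coordinates.

    ``terms`` is a sequence of ``(component, (px, py, pz), coeff)`` tuples:
    displacement component ``component`` (0..2) gains
    ``coeff * dx**px * dy**py * dz**pz`` with ``(dx, dy, dz)`` the world
    offset from ``center`` in mm.  Total degree per term is limited to 5.
    """
    centers = grid.voxel_to_world(grid.voxel_centers())
    d = centers - np.asarray(center, float)
    u = np.zeros((len(centers), 3))
    for comp, (px, py, pz), coeff in terms:
        if px + py + pz > 5:
            raise ValueError("polynomial degree must be <= 5")
        u[:, int(comp)] += coeff * d[:, 0] ** px * d[:, 1] ** py * d[:, 2] ** pz
    return DeformationField(grid, u.reshape(grid.dims + (3,)))


def rigid_displacement_field(grid: VoxelGrid, t: RigidTransform) -> DeformationField:
    """Field whose warp reproduces ``resample_rigid`` with transform ``t``:
    ``u(x) = t^{-1}(x) - x``."""
    centers = grid.voxel_to_world(grid.voxel_centers())
    u = t.inverse().apply(centers) - centers
    return DeformationField(grid, u.reshape(grid.dims + (3,)))


def jacobian_map(field: DeformationField) -> VoxelSizeMap:
    """Jacobian determinant ``det(I + du/dx)`` of the deformation.

    Values below 1 mean the true voxel is compressed (finer effective
    resolution), above 1 expanded.  A rigid-only field gives 1 everywhere
    up to finite-difference error.
    """
    if min(field.grid.dims) < 2:
        raise ValueError("need >= 2 voxels per axis for finite differences")
    u = field.displacement
    ainv3 = np.linalg.inv(field.grid.affine[:3, :3])
    # du[c, i] = d u_c / d index_i, then chain through d index / d world
    g = np.empty(u.shape[:3] + (3, 3))
    for c in range(3):
        di = np.gradient(u[..., c], axis=(0, 1, 2))
        for w in range(3):
            g[..., c, w] = sum(di[i] * ainv3[i, w] for i in range(3))
    jac = np.eye(3) + g
    det = np.linalg.det(jac)
    return VoxelSizeMap(field.grid, det)


def voxel_size_histogram(vmap: VoxelSizeMap, mask: np.ndarray | None = None,
                         bins=50, value_range=None) -> dict:
    """Histogram and summary statistics of relative voxel size in a mask."""
    vals = vmap.jacobian_det
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape != vals.shape:
            raise ValueError("mask shape must match the map")
        vals = vals[mask]
    else:
        vals = vals.ravel()
    if vals.size == 0:
        raise ValueError("empty mask")
    counts, edges = np.histogram(vals, bins=bins, range=value_range)
    return {
        "counts": counts,
        "bin_edges": edges,
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "n": int(vals.size),
    }


def apply_deformation(v: Volume, field: DeformationField, method="linear",
                      fill: float = 0.0) -> Volume:
    """Pull-back warp: sample ``v`` at ``x + u(x)`` for every output voxel
    center x of the field's grid.  4D input is warped frame-wise."""
    m = as_interpolant(method)
    centers = field.grid.voxel_to_world(field.grid.voxel_centers())
    src_world = centers + field.displacement.reshape(-1, 3)
    coords = v.grid.world_to_voxel(src_world)

    def one(frame):
        return sample_volume(frame, coords, m, fill=fill).reshape(field.grid.dims)

    out = v.map_frames(one)
    return Volume(field.grid, out)
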