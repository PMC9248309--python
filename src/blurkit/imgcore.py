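"""Volumes, voxel grids and rigid-body transforms.

World coordinates are RAS millimetres throughout: +x right, +y anterior,
+z superior.  Voxel indices are 0-based and voxel *centers* map through the
grid affine (NIfTI convention).  Rigid motion is parameterized the way
motion-correction tools report it: three rotations in degrees (roll about
the inferior-superior axis, pitch about the right-left axis, yaw about the
anterior-posterior axis) and three displacements in mm (dS superior,
dL left, dP posterior).  Rotations are composed roll∘pitch∘yaw about a
stated fixed center, by default the world origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "VoxelGrid",
    "Volume",
    "RigidTransform",
    "MotionTrace",
    "rigid_from_params",
    "rigid_from_matrix",
    "read_volume",
    "write_volume",
    "read_affine",
    "write_affine",
]


class FormatError(ValueError):
    """Raised for unreadable or structurally invalid input files."""


# --------------------------------------------------------------------------- #
# grids and volumes
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class VoxelGrid:
    """An axis-aligned voxel lattice with a voxel-index -> world-mm affine."""

    dims: tuple[int, int, int]
    affine: np.ndarray  # 4x4, voxel index -> world mm

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        if any(d < 1 for d in dims):
            raise ValueError(f"dims must be >= 1, got {dims}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("grid affine is not invertible")
        aff = aff.copy()
        aff[3] = (0.0, 0.0, 0.0, 1.0)
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    @classmethod
    def isotropic(cls, dims, spacing: float, origin=None) -> "VoxelGrid":
        """Axis-aligned grid; by default centered on the world origin."""
        dims = tuple(int(d) for d in np.atleast_1d(dims) * np.ones(3, int))
        if origin is None:
            origin = -(np.asarray(dims) - 1) / 2.0 * spacing
        aff = np.eye(4)
        aff[:3, :3] *= spacing
        aff[:3, 3] = origin
        return cls(dims, aff)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm (column norms of the affine 3x3 block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def center_world(self) -> np.ndarray:
        """World coordinates of the grid center (used as rotation center)."""
        c = (np.asarray(self.dims) - 1) / 2.0
        return self.affine[:3, :3] @ c + self.affine[:3, 3]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def voxel_to_world(self, idx) -> np.ndarray:
        idx = np.asarray(idx, float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, pts) -> np.ndarray:
        pts = np.asarray(pts, float)
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) voxel indices of every voxel, C-order."""
        ii = np.indices(self.dims).reshape(3, -1).T
        return ii.astype(float)

    def is_axis_aligned(self, tol: float = 1e-9) -> bool:
        a = self.affine[:3, :3]
        off = a - np.diag(np.diag(a))
        return bool(np.all(np.abs(off) <= tol))


@dataclass
class Volume:
    """Scalar data on a :class:`VoxelGrid`, 3D or 4D (last axis = frames)."""

    grid: VoxelGrid
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"data must be 3D or 4D, got {self.data.ndim}D")
        if tuple(self.data.shape[:3]) != tuple(self.grid.dims):
            raise ValueError(
                f"data shape {self.data.shape[:3]} != grid dims {self.grid.dims}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("volume data contains non-finite values")

    @property
    def nframes(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]

    @property
    def is4d(self) -> bool:
        return self.data.ndim == 4

    def frame(self, t: int) -> np.ndarray:
        return self.data if self.data.ndim == 3 else self.data[..., t]

    def map_frames(self, fn) -> np.ndarray:
        """Apply ``fn`` to each 3D frame; returns the stacked raw array."""
        if self.data.ndim == 3:
            return np.asarray(fn(self.data))
        return np.stack([fn(self.data[..., t]) for t in range(self.nframes)],
                        axis=-1)


# --------------------------------------------------------------------------- #
# rigid transforms
# --------------------------------------------------------------------------- #

# parameter order everywhere: (roll, pitch, yaw, dS, dL, dP)
PARAM_NAMES = ("roll", "pitch", "yaw", "dS", "dL", "dP")

# Euler sequence: roll about z (I-S), pitch about x (R-L), yaw about y (A-P),
# composed as R = Rz(roll) @ Rx(pitch) @ Ry(yaw)  (scipy intrinsic "ZXY").
_EULER_SEQ = "ZXY"


def _displacement_to_world(dS: float, dL: float, dP: float) -> np.ndarray:
    # dS along +z (superior), dL along -x (left), dP along -y (posterior)
    return np.array([-dL, -dP, dS], float)


def _world_to_displacement(t: np.ndarray) -> tuple[float, float, float]:
    return float(t[2]), float(-t[0]), float(-t[1])


@dataclass(frozen=True)
class RigidTransform:
    """A world->world rigid map, rotation about a fixed center then translation.

    ``x -> R (x - c) + c + d`` with R the rotation matrix and d the world
    translation.  The six motion parameters are recoverable away from gimbal
    lock (pitch = +-90 deg).
    """

    matrix: np.ndarray  # 4x4 world -> world
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        m = np.asarray(self.matrix, float).copy()
        if m.shape != (4, 4):
            raise ValueError("rigid matrix must be 4x4")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation block has determinant -1 (reflection)")
        m[3] = (0, 0, 0, 1)
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)
        c = np.asarray(self.center, float).copy()
        c.flags.writeable = False
        object.__setattr__(self, "center", c)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def params(self) -> np.ndarray:
        """(roll, pitch, yaw, dS, dL, dP) in degrees / mm."""
        r = Rotation.from_matrix(self.rotation)
        roll, pitch, yaw = r.as_euler(_EULER_SEQ, degrees=True)
        # matrix translation = c - R c + d
        d = self.matrix[:3, 3] - self.center + self.rotation @ self.center
        dS, dL, dP = _world_to_displacement(d)
        return np.array([roll, pitch, yaw, dS, dL, dP])

    def apply(self, pts) -> np.ndarray:
        pts = np.asarray(pts, float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        return RigidTransform(np.linalg.inv(self.matrix), self.center)

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(np.allclose(self.matrix, np.eye(4), atol=tol))


def rigid_from_params(params, center=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Build a rigid transform from the six motion parameters.

    Rotations (degrees) are applied as roll∘pitch∘yaw about ``center``
    (world mm), followed by the translation.
    """
    params = np.asarray(params, float)
    if params.shape != (6,):
        raise ValueError(f"expected 6 motion parameters, got shape {params.shape}")
    if not np.isfinite(params).all():
        raise ValueError("motion parameters must be finite")
    roll, pitch, yaw, dS, dL, dP = params
    r = Rotation.from_euler(_EULER_SEQ, [roll, pitch, yaw], degrees=True).as_matrix()
    c = np.asarray(center, float)
    d = _displacement_to_world(dS, dL, dP)
    m = np.eye(4)
    m[:3, :3] = r
    m[:3, 3] = c - r @ c + d
    return RigidTransform(m, c)


def rigid_from_matrix(matrix, center=(0.0, 0.0, 0.0)) -> RigidTransform:
    """Wrap an existing 4x4 rigid world map, attributing rotation to ``center``."""
    return RigidTransform(np.asarray(matrix, float), np.asarray(center, float))


@dataclass
class MotionTrace:
    """One rigid transform per frame; the reference frame's is the identity."""

    transforms: list[RigidTransform]
    reference_index: int

    def __post_init__(self):
        if len(self.transforms) == 0:
            raise ValueError("motion trace must contain at least one transform")
        if not 0 <= self.reference_index < len(self.transforms):
            raise ValueError("reference_index out of range")
        if not self.transforms[self.reference_index].is_identity(tol=1e-9):
            raise ValueError("reference frame transform must be the identity")

    def __len__(self) -> int:
        return len(self.transforms)

    @property
    def params(self) -> np.ndarray:
        """(nframes, 6) parameter array."""
        return np.stack([t.params for t in self.transforms])

    @classmethod
    def from_params(cls, params, reference_index=None, center=(0, 0, 0)) -> "MotionTrace":
        params = np.atleast_2d(np.asarray(params, float))
        if reference_index is None:
            reference_index = params.shape[0] // 2
        transforms = [rigid_from_params(p, center) for p in params]
        return cls(transforms, int(reference_index))

    def to_tsv(self, path) -> Path:
        path = Path(path)
        header = "\t".join(PARAM_NAMES)
        np.savetxt(path, self.params, delimiter="\t", header=header, comments="")
        return path

    @classmethod
    def from_tsv(cls, path, reference_index=None, center=(0, 0, 0)) -> "MotionTrace":
        arr = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
        return cls.from_params(arr, reference_index, center)


# --------------------------------------------------------------------------- #
# I/O
# --------------------------------------------------------------------------- #


def read_volume(path) -> Volume:
    """Read a NIfTI-1/2 volume, preserving on-disk dtype and frame order."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 2:
        data = data[..., None]
    if data.ndim not in (3, 4):
        raise FormatError(f"{path}: expected 3D/4D image, got {data.ndim}D")
    grid = VoxelGrid(data.shape[:3], img.affine)
    return Volume(grid, data)


def write_volume(v: Volume, path) -> Path:
    """Write a volume as NIfTI-1; float32 payloads round-trip bit-exactly."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(v.data), v.grid.affine)
    img.set_qform(v.grid.affine, code=1)
    img.set_sform(v.grid.affine, code=1)
    nib.save(img, str(path))
    return path


def read_affine(path) -> np.ndarray:
    """Read a 4x4 affine from 4-line whitespace-delimited text (FSL .mat)."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape != (4, 4):
        raise FormatError(f"{path}: expected a 4x4 matrix, got {arr.shape}")
    return arr


def write_affine(matrix, path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(matrix, float), fmt="%.12g")
    return path
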