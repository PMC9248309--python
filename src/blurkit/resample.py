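"""Interpolation kernels, upsampling, rigid resampling, transform composition.

Every resampling step in an fMRI pipeline convolves the data with its
interpolation kernel, which acts as an unwanted spatial smoothing filter.
This module provides the pull-back resampling primitives used everywhere
else, with a consistent set of interpolants:

========  =========================================================
nearest   pick the nearest source voxel (ties toward the lower index)
linear    trilinear (tent kernel)
cubic     cardinal cubic B-spline (prefiltered; on-grid exact)
quintic   cardinal quintic B-spline (prefiltered; on-grid exact)
sinc      Hann-windowed sinc, half-width 7 voxels
========  =========================================================

Boundary policy for spatial transforms is a constant fill value (default 0)
outside the source field of view; upsampling clamps at the edge instead so
that a constant volume stays exactly constant.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .imgcore import RigidTransform, VoxelGrid, Volume, rigid_from_matrix

__all__ = [
    "Interpolant",
    "as_interpolant",
    "sample_volume",
    "upsample",
    "resample_rigid",
    "translate_volume",
    "compose_transforms",
    "motion_correct",
]

SINC_HALFWIDTH = 7  # voxels

_SPLINE_ORDER = {"nearest": 0, "linear": 1, "cubic": 3, "quintic": 5}
_SUPPORT = {"nearest": 0.5, "linear": 1.0, "cubic": 2.0, "quintic": 3.0,
            "sinc": float(SINC_HALFWIDTH)}


class Interpolant:
    """A named interpolation kernel with its half-width in voxels."""

    names = ("nearest", "linear", "cubic", "quintic", "sinc")

    def __init__(self, name: str):
        if name not in self.names:
            raise ValueError(f"unknown interpolant {name!r}; choose from {self.names}")
        self.name = name

    @property
    def support(self) -> float:
        return _SUPPORT[self.name]

    @property
    def spline_order(self) -> int | None:
        return _SPLINE_ORDER.get(self.name)

    def __repr__(self):
        return f"Interpolant({self.name!r})"

    def __eq__(self, other):
        return isinstance(other, Interpolant) and other.name == self.name


def as_interpolant(method) -> Interpolant:
    return method if isinstance(method, Interpolant) else Interpolant(method)


# --------------------------------------------------------------------------- #
# point sampling
# --------------------------------------------------------------------------- #


def _nearest_indices(coords: np.ndarray) -> np.ndarray:
    # round to nearest with ties (x = k + 0.5) broken toward the lower index
    return np.ceil(coords - 0.5).astype(np.int64)


def _hann_sinc(x: np.ndarray, radius: int = SINC_HALFWIDTH) -> np.ndarray:
    w = np.sinc(x) * (0.5 + 0.5 * np.cos(np.pi * x / radius))
    w[np.abs(x) >= radius] = 0.0
    return w


def _sinc_sample(data: np.ndarray, pts: np.ndarray, fill: float,
                 edge_mode: str, chunk: int = 16384) -> np.ndarray:
    """Windowed-sinc gather at arbitrary voxel coordinates pts (3, N)."""
    r = SINC_HALFWIDTH
    pad_mode = "edge" if edge_mode == "nearest" else "constant"
    kw = {} if pad_mode == "edge" else {"constant_values": fill}
    padded = np.pad(data, r, mode=pad_mode, **kw)
    dims = np.array(data.shape)
    out = np.full(pts.shape[1], fill, float)
    inside = np.all((pts > -0.5) & (pts < dims[:, None] - 0.5), axis=0) \
        if edge_mode == "constant" else np.ones(pts.shape[1], bool)
    taps = np.arange(-r + 1, r + 1)
    p = pts[:, inside]
    base = np.floor(p).astype(np.int64)
    frac = p - base
    # per-axis weights, normalized to sum 1 (partition of unity)
    w = [_hann_sinc(taps[:, None] - frac[a][None, :]) for a in range(3)]
    w = [wa / wa.sum(axis=0, keepdims=True) for wa in w]
    n = p.shape[1]
    acc = np.zeros(n)
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        bx, by, bz = base[0, s:e] + r, base[1, s:e] + r, base[2, s:e] + r
        a = np.zeros(e - s)
        for i, ti in enumerate(taps):
            wx = w[0][i, s:e]
            px = padded[bx + ti]
            for j, tj in enumerate(taps):
                wxy = wx * w[1][j, s:e]
                pxy = px[np.arange(e - s), by + tj]
                for k, tk in enumerate(taps):
                    a += wxy * w[2][k, s:e] * pxy[np.arange(e - s), bz + tk]
        acc[s:e] = a
    out[inside] = acc
    return out


def sample_volume(data: np.ndarray, coords, method="linear", fill: float = 0.0,
                  edge_mode: str = "constant") -> np.ndarray:
    """Sample a 3D array at fractional voxel coordinates.

    Parameters
    ----------
    data : 3D array.
    coords : (..., 3) voxel coordinates (0-based, voxel centers at integers).
    method : interpolant name or :class:`Interpolant`.
    fill : value outside the field of view (``edge_mode="constant"``).
    edge_mode : "constant" or "nearest" (clamp at the border).
    """
    m = as_interpolant(method)
    coords = np.asarray(coords, float)
    pts = coords.reshape(-1, 3).T
    dims = np.array(data.shape)
    if m.name == "nearest":
        idx = _nearest_indices(pts)
        if edge_mode == "nearest":
            idx = np.clip(idx, 0, (dims - 1)[:, None])
            out = data[tuple(idx)].astype(float)
        else:
            inside = np.all((idx >= 0) & (idx < dims[:, None]), axis=0)
            out = np.full(pts.shape[1], fill, float)
            out[inside] = data[tuple(idx[:, inside])]
    elif m.name == "sinc":
        out = _sinc_sample(np.asarray(data, float), pts, fill, edge_mode)
    else:
        out = ndimage.map_coordinates(
            data, pts, order=m.spline_order, mode=edge_mode,
            cval=fill, prefilter=m.spline_order > 1)
    return out.reshape(coords.shape[:-1])


# --------------------------------------------------------------------------- #
# grid resampling
# --------------------------------------------------------------------------- #


def _out_coords(src_grid: VoxelGrid, out_grid: VoxelGrid,
                world_map: np.ndarray | None = None) -> np.ndarray:
    """Source voxel coordinates of every out-grid voxel center, (N, 3)."""
    m = np.linalg.inv(src_grid.affine)
    if world_map is not None:
        m = m @ world_map
    m = m @ out_grid.affine
    idx = out_grid.voxel_centers()
    return idx @ m[:3, :3].T + m[:3, 3]


def upsample(v: Volume, factor, method="cubic") -> Volume:
    """Resample onto a finer grid covering the same field of view.

    The output spacing is input spacing / factor and the first output voxel
    center sits at the input center minus ``spacing_out * (factor - 1) / 2``,
    keeping the field of view centered.  Edges are clamped so a constant
    volume stays exactly constant.
    """
    f = np.atleast_1d(np.asarray(factor, int)) * np.ones(3, int)
    if np.any(f < 1):
        raise ValueError(f"upsampling factor must be >= 1, got {factor}")
    if np.all(f == 1):
        return Volume(v.grid, v.data.copy())
    out_dims = tuple(int(d * fi) for d, fi in zip(v.grid.dims, f))
    k = np.eye(4)
    k[:3, :3] = np.diag(1.0 / f)
    k[:3, 3] = -(f - 1) / (2.0 * f)
    out_grid = VoxelGrid(out_dims, v.grid.affine @ k)
    coords = _out_coords(v.grid, out_grid)  # == k applied to out indices
    m = as_interpolant(method)

    def one(frame):
        return sample_volume(frame, coords, m, edge_mode="nearest"
                             ).reshape(out_dims)

    out = v.map_frames(one)
    return Volume(out_grid, out)


def resample_rigid(v: Volume, t: RigidTransform, out_grid: VoxelGrid | None = None,
                   method="linear", fill: float = 0.0) -> Volume:
    """Apply a rigid transform to the image: ``out(x) = v(t^{-1} x)``.

    Output is sampled at ``out_grid`` voxel centers pulled back through the
    inverse transform; samples outside the source field of view get ``fill``.
    4D input is resampled frame-wise with the same transform.
    """
    out_grid = out_grid or v.grid
    coords = _out_coords(v.grid, out_grid, np.linalg.inv(t.matrix))
    m = as_interpolant(method)

    def one(frame):
        return sample_volume(frame, coords, m, fill=fill).reshape(out_grid.dims)

    out = v.map_frames(one)
    return Volume(out_grid, out)


# --------------------------------------------------------------------------- #
# fast separable path for pure translations
# --------------------------------------------------------------------------- #


def _shift_kernel_1d(shift: float, method: Interpolant) -> tuple[np.ndarray, int]:
    """Taps and integer offset such that out(i) = sum_k w[k] in(i - off - k).

    For the spline methods the taps apply to *prefiltered* coefficients
    (B-spline basis values); for the others they apply to the data itself.
    """
    n = int(np.floor(shift))
    f = shift - n
    if method.name == "nearest":
        # nearest source of i - shift, ties toward the lower index
        off = int(np.ceil(shift - 0.5))
        return np.array([1.0]), off
    if method.name == "linear":
        if f == 0:
            return np.array([1.0]), n
        return np.array([1 - f, f]), n
    if method.name == "sinc":
        r = SINC_HALFWIDTH
        t = np.arange(-r + 1, r + 1)
        w = _hann_sinc(t - f)
        w /= w.sum()
        return w, n + t[0]
    # cubic / quintic: B-spline basis sampled at (t - f) via an impulse
    order = method.spline_order
    half = order // 2 + 1
    imp = np.zeros(4 * half + 1)
    imp[2 * half] = 1.0
    resp = ndimage.shift(imp, f, order=order, prefilter=False, mode="constant")
    t = np.arange(-half, half + 1)
    w = resp[2 * half + t]
    nz = np.abs(w) > 1e-15
    return w[nz], n + int(t[nz][0])


def _apply_shift_axis(data: np.ndarray, w: np.ndarray, off: int, axis: int,
                      fill: float) -> np.ndarray:
    """out(i) = sum_k w[k] * in(i - off - k) along one axis, constant fill."""
    n = data.shape[axis]
    out = np.zeros_like(data, dtype=float)
    for k, wk in enumerate(w):
        s = off + k  # out(i) += wk * in(i - s)
        if abs(s) >= n:
            out += wk * fill
            continue
        src = [slice(None)] * data.ndim
        dst = [slice(None)] * data.ndim
        if s >= 0:
            src[axis] = slice(0, n - s)
            dst[axis] = slice(s, n)
        else:
            src[axis] = slice(-s, n)
            dst[axis] = slice(0, n + s)
        shifted = np.full_like(data, fill, dtype=float)
        shifted[tuple(dst)] = data[tuple(src)]
        out += wk * shifted
    return out


def translate_volume(v: Volume, shift_mm, method="linear", fill: float = 0.0) -> Volume:
    """Translate the image content by ``shift_mm`` (world mm) on its own grid.

    Separable fast path equivalent to :func:`resample_rigid` with a pure
    translation; 4D series are shifted with a single pass over all frames.
    """
    if not v.grid.is_axis_aligned():
        raise ValueError("translate_volume requires an axis-aligned grid")
    m = as_interpolant(method)
    shift_vox = np.asarray(shift_mm, float) / v.grid.spacing
    data = np.asarray(v.data, float)
    out = data
    if m.spline_order is not None and m.spline_order > 1:
        # prefilter the spatial axes once, then convolve with basis taps
        for axis in range(3):
            out = ndimage.spline_filter1d(out, order=m.spline_order,
                                          axis=axis, mode="mirror")
    for axis in range(3):
        w, off = _shift_kernel_1d(shift_vox[axis], m)
        out = _apply_shift_axis(out, w, off, axis, fill)
    return Volume(v.grid, out)


# --------------------------------------------------------------------------- #
# composition and motion correction
# --------------------------------------------------------------------------- #


def compose_transforms(chain) -> RigidTransform:
    """Compose rigid transforms in application order (chain[0] applied first)."""
    chain = list(chain)
    if not chain:
        raise ValueError("cannot compose an empty transform chain")
    m = np.eye(4)
    for t in chain:
        m = t.matrix @ m
    return rigid_from_matrix(m, chain[0].center)


def motion_correct(series: Volume, trace, method="linear",
                   upsample_factor: int = 1, upsample_method="cubic",
                   fill: float = 0.0) -> Volume:
    """Resample every frame into the reference frame's grid.

    ``trace.transforms[t]`` is the rigid motion of the head at frame t
    relative to the reference frame, so correction resamples frame t through
    its inverse.  With ``upsample_factor > 1`` the series is first upsampled
    (the anti-blur strategy of working on a finer grid), and the correction
    transforms — computed on the native grid — are applied on that grid.
    """
    if not series.is4d:
        raise ValueError("motion_correct expects a 4D series")
    if len(trace.transforms) != series.nframes:
        raise ValueError(
            f"trace length {len(trace.transforms)} != frame count {series.nframes}")
    work = upsample(series, upsample_factor, upsample_method) \
        if upsample_factor > 1 else series
    out = np.empty(work.grid.dims + (work.nframes,), float)
    for t, transform in enumerate(trace.transforms):
        frame = Volume(work.grid, work.frame(t))
        if transform.is_identity(tol=1e-12):
            out[..., t] = frame.data
        else:
            out[..., t] = resample_rigid(
                frame, transform.inverse(), work.grid, method, fill).data
    return Volume(work.grid, out)
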