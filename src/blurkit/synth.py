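"""Synthetic fixtures: folded cortical sheets, stripe phantoms, BOLD runs,
motion traces and smooth structured phantoms.

Everything a blur evaluation needs can be generated here with no external
data: a two-boundary (white/pial) folded cortical sheet mesh, disjoint
interdigitated stripe labelings standing in for the V2 thin/thick column
systems, forward-modeled block-design BOLD runs with gamma-HRF responses,
rigid motion traces, and smooth Gaussian-blob phantoms for motion
estimation experiments.  All randomness is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .imgcore import MotionTrace, VoxelGrid, Volume
from .resample import resample_rigid
from .surface import SurfaceMap, TriangleMesh

__all__ = [
    "CorticalSheetSpec",
    "StripeSpec",
    "make_cortical_sheet",
    "make_stripe_phantom",
    "make_bold_run",
    "make_motion_trace",
    "make_smooth_phantom",
]


@dataclass(frozen=True)
class CorticalSheetSpec:
    """Geometry of a synthetic folded cortical patch.

    ``extent`` is the square patch side in mm; ``mean_vertex_spacing`` the
    target mean edge length; folds are sinusoidal with the given amplitude
    and wavelength; ``thickness`` separates white and pial along the white
    surface normal.
    """

    extent: float = 40.0
    mean_vertex_spacing: float = 1.0
    fold_amplitude: float = 2.5
    fold_wavelength: float = 25.0
    thickness: float = 2.0

    def __post_init__(self):
        if self.mean_vertex_spacing <= 0 or self.thickness <= 0:
            raise ValueError("spacing and thickness must be positive")
        if self.mean_vertex_spacing > self.extent:
            raise ValueError("vertex spacing larger than the sheet extent")


@dataclass(frozen=True)
class StripeSpec:
    """Interdigitated two-system stripe pattern on the sheet.

    Stripes of width ``stripe_width`` for each system alternate along
    ``orientation`` (a 2D direction in the sheet plane) with unlabeled gaps
    occupying ``gap_fraction`` of each period.
    """

    stripe_width: float = 4.0
    gap_fraction: float = 0.2
    orientation: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self):
        if not 0 <= self.gap_fraction < 1:
            raise ValueError("gap_fraction must be in [0, 1)")
        if self.stripe_width <= 0:
            raise ValueError("stripe_width must be positive")


def make_cortical_sheet(spec: CorticalSheetSpec, seed: int = 0
                        ) -> tuple[TriangleMesh, TriangleMesh]:
    """Folded triangulated sheet: returns ``(white, pial)`` sharing topology.

    Vertices sit on a staggered (near-equilateral) lattice so the mean edge
    length tracks ``mean_vertex_spacing``; the sheet is folded as
    ``z = A sin(2 pi x / L) cos(2 pi y / L)`` and the pial surface is offset
    from white by ``thickness`` along the vertex normals.  The patch is an
    open (bordered) mesh centered on the world origin.
    """
    h = spec.mean_vertex_spacing
    nx = max(2, int(round(spec.extent / h)) + 1)
    row_step = h * np.sqrt(3) / 2.0
    ny = max(2, int(round(spec.extent / row_step)) + 1)
    xs = np.arange(nx) * h
    ys = np.arange(ny) * row_step
    vx = np.empty((ny, nx))
    vy = np.empty((ny, nx))
    for j in range(ny):
        vx[j] = xs + (0.5 * h if j % 2 else 0.0)
        vy[j] = ys[j]
    vx -= vx.mean()
    vy -= vy.mean()
    if spec.fold_amplitude != 0:
        k = 2 * np.pi / spec.fold_wavelength
        vz = spec.fold_amplitude * np.sin(k * vx) * np.cos(k * vy)
    else:
        vz = np.zeros_like(vx)
    verts = np.column_stack([vx.ravel(), vy.ravel(), vz.ravel()])

    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            b = a + 1
            c = a + nx
            d = c + 1
            if j % 2 == 0:
                faces.append((a, b, c))
                faces.append((b, d, c))
            else:
                faces.append((a, b, d))
                faces.append((a, d, c))
    white = TriangleMesh(verts, np.asarray(faces))
    normals = white.vertex_normals()
    # orient consistently toward +z
    if np.mean(normals[:, 2]) < 0:
        normals = -normals
    pial = TriangleMesh(verts + spec.thickness * normals, white.faces)
    return white, pial


def make_stripe_phantom(sheet: TriangleMesh, spec: StripeSpec
                        ) -> tuple[SurfaceMap, SurfaceMap]:
    """Two disjoint ground-truth stripe masks on the sheet.

    One period along the stripe orientation holds system-A stripe, gap,
    system-B stripe, gap; the masks never overlap by construction
    (Dice = 0 exactly).  Labeling is a pure function of the in-plane vertex
    coordinates, so a refined sheet gets a consistent labeling.
    """
    mean_edge = sheet.mean_edge_length()
    if spec.stripe_width < mean_edge:
        raise ValueError("stripe_width must be at least the vertex spacing")
    u = np.asarray(spec.orientation, float)
    u = u / np.linalg.norm(u)
    coord = sheet.vertices[:, 0] * u[0] + sheet.vertices[:, 1] * u[1]
    w = spec.stripe_width
    period = 2.0 * w / (1.0 - spec.gap_fraction)
    t = np.mod(coord - coord.min(), period)
    a = t < w
    b = (t >= period / 2.0) & (t < period / 2.0 + w)
    return (SurfaceMap(a, sheet, {"system": "thin"}),
            SurfaceMap(b, sheet, {"system": "thick"}))


def _boxcar_regressor(design, hrf_kernel: np.ndarray, dt: float) -> np.ndarray:
    """Boxcar ⊗ HRF sampled at the design's frame times."""
    t_end = float(design.frame_times[-1]) + design.TR
    n_hi = int(np.ceil(t_end / dt)) + len(hrf_kernel)
    stim = np.zeros(n_hi)
    for onset, dur in zip(design.condition_onsets, design.condition_durations):
        i0 = int(round(onset / dt))
        i1 = int(round((onset + dur) / dt))
        stim[i0:i1] = 1.0
    conv = np.convolve(stim, hrf_kernel)[:n_hi] * dt
    idx = np.round(np.asarray(design.frame_times) / dt).astype(int)
    return conv[idx]


def make_bold_run(white: TriangleMesh, pial: TriangleMesh, truth: SurfaceMap,
                  grid: VoxelGrid, design, hrf, amplitude: float = 2.0,
                  noise_sd: float = 1.0, trace: MotionTrace | None = None,
                  baseline: float = 100.0, seed: int = 0,
                  motion_method: str = "linear") -> Volume:
    """Forward-model a block-design BOLD run on a voxel grid.

    A voxel belongs to the active cortical ribbon when its center lies
    within ``thickness / 2`` of a truth-labeled mid-surface vertex.  Its
    time series is ``baseline + amplitude * (boxcar ⊗ HRF)(t)``, everything
    else sits at ``baseline``; each frame is then rigidly moved by the
    motion trace and i.i.d. Gaussian noise of ``noise_sd`` is added
    (scanner noise enters after head motion).  ``amplitude`` is in percent
    signal change relative to baseline.
    """
    from .stripemap import gamma_hrf  # local import; stripemap imports us

    rng = np.random.default_rng(seed)
    mid = 0.5 * (white.vertices + pial.vertices)
    thickness = float(np.mean(np.linalg.norm(pial.vertices - white.vertices,
                                             axis=1)))
    labeled = mid[np.asarray(truth.values, bool)]
    if len(labeled) == 0:
        raise ValueError("truth map labels no vertices")
    centers = grid.voxel_to_world(grid.voxel_centers())
    lo, hi = centers.min(axis=0), centers.max(axis=0)
    if np.any(mid.min(axis=0) < lo - thickness) \
            or np.any(mid.max(axis=0) > hi + thickness):
        raise ValueError("voxel grid does not cover the cortical sheet")
    tree = cKDTree(labeled)
    d, _ = tree.query(centers, k=1)
    indicator = (d <= thickness / 2.0).astype(float).reshape(grid.dims)

    dt = 0.1
    kernel = gamma_hrf(hrf, dt=dt)
    reg = _boxcar_regressor(design, kernel, dt)
    nframes = len(reg)
    signal_amp = baseline * amplitude / 100.0

    out = np.empty(grid.dims + (nframes,), float)
    static = baseline + np.zeros(grid.dims)
    for t in range(nframes):
        frame = static + signal_amp * indicator * reg[t]
        if trace is not None and not trace.transforms[t].is_identity(1e-12):
            frame = resample_rigid(Volume(grid, frame), trace.transforms[t],
                                   grid, motion_method, fill=baseline).data
        out[..., t] = frame
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, out.shape)
    return Volume(grid, out)


def make_motion_trace(nframes: int, amplitudes=None, style: str = "sinusoidal",
                      seed: int = 0, cycles: int = 2,
                      center=(0.0, 0.0, 0.0)) -> MotionTrace:
    """Rigid motion trace with the middle frame as the identity reference.

    ``amplitudes`` bounds each of the six parameters (deg for rotations, mm
    for displacements); excursions are scaled so the largest sampled value
    of each parameter equals its amplitude exactly.  Styles: ``sinusoidal``
    (one random-phase sinusoid per parameter, zero at the reference frame)
    or ``random-walk`` (cumulative Gaussian steps re-referenced to the
    middle frame and rescaled to the bound).
    """
    if nframes < 1:
        raise ValueError("nframes must be >= 1")
    if amplitudes is None:
        amplitudes = (0.3, 0.3, 0.3, 0.5, 0.5, 0.5)
    amplitudes = np.asarray(amplitudes, float)
    rng = np.random.default_rng(seed)
    ref = nframes // 2
    t = np.arange(nframes)
    params = np.zeros((nframes, 6))
    for p in range(6):
        if amplitudes[p] == 0 or nframes == 1:
            continue
        if style == "sinusoidal":
            c = cycles + rng.integers(0, 2)
            phi = rng.uniform(0, 2 * np.pi)
            # zero at the reference frame by construction
            s = np.sin(2 * np.pi * c * (t - ref) / nframes + phi) - np.sin(phi)
        elif style == "random-walk":
            s = np.cumsum(rng.normal(size=nframes))
            s = s - s[ref]
        else:
            raise ValueError(f"unknown motion style {style!r}")
        peak = np.max(np.abs(s))
        if peak > 0:
            params[:, p] = amplitudes[p] * s / peak
    params[ref] = 0.0
    return MotionTrace.from_params(params, ref, center)


def make_smooth_phantom(grid: VoxelGrid, n_blobs: int = 15, seed: int = 0
                        ) -> Volume:
    """Sum of anisotropic Gaussian blobs — a smooth structured image with
    nonzero gradients over most of the field of view, for motion tests."""
    if n_blobs < 1:
        raise ValueError("n_blobs must be >= 1")
    rng = np.random.default_rng(seed)
    centers_vox = grid.voxel_to_world(grid.voxel_centers())
    fov_lo, fov_hi = centers_vox.min(axis=0), centers_vox.max(axis=0)
    span = fov_hi - fov_lo
    data = np.zeros(len(centers_vox))
    for b in range(n_blobs):
        if b == 0:
            c = grid.center_world  # anchor structure at the rotation center
            widths = np.full(3, 5.0)
            amp = 1.0
        else:
            c = fov_lo + span * (0.1 + 0.8 * rng.random(3))
            widths = 3.0 + 5.0 * rng.random(3)  # mm
            amp = 0.5 + 0.5 * rng.random()
        d = (centers_vox - c) / widths
        data += amp * np.exp(-0.5 * np.sum(d * d, axis=1))
    return Volume(grid, data.reshape(grid.dims))
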