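"""Siddon ray-traced forward projection.

For every detector pixel a ray is cast from the source through the pixel
center and the exact intersection length with each voxel (an axis-aligned
box of side ``voxel_size`` centered on the voxel center) is accumulated,
weighted by the voxel value.  This is exact for piecewise-constant
volumes, so a binary metal mask yields metal path lengths in millimetres.

Three traversal modes share one incremental Siddon kernel:

* ``sum``  — line integral (path-length / DRR images),
* ``max``  — maximum voxel value along the ray (overlay projection),
* ``label``— per-material path lengths from a label volume.

Rays are parameterized from the source; half-open parametric intervals
resolve boundary ties, attributing a grazed face to the voxel the ray
enters.  Kernels are compiled with numba (cached); the wrappers do the
geometry bookkeeping in numpy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit, prange

from .geometry import Trajectory, ViewGeometry, decompose_view
from .phantoms import AttenuationVolume, MetalMask, VoxelGrid

__all__ = [
    "PathLengthImage",
    "PathLengthStack",
    "siddon_path_length",
    "project_trajectory",
    "project_materials",
    "max_project_volume",
]


@dataclass(frozen=True)
class PathLengthImage:
    """(n_u, n_v) map of intersected material (mm) for one view."""

    values: np.ndarray
    view: ViewGeometry

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))


@dataclass(frozen=True)
class PathLengthStack:
    """One path-length image per view of a trajectory, order preserved.

    ``values`` has shape (n_views, n_u, n_v)."""

    values: np.ndarray
    trajectory: Trajectory

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape[0] != self.trajectory.n_views:
            raise ValueError("stack must hold one image per view")
        object.__setattr__(self, "values", v)

    def __getitem__(self, i: int) -> PathLengthImage:
        return PathLengthImage(self.values[i], self.trajectory[i])

    def __len__(self) -> int:
        return self.values.shape[0]


@njit(cache=True, inline="always")
def _trace_ray(vol, lo0, lo1, lo2, vox, sx, sy, sz, dx, dy, dz, mode, out_mat, pix_u, pix_v):
    """Traverse one ray through the grid.  Returns the 'sum' or 'max' result;
    in label mode accumulates per-material lengths into out_mat[:, pix_u, pix_v]."""
    n0, n1, n2 = vol.shape
    hi0 = lo0 + vox * n0
    hi1 = lo1 + vox * n1
    hi2 = lo2 + vox * n2

    tmin = 0.0
    tmax = 1e30
    # slab intersection per axis
    for axis in range(3):
        if axis == 0:
            s, d, lo, hi = sx, dx, lo0, hi0
        elif axis == 1:
            s, d, lo, hi = sy, dy, lo1, hi1
        else:
            s, d, lo, hi = sz, dz, lo2, hi2
        if abs(d) < 1e-12:
            if s < lo or s > hi:
                return 0.0
        else:
            t0 = (lo - s) / d
            t1 = (hi - s) / d
            if t0 > t1:
                t0, t1 = t1, t0
            if t0 > tmin:
                tmin = t0
            if t1 < tmax:
                tmax = t1
    if tmax <= tmin:
        return 0.0

    eps = 1e-9
    # entry point, nudged inside
    t = tmin
    px = sx + (t + eps) * dx
    py = sy + (t + eps) * dy
    pz = sz + (t + eps) * dz
    i0 = int((px - lo0) / vox)
    i1 = int((py - lo1) / vox)
    i2 = int((pz - lo2) / vox)
    if i0 < 0:
        i0 = 0
    if i1 < 0:
        i1 = 0
    if i2 < 0:
        i2 = 0
    if i0 > n0 - 1:
        i0 = n0 - 1
    if i1 > n1 - 1:
        i1 = n1 - 1
    if i2 > n2 - 1:
        i2 = n2 - 1

    step0 = 1 if dx > 0 else -1
    step1 = 1 if dy > 0 else -1
    step2 = 1 if dz > 0 else -1
    big = 1e30
    if abs(dx) > 1e-12:
        tdelta0 = vox / abs(dx)
        nxt = lo0 + (i0 + (1 if dx > 0 else 0)) * vox
        tnext0 = (nxt - sx) / dx
    else:
        tdelta0 = big
        tnext0 = big
    if abs(dy) > 1e-12:
        tdelta1 = vox / abs(dy)
        nxt = lo1 + (i1 + (1 if dy > 0 else 0)) * vox
        tnext1 = (nxt - sy) / dy
    else:
        tdelta1 = big
        tnext1 = big
    if abs(dz) > 1e-12:
        tdelta2 = vox / abs(dz)
        nxt = lo2 + (i2 + (1 if dz > 0 else 0)) * vox
        tnext2 = (nxt - sz) / dz
    else:
        tdelta2 = big
        tnext2 = big

    dlen = (dx * dx + dy * dy + dz * dz) ** 0.5
    acc = 0.0
    t = tmin
    while t < tmax - 1e-12:
        # next crossing
        if tnext0 <= tnext1 and tnext0 <= tnext2:
            tn = tnext0
            ax = 0
        elif tnext1 <= tnext2:
            tn = tnext1
            ax = 1
        else:
            tn = tnext2
            ax = 2
        if tn > tmax:
            tn = tmax
        seg = (tn - t) * dlen
        if seg > 0.0:
            val = vol[i0, i1, i2]
            if mode == 0:  # line integral
                acc += seg * val
            elif mode == 1:  # max projection
                if val > acc:
                    acc = val
            else:  # label mode: accumulate per material
                out_mat[int(val), pix_u, pix_v] += seg
        t = tn
        if ax == 0:
            i0 += step0
            tnext0 += tdelta0
            if i0 < 0 or i0 >= n0:
                break
        elif ax == 1:
            i1 += step1
            tnext1 += tdelta1
            if i1 < 0 or i1 >= n1:
                break
        else:
            i2 += step2
            tnext2 += tdelta2
            if i2 < 0 or i2 >= n2:
                break
    return acc


@njit(cache=True, parallel=False)
def _project_view(vol, lo0, lo1, lo2, vox, src, ray_mat, n_u, n_v, mode, out, out_mat):
    for iu in prange(n_u):
        for iv in range(n_v):
            dx = ray_mat[0, 0] * iu + ray_mat[0, 1] * iv + ray_mat[0, 2]
            dy = ray_mat[1, 0] * iu + ray_mat[1, 1] * iv + ray_mat[1, 2]
            dz = ray_mat[2, 0] * iu + ray_mat[2, 1] * iv + ray_mat[2, 2]
            r = _trace_ray(
                vol, lo0, lo1, lo2, vox, src[0], src[1], src[2], dx, dy, dz, mode, out_mat, iu, iv
            )
            if mode != 2:
                out[iu, iv] = r


def _ray_matrix(view: ViewGeometry) -> np.ndarray:
    """3x3 matrix mapping homogeneous pixel (u, v, 1) to a world ray direction."""
    K, R, _ = decompose_view(view)
    return R.T @ np.linalg.inv(K)


def _volume_array(volume) -> tuple[np.ndarray, VoxelGrid]:
    if isinstance(volume, MetalMask):
        return volume.values.astype(np.float64), volume.grid
    if isinstance(volume, AttenuationVolume):
        return volume.labels.astype(np.float64), volume.grid
    if hasattr(volume, "values") and hasattr(volume, "grid"):
        return np.asarray(volume.values, dtype=np.float64), volume.grid
    raise TypeError("expected a MetalMask, AttenuationVolume or (grid, values) volume")


def _check_source_outside(grid: VoxelGrid, view: ViewGeometry) -> None:
    lo, hi = grid.bounds
    s = view.source_position
    if np.all(s >= lo) and np.all(s <= hi):
        raise ValueError("unsupported geometry: source inside the volume bounding box")


def _run_view(arr, grid: VoxelGrid, view: ViewGeometry, mode: int, n_materials: int = 0):
    _check_source_outside(grid, view)
    lo, _ = grid.bounds
    det = view.detector
    out = np.zeros((det.n_u, det.n_v), dtype=np.float64)
    out_mat = np.zeros((max(n_materials, 1), det.n_u, det.n_v), dtype=np.float64)
    _project_view(
        arr,
        lo[0],
        lo[1],
        lo[2],
        grid.voxel_size,
        view.source_position.astype(np.float64),
        _ray_matrix(view).astype(np.float64),
        det.n_u,
        det.n_v,
        mode,
        out,
        out_mat,
    )
    return out_mat if mode == 2 else out


def siddon_path_length(volume, view: ViewGeometry) -> PathLengthImage:
    """Exact line-integral image of ``volume`` for one view.

    For a binary metal mask the result is the metal path length (mm) per
    detector pixel; for a float volume it is the line integral of the
    voxel values."""
    arr, grid = _volume_array(volume)
    return PathLengthImage(_run_view(arr, grid, view, mode=0), view)


def project_trajectory(volume, trajectory: Trajectory) -> PathLengthStack:
    """Path-length image for every view of a trajectory (pipeline step L1)."""
    arr, grid = _volume_array(volume)
    det = trajectory.detector
    out = np.zeros((trajectory.n_views, det.n_u, det.n_v), dtype=np.float64)
    for i, view in enumerate(trajectory):
        out[i] = _run_view(arr, grid, view, mode=0)
    return PathLengthStack(out, trajectory)


def project_materials(scene: AttenuationVolume, trajectory: Trajectory) -> dict[str, np.ndarray]:
    """Per-material path-length stacks (mm) through a label scene.

    Returns a dict mapping material name to an (n_views, n_u, n_v) array;
    air is omitted.  One traversal per ray accumulates all materials."""
    from .phantoms import MATERIALS

    arr = scene.labels.astype(np.float64)
    det = trajectory.detector
    n_mat = len(MATERIALS)
    stacks = np.zeros((trajectory.n_views, n_mat, det.n_u, det.n_v), dtype=np.float64)
    for i, view in enumerate(trajectory):
        stacks[i] = _run_view(arr, scene.grid, view, mode=2, n_materials=n_mat)
    return {
        name: np.ascontiguousarray(stacks[:, code])
        for name, code in MATERIALS.items()
        if name != "air"
    }


def max_project_volume(values: np.ndarray, grid: VoxelGrid, view: ViewGeometry) -> np.ndarray:
    """Maximum voxel value along each detector ray (pipeline step L4)."""
    return _run_view(np.asarray(values, dtype=np.float64), grid, view, mode=1)


def save_stack(path, stack: PathLengthStack | np.ndarray) -> None:
    """Export a projection stack for inspection as multi-page TIFF (.tif)
    or 3D MetaImage (.mhd)."""
    from pathlib import Path

    path = Path(path)
    arr = np.asarray(getattr(stack, "values", stack), dtype=np.float32)
    if path.suffix in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, arr)
    elif path.suffix == ".mhd":
        import SimpleITK as sitk

        sitk.WriteImage(sitk.GetImageFromArray(arr), str(path))
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")
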