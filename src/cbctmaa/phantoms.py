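"""Synthetic voxel phantoms: titanium calibration wedge, pedicle screws,
and a simple soft-tissue/vertebra scene.

All solids are rasterized by a voxel-center-in-solid test on a metric,
isocenter-centered grid, so every mask is reproducible bit-exactly from
its spec.  Masks are binary uint8; attenuation scenes carry a material
label per voxel (air / soft tissue / bone / titanium).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "VoxelGrid",
    "MetalMask",
    "AttenuationVolume",
    "ScrewSpec",
    "MATERIALS",
    "make_wedge_mask",
    "wedge_slice_height",
    "make_screw_mask",
    "make_spine_scene",
    "save_volume",
    "load_mask",
    "load_attenuation",
]

# Material label codes used throughout the package.
MATERIALS = {"air": 0, "soft_tissue": 1, "bone": 2, "titanium": 3}

DEFAULT_GRID_SHAPE = (128, 128, 128)
DEFAULT_VOXEL_MM = 1.2

# Full-scale titanium calibration wedge: 50 mm height ramp x 150 mm length x 5 mm width.
WEDGE_MAX_HEIGHT_MM = 50.0
WEDGE_LENGTH_MM = 150.0
WEDGE_WIDTH_MM = 5.0

DEFAULT_SCREW_DIAMETER_MM = 4.5


@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic metric voxel grid.  ``origin`` is the world position (mm) of
    the center of voxel (0, 0, 0); by default the grid is centered on the
    isocenter."""

    shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    voxel_size: float = DEFAULT_VOXEL_MM
    origin: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be > 0")
        if self.origin is None:
            o = tuple(-(n - 1) / 2.0 * self.voxel_size for n in self.shape)
            object.__setattr__(self, "origin", o)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_size for n in self.shape)

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.voxel_size * np.arange(self.shape[axis])

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2), indexing="ij"
        )

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """World positions (N, 3) of voxel index triples (N, 3)."""
        return np.asarray(self.origin) + self.voxel_size * np.asarray(indices, dtype=float)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin) - self.voxel_size / 2.0
        hi = lo + self.voxel_size * np.asarray(self.shape)
        return lo, hi


@dataclass(frozen=True)
class MetalMask:
    """Binary metal segmentation on a metric grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(self.values, dtype=np.uint8)
        if v.shape != tuple(self.grid.shape):
            raise ValueError("mask shape does not match grid")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask values must be binary")
        object.__setattr__(self, "values", v)

    @property
    def n_metal(self) -> int:
        return int(self.values.sum())

    def metal_indices(self) -> np.ndarray:
        return np.argwhere(self.values > 0)

    def union(self, other: "MetalMask") -> "MetalMask":
        if other.grid != self.grid:
            raise ValueError("masks must share a grid")
        return MetalMask(self.grid, np.maximum(self.values, other.values))


@dataclass(frozen=True)
class AttenuationVolume:
    """Material-label volume (codes from :data:`MATERIALS`) plus an optional
    per-voxel density scale, sharing a grid with any paired MetalMask."""

    grid: VoxelGrid
    labels: np.ndarray
    density_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        lab = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if lab.shape != tuple(self.grid.shape):
            raise ValueError("label volume shape does not match grid")
        if lab.max(initial=0) >= len(MATERIALS):
            raise ValueError("unknown material label")
        object.__setattr__(self, "labels", lab)
        if self.density_scale is not None:
            ds = np.ascontiguousarray(self.density_scale, dtype=np.float32)
            if ds.shape != lab.shape:
                raise ValueError("density scale shape does not match grid")
            object.__setattr__(self, "density_scale", ds)

    def metal_mask(self) -> MetalMask:
        return MetalMask(self.grid, (self.labels == MATERIALS["titanium"]).astype(np.uint8))

    def mu_volume(self, mu_by_label: dict[int, float]) -> np.ndarray:
        """Scalar attenuation volume (mm^-1) for given per-material mu."""
        out = np.zeros(self.labels.shape, dtype=np.float32)
        for lab, mu in mu_by_label.items():
            out[self.labels == lab] = mu
        if self.density_scale is not None:
            out *= self.density_scale
        return out


@dataclass(frozen=True)
class ScrewSpec:
    """Pedicle-screw-like capsule between head and tip."""

    head: tuple[float, float, float]
    tip: tuple[float, float, float]
    diameter: float = DEFAULT_SCREW_DIAMETER_MM

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("screw diameter must be > 0")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.tip, self.head)))

    @property
    def midpoint(self) -> np.ndarray:
        return (np.asarray(self.head) + np.asarray(self.tip)) / 2.0

    @property
    def axis(self) -> np.ndarray:
        d = np.subtract(self.tip, self.head)
        n = np.linalg.norm(d)
        return d / n if n > 0 else np.array([0.0, 0.0, 1.0])


def make_wedge_mask(
    grid: VoxelGrid,
    width: float = WEDGE_WIDTH_MM,
    length: float = WEDGE_LENGTH_MM,
    max_height: float = WEDGE_MAX_HEIGHT_MM,
    axis: int = 2,
) -> MetalMask:
    """Titanium calibration wedge: a triangular prism whose height ramps
    linearly from 0 to ``max_height`` along ``axis`` (default z).

    Default dimensions 50 x 150 x 5 mm: 5 mm wide, 150 mm long, with the
    height ramp reaching 50 mm.  The wedge is centered on the isocenter;
    the height direction is the next axis after ``axis`` (y for axis=z),
    the width direction the remaining one.
    """
    ax_len = axis
    ax_h = {0: 1, 1: 2, 2: 1}[axis]
    ax_w = ({0, 1, 2} - {ax_len, ax_h}).pop()
    ext = grid.extent_mm
    if length > ext[ax_len] or max_height > ext[ax_h] or width > ext[ax_w]:
        raise ValueError("wedge does not fit inside the grid extent")
    coords = grid.meshgrid()
    c_len, c_h, c_w = coords[ax_len], coords[ax_h], coords[ax_w]
    frac = (c_len + length / 2.0) / length  # 0 at thin end, 1 at tall end
    h = max_height * frac
    inside = (
        (frac >= 0)
        & (frac <= 1)
        & (np.abs(c_w) <= width / 2.0)
        & (c_h >= -max_height / 2.0)
        & (c_h <= -max_height / 2.0 + h)
    )
    return MetalMask(grid, inside.astype(np.uint8))


def wedge_slice_height(mask: MetalMask, slice_index: int, axis: int = 2, height_axis: int | None = None) -> float:
    """Local wedge height at one slice, measured from the mask as the metal
    extent along the height axis (voxel count x voxel size) — the in-image
    measurement a surgeon would make on the axial slice."""
    if height_axis is None:
        height_axis = {0: 1, 1: 2, 2: 1}[axis]
    sl = np.take(mask.values, slice_index, axis=axis)
    # after np.take the remaining axes keep their order
    rem = [a for a in range(3) if a != axis]
    h_ax = rem.index(height_axis)
    counts = sl.sum(axis=h_ax)
    return float(counts.max(initial=0)) * mask.grid.voxel_size


def _capsule_mask(grid: VoxelGrid, head: np.ndarray, tip: np.ndarray, radius: float) -> np.ndarray:
    X, Y, Z = grid.meshgrid()
    p = np.stack([X, Y, Z], axis=-1)
    d = tip - head
    L2 = float(d @ d)
    if L2 == 0:
        dist2 = ((p - head) ** 2).sum(axis=-1)
    else:
        t = np.clip(((p - head) @ d) / L2, 0.0, 1.0)
        closest = head + t[..., None] * d
        dist2 = ((p - closest) ** 2).sum(axis=-1)
    return (dist2 <= radius * radius).astype(np.uint8)


def make_screw_mask(grid: VoxelGrid, screw: ScrewSpec) -> MetalMask:
    """Voxelized capsule: a voxel is metal iff its center lies within the
    screw radius of the head-tip axis segment."""
    lo, hi = grid.bounds
    r = screw.diameter / 2.0
    for pnt in (screw.head, screw.tip):
        p = np.asarray(pnt, dtype=float)
        if np.any(p - r < lo) or np.any(p + r > hi):
            raise ValueError("screw extends outside the grid")
    vals = _capsule_mask(grid, np.asarray(screw.head, float), np.asarray(screw.tip, float), r)
    return MetalMask(grid, vals)


def make_spine_scene(
    grid: VoxelGrid,
    screws: list[ScrewSpec],
    body_halfaxes: tuple[float, float, float] = (90.0, 70.0, 120.0),
    bone_radius: float = 15.0,
    bone_center_y: float = 0.0,
) -> tuple[AttenuationVolume, MetalMask]:
    """Coarse lumbar-like scene: soft-tissue ellipsoid, a cylindrical bone
    column along z at ``(0, bone_center_y)``, and titanium screws.

    Material precedence: titanium over bone over soft tissue over air.
    The returned MetalMask contains the titanium voxels only.
    """
    X, Y, Z = grid.meshgrid()
    a, b, c = body_halfaxes
    labels = np.zeros(grid.shape, dtype=np.uint8)
    body = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    labels[body] = MATERIALS["soft_tissue"]
    bone = (X**2 + (Y - bone_center_y) ** 2 <= bone_radius**2) & body
    labels[bone] = MATERIALS["bone"]
    metal = np.zeros(grid.shape, dtype=np.uint8)
    for s in screws:
        m = make_screw_mask(grid, s).values
        if not (body | (m == 0)).all():
            raise ValueError("screw extends outside the body ellipsoid")
        metal = np.maximum(metal, m)
    labels[metal > 0] = MATERIALS["titanium"]
    return AttenuationVolume(grid, labels), MetalMask(grid, metal)


# ---------------------------------------------------------------------------
# Volume I/O (NIfTI via nibabel, MetaImage via SimpleITK)

def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4) * grid.voxel_size
    aff[3, 3] = 1.0
    aff[:3, 3] = grid.origin
    return aff


def save_volume(path: str | Path, grid: VoxelGrid, values: np.ndarray) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mhd) with the
    voxel size and origin recorded in the header.  Binary masks are written
    as uint8, everything else as float32."""
    path = Path(path)
    values = np.asarray(values)
    dtype = np.uint8 if values.dtype == np.uint8 else np.float32
    arr = np.ascontiguousarray(values, dtype=dtype)
    if path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        nib.save(nib.Nifti1Image(arr, _affine(grid)), str(path))
    elif path.suffix == ".mhd":
        img = sitk.GetImageFromArray(np.transpose(arr, (2, 1, 0)))
        img.SetSpacing((grid.voxel_size,) * 3)
        img.SetOrigin(tuple(grid.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def _load(path: Path) -> tuple[VoxelGrid, np.ndarray]:
    if path.suffix == ".mhd":
        img = sitk.ReadImage(str(path))
        arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        sp = img.GetSpacing()
        grid = VoxelGrid(shape=arr.shape, voxel_size=float(sp[0]), origin=tuple(img.GetOrigin()))
    else:
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj)
        aff = img.affine
        grid = VoxelGrid(shape=arr.shape, voxel_size=float(aff[0, 0]), origin=tuple(aff[:3, 3]))
    return grid, arr


def load_mask(path: str | Path) -> MetalMask:
    grid, arr = _load(Path(path))
    return MetalMask(grid, (arr > 0).astype(np.uint8))


def load_attenuation(path: str | Path) -> AttenuationVolume:
    grid, arr = _load(Path(path))
    return AttenuationVolume(grid, arr.astype(np.uint8))
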