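"""Metal-artifact-avoidance scoring and guidance.

Two complementary predictors are computed from a binary metal mask:

* **Global score** — one number per trajectory: the variance, across the
  trajectory's views, of the per-view mean spectral shift.  Evaluated on a
  tilt grid and min-max normalized it yields the 1D objective curve used
  to pick a tilt (0 = best, 1 = worst).

* **Voxel impact map** — for every metal voxel, the variance across views
  of the spectral shift sampled at the voxel's projected detector
  location.  This localizes the expected artifact strength in 3D and,
  after wedge calibration, maps to an absolute color scale.  The running
  variance is accumulated with Welford's online algorithm, vectorized
  over voxels.

A guidance overlay is the maximum projection of the impact map onto a
scout view, with colors normalized by the calibration constant; the task
recommender evaluates the impact map over a tilt grid and returns the
tilt minimizing the mean impact inside a clinical region of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import ScanProtocol, TiltGrid, Trajectory, ViewGeometry
from .phantoms import MetalMask, VoxelGrid
from .projector import PathLengthStack, max_project_volume, project_trajectory
from .spectral import MaterialAttenuation, Spectrum, material_attenuation, default_spectrum, shift_stack

logger = logging.getLogger(__name__)

__all__ = [
    "TiltScoreCurve",
    "VoxelImpactMap",
    "OverlayImage",
    "TaskROI",
    "WelfordAccumulator",
    "global_score",
    "score_curve",
    "voxel_impact_map",
    "render_overlay",
    "overlay_rgba",
    "recommend_tilt",
]


def _defaults(spectrum, material):
    if spectrum is None:
        spectrum = default_spectrum()
    if material is None:
        material = material_attenuation("titanium")
    return spectrum, material


class WelfordAccumulator:
    """Streaming mean/variance (Welford's online algorithm), vectorized:
    each element of the accumulator tracks its own sample stream and
    updates may address a subset of elements per step."""

    def __init__(self, n: int):
        self.count = np.zeros(n, dtype=np.int64)
        self.mean = np.zeros(n, dtype=np.float64)
        self.m2 = np.zeros(n, dtype=np.float64)

    def update(self, values: np.ndarray, where: np.ndarray | None = None) -> None:
        if where is None:
            where = np.ones(self.count.shape, dtype=bool)
        self.count[where] += 1
        delta = values - self.mean[where]
        self.mean[where] += delta / self.count[where]
        self.m2[where] += delta * (values - self.mean[where])

    def variance(self) -> np.ndarray:
        """Population (biased) variance; 0 where fewer than one sample."""
        out = np.zeros_like(self.mean)
        seen = self.count > 0
        out[seen] = self.m2[seen] / self.count[seen]
        return out


@dataclass(frozen=True)
class TiltScoreCurve:
    """Global-MAA objective over a tilt grid, raw and min-max normalized."""

    tilt_grid: TiltGrid
    raw: np.ndarray
    normalized: np.ndarray
    degenerate: bool = False  # all raw scores equal; normalized set to zero

    @property
    def best_tilt(self) -> float:
        i = int(np.argmin(self.normalized))
        ties = np.flatnonzero(self.normalized == self.normalized[i])
        angles = np.asarray(self.tilt_grid.angles)[ties]
        return float(angles[np.lexsort((angles, np.abs(angles)))[0]])


@dataclass(frozen=True)
class VoxelImpactMap:
    """Per-voxel predicted artifact strength (variance of spectral shift);
    zero outside the metal mask."""

    grid: VoxelGrid
    values: np.ndarray
    tilt: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != tuple(self.grid.shape):
            raise ValueError("impact map shape does not match grid")
        object.__setattr__(self, "values", v)

    def mean_in(self, roi_mask: np.ndarray) -> float:
        return float(self.values[roi_mask.astype(bool)].mean())


@dataclass(frozen=True)
class OverlayImage:
    """Scout-view guidance overlay: raw max-projected impact values and
    calibrated color values in [0, 1]."""

    values: np.ndarray
    color: np.ndarray
    scout: ViewGeometry
    c_crit: float


@dataclass(frozen=True)
class TaskROI:
    """Voxel mask marking the clinically relevant region (e.g. one screw)."""

    grid: VoxelGrid
    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask).astype(bool)
        if m.shape != tuple(self.grid.shape):
            raise ValueError("ROI shape does not match grid")
        if not m.any():
            raise ValueError("ROI must be non-empty")
        object.__setattr__(self, "mask", m)

    @classmethod
    def from_indices(cls, grid: VoxelGrid, indices: np.ndarray) -> "TaskROI":
        m = np.zeros(grid.shape, dtype=bool)
        idx = np.asarray(indices)
        m[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return cls(grid, m)


# ---------------------------------------------------------------------------
# Global-MAA

def global_score(
    metal: MetalMask,
    trajectory: Trajectory,
    spectrum: Spectrum | None = None,
    material: MaterialAttenuation | None = None,
    paths: PathLengthStack | None = None,
) -> float:
    """Variance across views of the per-view mean spectral shift.

    The mean is taken over all detector pixels (zeros included); the
    variance is the population variance, so a single-view trajectory
    scores exactly 0.
    """
    if metal.n_metal == 0:
        raise ValueError("metal mask is empty")
    spectrum, material = _defaults(spectrum, material)
    if paths is None:
        paths = project_trajectory(metal, trajectory)
    shifts = shift_stack(paths, spectrum, material)
    view_means = shifts.mean(axis=(1, 2))
    return float(np.var(view_means))


def score_curve(
    metal: MetalMask,
    tilt_grid: TiltGrid,
    protocol: ScanProtocol | None = None,
    spectrum: Spectrum | None = None,
    material: MaterialAttenuation | None = None,
) -> TiltScoreCurve:
    """Global-MAA objective Q(delta) over a tilt grid, min-max normalized
    relative to the worst and best trajectory in the evaluated range
    (0 = best / lowest variance, 1 = worst)."""
    if len(tilt_grid) == 0:
        raise ValueError("tilt grid is empty")
    protocol = protocol or ScanProtocol()
    raw = np.array(
        [
            global_score(metal, protocol.trajectory(t), spectrum, material)
            for t in tilt_grid
        ]
    )
    span = raw.max() - raw.min()
    if span <= 0:
        logger.warning("all tilt scores equal; normalized curve set to zero")
        return TiltScoreCurve(tilt_grid, raw, np.zeros_like(raw), degenerate=True)
    return TiltScoreCurve(tilt_grid, raw, (raw - raw.min()) / span)


# ---------------------------------------------------------------------------
# Local-MAA

def _bilinear_sample(img: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of img[(u, v)] for in-bounds continuous coords."""
    n_u, n_v = img.shape
    u0 = np.clip(np.floor(u).astype(np.int64), 0, n_u - 2)
    v0 = np.clip(np.floor(v).astype(np.int64), 0, n_v - 2)
    fu = u - u0
    fv = v - v0
    return (
        img[u0, v0] * (1 - fu) * (1 - fv)
        + img[u0 + 1, v0] * fu * (1 - fv)
        + img[u0, v0 + 1] * (1 - fu) * fv
        + img[u0 + 1, v0 + 1] * fu * fv
    )


def voxel_impact_map(
    metal: MetalMask,
    trajectory: Trajectory,
    shifts: np.ndarray | None = None,
    spectrum: Spectrum | None = None,
    material: MaterialAttenuation | None = None,
) -> VoxelImpactMap:
    """Per-voxel variance of the spectral shift at the voxel's projected
    detector locations (pipeline step L3).

    Every metal voxel center is forward-projected into each view, the
    spectral-shift image is sampled bilinearly at (u*, v*) and the variance
    across views is accumulated with Welford's online algorithm.  Views in
    which a voxel projects outside the detector are skipped for that voxel;
    a voxel visible in no view keeps value 0 (logged).
    """
    if metal.n_metal == 0:
        raise ValueError("metal mask is empty")
    spectrum, material = _defaults(spectrum, material)
    if shifts is None:
        shifts = shift_stack(project_trajectory(metal, trajectory), spectrum, material)
    shifts = np.asarray(shifts, dtype=np.float64)
    det = trajectory.detector
    idx = metal.metal_indices()
    centers = metal.grid.voxel_centers(idx)
    hom = np.hstack([centers, np.ones((centers.shape[0], 1))])
    acc = WelfordAccumulator(centers.shape[0])
    for i, view in enumerate(trajectory):
        uvw = hom @ view.P.T
        w = uvw[:, 2]
        valid = np.abs(w) > 1e-12
        u = np.where(valid, uvw[:, 0] / np.where(valid, w, 1.0), -1.0)
        v = np.where(valid, uvw[:, 1] / np.where(valid, w, 1.0), -1.0)
        inb = valid & (u >= 0) & (u <= det.n_u - 1) & (v >= 0) & (v <= det.n_v - 1)
        if not inb.any():
            continue
        samples = _bilinear_sample(shifts[i], u[inb], v[inb])
        acc.update(samples, inb)
    unseen = acc.count == 0
    if unseen.any():
        logger.warning("%d metal voxels project outside every view; impact set to 0", int(unseen.sum()))
    out = np.zeros(metal.grid.shape, dtype=np.float64)
    out[idx[:, 0], idx[:, 1], idx[:, 2]] = acc.variance()
    return VoxelImpactMap(metal.grid, out, trajectory.tilt)


def render_overlay(impact: VoxelImpactMap, scout: ViewGeometry, c_crit: float) -> OverlayImage:
    """Maximum projection of the impact map onto a scout view (step L4),
    with color values clipped to [0, 1] by the calibration constant."""
    if c_crit <= 0:
        raise ValueError("calibration constant must be positive")
    values = max_project_volume(impact.values, impact.grid, scout)
    color = np.clip(values / c_crit, 0.0, 1.0)
    return OverlayImage(values=values, color=color, scout=scout, c_crit=c_crit)


def overlay_rgba(overlay: OverlayImage, drr: np.ndarray | None = None) -> np.ndarray:
    """RGBA composition of an overlay: hue ramp blue (low) -> red (high),
    alpha proportional to the color value, optionally over a grayscale DRR."""
    from matplotlib.colors import hsv_to_rgb

    c = overlay.color
    hsv = np.stack([(1.0 - c) * 2.0 / 3.0, np.ones_like(c), np.ones_like(c)], axis=-1)
    rgb = hsv_to_rgb(hsv)
    alpha = c
    if drr is not None:
        bg = np.asarray(drr, dtype=float)
        if bg.max() > 0:
            bg = bg / bg.max()
        rgb = rgb * alpha[..., None] + bg[..., None] * (1 - alpha[..., None])
        alpha = np.ones_like(c)
    out = np.concatenate([rgb, alpha[..., None]], axis=-1)
    return (np.clip(out, 0, 1) * 255).astype(np.uint8)


def recommend_tilt(
    metal: MetalMask,
    tilt_grid: TiltGrid,
    roi: TaskROI,
    protocol: ScanProtocol | None = None,
    spectrum: Spectrum | None = None,
    material: MaterialAttenuation | None = None,
) -> tuple[float, np.ndarray]:
    """Task-conditioned tilt recommendation (the deterministic surrogate of
    the interactive overlay loop): evaluate the voxel impact map per grid
    tilt and return the tilt minimizing the mean impact inside the ROI,
    plus the full per-tilt ROI-mean curve.  Ties go to the smaller |tilt|.
    """
    if not (roi.mask & (metal.values > 0)).any():
        raise ValueError("ROI does not intersect the metal mask")
    protocol = protocol or ScanProtocol()
    roi_metal = roi.mask & (metal.values > 0)
    means = np.empty(len(tilt_grid))
    for k, tilt in enumerate(tilt_grid):
        imp = voxel_impact_map(metal, protocol.trajectory(tilt), spectrum=spectrum, material=material)
        means[k] = imp.values[roi_metal].mean()
    best = means.min()
    ties = np.flatnonzero(means == best)
    angles = np.asarray(tilt_grid.angles)[ties]
    order = np.lexsort((angles, np.abs(angles)))
    return float(angles[order[0]]), means
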