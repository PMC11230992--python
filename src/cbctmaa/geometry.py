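"""C-arm acquisition geometry for tilted circular CBCT orbits.

Conventions
-----------
World frame: right-handed, millimetres, origin at the isocenter.
``+z`` is the patient longitudinal (cranio-caudal) axis; the untilted
source orbit lies in the ``x``-``y`` plane.  A gantry tilt ``delta``
rotates the whole orbital plane about the world ``x`` axis (patient
left-right), which is the cranio-caudal C-arm tilt used for spine
imaging.

Detector frame: ``u`` runs along the rotation direction, ``v`` along the
tilt axis.  Pixel ``(0, 0)`` is the *center* of the corner pixel and
continuous detector coordinates are expressed in pixel units, so the
default principal point is ``((n_u - 1) / 2, (n_v - 1) / 2)``.

Each view is described by a 3x4 projection matrix ``P = K [R | t]``
mapping homogeneous world points (mm) to homogeneous detector pixels.
A trajectory is an ordered sequence of views sharing tilt and detector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import rq
from scipy.spatial.transform import Rotation, Slerp

__all__ = [
    "DetectorSpec",
    "ViewGeometry",
    "Trajectory",
    "TiltGrid",
    "ScanProtocol",
    "make_circular_trajectory",
    "project_point",
    "project_points",
    "decompose_view",
    "recompose",
    "interpolate_views",
    "enumerate_tilt_grid",
    "trajectory_to_json",
    "trajectory_from_json",
]

# Default scan protocol: a mobile C-arm short scan.  Detector 244^2 pixels
# at 1.3 mm pitch; 200 views over a 200 degree arc.  Source-isocenter and
# source-detector distances are typical mobile C-arm values.
DEFAULT_N_U = 244
DEFAULT_N_V = 244
DEFAULT_PIXEL_MM = 1.3
DEFAULT_N_VIEWS = 200
DEFAULT_ARC_DEG = 200.0
DEFAULT_SOURCE_ISO_MM = 600.0
DEFAULT_SOURCE_DET_MM = 1100.0


@dataclass(frozen=True)
class DetectorSpec:
    """Flat-panel detector: pixel counts, pitch (mm) and principal point (px)."""

    n_u: int = DEFAULT_N_U
    n_v: int = DEFAULT_N_V
    pixel_size_u: float = DEFAULT_PIXEL_MM
    pixel_size_v: float = DEFAULT_PIXEL_MM
    u0: float | None = None
    v0: float | None = None

    def __post_init__(self) -> None:
        if self.n_u < 1 or self.n_v < 1:
            raise ValueError("detector pixel counts must be >= 1")
        if self.pixel_size_u <= 0 or self.pixel_size_v <= 0:
            raise ValueError("detector pixel sizes must be > 0")
        if self.u0 is None:
            object.__setattr__(self, "u0", (self.n_u - 1) / 2.0)
        if self.v0 is None:
            object.__setattr__(self, "v0", (self.n_v - 1) / 2.0)

    @property
    def width_mm(self) -> float:
        return self.n_u * self.pixel_size_u

    @property
    def height_mm(self) -> float:
        return self.n_v * self.pixel_size_v


@dataclass(frozen=True)
class ViewGeometry:
    """One projection view: 3x4 matrix, source position, angles, detector."""

    P: np.ndarray
    source_position: np.ndarray
    tilt: float
    theta: float
    detector: DetectorSpec

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (3, 4):
            raise ValueError("projection matrix must be 3x4")
        if np.linalg.matrix_rank(P) != 3:
            raise ValueError("projection matrix must have rank 3")
        object.__setattr__(self, "P", P)
        object.__setattr__(
            self, "source_position", np.asarray(self.source_position, dtype=float)
        )

    @property
    def source_detector_distance(self) -> float:
        K, _, _ = decompose_view(self)
        return K[0, 0] * self.detector.pixel_size_u


@dataclass(frozen=True)
class Trajectory:
    """Ordered sequence of views sharing tilt, arc and detector."""

    views: tuple[ViewGeometry, ...]
    arc_degrees: float
    tilt: float

    def __post_init__(self) -> None:
        thetas = [v.theta for v in self.views]
        if any(b <= a for a, b in zip(thetas, thetas[1:])):
            raise ValueError("view rotation angles must be strictly increasing")

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def thetas(self) -> np.ndarray:
        return np.array([v.theta for v in self.views])

    @property
    def detector(self) -> DetectorSpec:
        return self.views[0].detector

    def __iter__(self):
        return iter(self.views)

    def __len__(self) -> int:
        return len(self.views)

    def __getitem__(self, i: int) -> ViewGeometry:
        return self.views[i]


@dataclass(frozen=True)
class TiltGrid:
    """Inclusive arithmetic grid of gantry tilts (degrees)."""

    delta_min: float
    delta_max: float
    step: float
    angles: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.angles:
            object.__setattr__(
                self,
                "angles",
                tuple(_inclusive_arange(self.delta_min, self.delta_max, self.step)),
            )

    def __iter__(self):
        return iter(self.angles)

    def __len__(self) -> int:
        return len(self.angles)


def _inclusive_arange(lo: float, hi: float, step: float) -> list[float]:
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return [lo + i * step for i in range(n)]


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _intrinsics(detector: DetectorSpec, source_det_dist: float) -> np.ndarray:
    return np.array(
        [
            [source_det_dist / detector.pixel_size_u, 0.0, detector.u0],
            [0.0, source_det_dist / detector.pixel_size_v, detector.v0],
            [0.0, 0.0, 1.0],
        ]
    )


def _view_at(
    theta: float,
    tilt: float,
    source_iso_dist: float,
    source_det_dist: float,
    detector: DetectorSpec,
) -> ViewGeometry:
    th = np.deg2rad(theta)
    # Untilted orbit in the x-y plane; theta = 0 is the AP view with the
    # source at (0, -SID, 0) looking along +y.
    source0 = np.array([-np.sin(th), -np.cos(th), 0.0]) * source_iso_dist
    e_u = np.array([-np.cos(th), np.sin(th), 0.0])  # rotation direction
    e_v = np.array([0.0, 0.0, 1.0])  # tilt axis
    e_w = np.array([np.sin(th), np.cos(th), 0.0])  # viewing direction
    R0 = np.vstack([e_u, e_v, e_w])  # world -> camera
    Rx = _rot_x(tilt)
    source = Rx @ source0
    R = R0 @ Rx.T
    t = -R @ source
    K = _intrinsics(detector, source_det_dist)
    P = K @ np.hstack([R, t[:, None]])
    return ViewGeometry(P=P, source_position=source, tilt=tilt, theta=theta, detector=detector)


def make_circular_trajectory(
    tilt: float = 0.0,
    n_views: int = DEFAULT_N_VIEWS,
    arc: float = DEFAULT_ARC_DEG,
    source_iso_dist: float = DEFAULT_SOURCE_ISO_MM,
    source_det_dist: float = DEFAULT_SOURCE_DET_MM,
    detector: DetectorSpec | None = None,
) -> Trajectory:
    """Build a tilted circular short-scan trajectory.

    The source travels on a circle of radius ``source_iso_dist`` in a plane
    rotated by ``tilt`` degrees about the world x axis.  Rotation angles are
    sampled symmetrically about the AP view:
    ``theta_i = -arc/2 + i * arc / (n_views - 1)``.

    The isocenter projects to the principal point in every view.
    """
    if n_views < 2:
        raise ValueError("a trajectory needs at least 2 views")
    if source_iso_dist <= 0 or source_det_dist <= 0:
        raise ValueError("distances must be positive")
    if source_det_dist <= source_iso_dist:
        raise ValueError("source-detector distance must exceed source-isocenter distance")
    if detector is None:
        detector = DetectorSpec()
    thetas = -arc / 2.0 + np.arange(n_views) * arc / (n_views - 1)
    views = tuple(
        _view_at(th, tilt, source_iso_dist, source_det_dist, detector) for th in thetas
    )
    return Trajectory(views=views, arc_degrees=arc, tilt=tilt)


def project_points(view: ViewGeometry, xyz: np.ndarray) -> np.ndarray:
    """Project an (N, 3) array of world points to (N, 2) pixel coordinates."""
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    hom = np.hstack([xyz, np.ones((xyz.shape[0], 1))])
    uvw = hom @ view.P.T
    w = uvw[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise ValueError("degenerate projection: point at the source position")
    return uvw[:, :2] / w[:, None]


def project_point(view: ViewGeometry, xyz: Sequence[float]) -> tuple[float, float]:
    """Project a single world point (mm) to continuous pixel coordinates."""
    uv = project_points(view, np.asarray(xyz, dtype=float)[None, :])[0]
    return float(uv[0]), float(uv[1])


def decompose_view(view: ViewGeometry | np.ndarray):
    """Split ``P`` into intrinsics ``K``, rotation ``R`` and translation ``t``.

    ``K`` is upper triangular with positive diagonal and ``K[2, 2] = 1``;
    ``R`` is a proper rotation; ``K [R | t]`` is proportional to ``P``.
    """
    P = view.P if isinstance(view, ViewGeometry) else np.asarray(view, dtype=float)
    M = P[:, :3]
    if np.linalg.matrix_rank(P) != 3:
        raise ValueError("cannot decompose a rank-deficient projection matrix")
    K, R = rq(M)  # K R = M exactly
    S = np.diag(np.sign(np.diag(K)))  # make diag(K) positive
    K = K @ S
    R = S @ R
    m = 1.0
    if np.linalg.det(R) < 0:  # the overall homogeneous scale of P is negative
        R = -R
        m = -1.0
    # Here K R = m * M.  Normalize K[2,2] = 1 and solve K t = (m / k22) P[:,3]
    # so that K [R | t] is proportional to P with a positive factor.
    k22 = K[2, 2]
    K = K / k22
    t = np.linalg.solve(K, (m / k22) * P[:, 3])
    return K, R, t


def recompose(K: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Assemble ``P = K [R | t]``."""
    return K @ np.hstack([R, np.asarray(t, dtype=float)[:, None]])


def interpolate_views(view_a: ViewGeometry, view_b: ViewGeometry, w: float) -> ViewGeometry:
    """Blend two calibrated views at fraction ``w`` in [0, 1].

    Intrinsics and translation are interpolated linearly; the rotation is
    interpolated on the rotation manifold (quaternion slerp of the relative
    rotation), then everything is recomposed into a valid view.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("interpolation fraction must lie in [0, 1]")
    Ka, Ra, ta = decompose_view(view_a)
    Kb, Rb, tb = decompose_view(view_b)
    K = (1 - w) * Ka + w * Kb
    t = (1 - w) * ta + w * tb
    slerp = Slerp([0.0, 1.0], Rotation.from_matrix(np.stack([Ra, Rb])))
    R = slerp(w).as_matrix()
    P = recompose(K, R, t)
    source = -R.T @ t
    return ViewGeometry(
        P=P,
        source_position=source,
        tilt=(1 - w) * view_a.tilt + w * view_b.tilt,
        theta=(1 - w) * view_a.theta + w * view_b.theta,
        detector=view_a.detector,
    )


@dataclass(frozen=True)
class ScanProtocol:
    """Scan configuration shared by all tilts of an optimization run."""

    n_views: int = DEFAULT_N_VIEWS
    arc_degrees: float = DEFAULT_ARC_DEG
    source_iso_dist: float = DEFAULT_SOURCE_ISO_MM
    source_det_dist: float = DEFAULT_SOURCE_DET_MM
    detector: DetectorSpec = field(default_factory=DetectorSpec)

    def trajectory(self, tilt: float) -> Trajectory:
        return make_circular_trajectory(
            tilt=tilt,
            n_views=self.n_views,
            arc=self.arc_degrees,
            source_iso_dist=self.source_iso_dist,
            source_det_dist=self.source_det_dist,
            detector=self.detector,
        )


def enumerate_tilt_grid(delta_min: float, delta_max: float, step: float) -> TiltGrid:
    """Inclusive arithmetic tilt grid, e.g. (-30, 30, 5) -> 13 angles."""
    if step <= 0:
        raise ValueError("tilt grid step must be > 0")
    if delta_max < delta_min:
        raise ValueError("delta_max must be >= delta_min")
    return TiltGrid(delta_min=delta_min, delta_max=delta_max, step=step)


# ---------------------------------------------------------------------------
# Serialization

def trajectory_to_json(traj: Trajectory) -> str:
    d = traj.detector
    return json.dumps(
        {
            "arc_degrees": traj.arc_degrees,
            "tilt": traj.tilt,
            "detector": {
                "n_u": d.n_u,
                "n_v": d.n_v,
                "pixel_size_u": d.pixel_size_u,
                "pixel_size_v": d.pixel_size_v,
                "u0": d.u0,
                "v0": d.v0,
            },
            "views": [
                {
                    "theta": v.theta,
                    "P": np.asarray(v.P).reshape(-1).tolist(),  # row-major 3x4
                    "source": v.source_position.tolist(),
                }
                for v in traj
            ],
        }
    )


def trajectory_from_json(text: str) -> Trajectory:
    obj = json.loads(text)
    det = DetectorSpec(**obj["detector"])
    views = tuple(
        ViewGeometry(
            P=np.array(v["P"], dtype=float).reshape(3, 4),
            source_position=np.array(v["source"], dtype=float),
            tilt=obj["tilt"],
            theta=v["theta"],
            detector=det,
        )
        for v in obj["views"]
    )
    return Trajectory(views=views, arc_degrees=obj["arc_degrees"], tilt=obj["tilt"])
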