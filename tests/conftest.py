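"""Shared fixtures: small-scale scan protocols and phantoms.

Heavy pipeline products (wedge impact map, two-screw blooming study) are
session-scoped so that the acceptance checks and the unit tests share
one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from cbctmaa.calibration import calibrate_from_wedge
from cbctmaa.geometry import DetectorSpec, ScanProtocol, enumerate_tilt_grid
from cbctmaa.maa import voxel_impact_map
from cbctmaa.phantoms import ScrewSpec, VoxelGrid, make_spine_scene, make_wedge_mask
from cbctmaa.validation import blooming_vs_prediction


@pytest.fixture(scope="session")
def small_detector() -> DetectorSpec:
    return DetectorSpec(n_u=96, n_v=96, pixel_size_u=1.3, pixel_size_v=1.3)


@pytest.fixture(scope="session")
def small_protocol(small_detector) -> ScanProtocol:
    return ScanProtocol(n_views=60, detector=small_detector)


@pytest.fixture(scope="session")
def wedge_mask():
    # 64^3 grid large enough (153.6 mm) to hold the 150 mm wedge
    return make_wedge_mask(VoxelGrid(shape=(64, 64, 64), voxel_size=2.4))


@pytest.fixture(scope="session")
def wedge_protocol() -> ScanProtocol:
    # full-size detector so the whole wedge stays on the panel in every view
    return ScanProtocol(n_views=100)


@pytest.fixture(scope="session")
def wedge_impact(wedge_mask, wedge_protocol):
    return voxel_impact_map(wedge_mask, wedge_protocol.trajectory(0.0))


@pytest.fixture(scope="session")
def wedge_calibration(wedge_mask, wedge_impact):
    return calibrate_from_wedge(wedge_mask, 25.0, impact=wedge_impact)


def _inclined_screw(x0: float, tilt_deg: float, length: float = 28.0) -> ScrewSpec:
    """Screw axis in the y-z plane, inclined by tilt_deg toward +z."""
    a = np.deg2rad(tilt_deg)
    half = np.array([0.0, np.cos(a), np.sin(a)]) * length / 2.0
    center = np.array([x0, 0.0, 0.0])
    return ScrewSpec(head=tuple(center - half), tip=tuple(center + half), diameter=4.5)


@pytest.fixture(scope="session")
def lumbar_scene():
    """Two-pedicle-screw lumbar-like scene with a cranio-caudal screw
    inclination of 12 degrees, so the artifact burden varies over tilt."""
    grid = VoxelGrid(shape=(80, 80, 80), voxel_size=1.0)
    screws = [_inclined_screw(-10.0, 12.0), _inclined_screw(10.0, 12.0)]
    scene, mask = make_spine_scene(grid, screws, body_halfaxes=(32.0, 28.0, 36.0), bone_radius=12.0)
    return scene, mask, screws


@pytest.fixture(scope="session")
def validation_protocol() -> ScanProtocol:
    det = DetectorSpec(n_u=128, n_v=128, pixel_size_u=1.6, pixel_size_v=1.6)
    return ScanProtocol(n_views=100, detector=det)


@pytest.fixture(scope="session")
def blooming_study(lumbar_scene, validation_protocol, wedge_calibration):
    scene, mask, screws = lumbar_scene
    grid = VoxelGrid(shape=(64, 64, 64), voxel_size=0.9)
    return blooming_vs_prediction(
        scene,
        mask,
        screws,
        enumerate_tilt_grid(-15, 20, 5),
        wedge_calibration,
        protocol=validation_protocol,
        recon_grid=grid,
    )
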