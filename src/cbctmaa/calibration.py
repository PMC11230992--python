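"""Wedge-based color calibration.

Voxel-impact values are unbounded variances; to present them as an
absolute color scale they are normalized by a calibration constant
``c_crit`` obtained from a titanium wedge phantom.  The wedge models a
monotone increase of spectral-shift variance with metal thickness: its
height ramp stands in for increasing screw shaft lengths while its 5 mm
thickness is loosely similar to a pedicle screw diameter.

Protocol: scan the wedge with the untilted default trajectory, run the
artifact-prediction pipeline (path lengths -> spectral shift -> voxel
impact map), locate the slice along the ramp where the wedge height
equals the empirically chosen *critical height* (default 25 mm — the
height at which artifacts were judged intolerable), and use the mean
impact over the metal voxels of that slice as ``c_crit``.  Color values
are then ``clip(impact / c_crit, 0, 1)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .geometry import ScanProtocol
from .maa import VoxelImpactMap, voxel_impact_map
from .phantoms import MetalMask, wedge_slice_height
from .spectral import MaterialAttenuation, Spectrum, default_spectrum, material_attenuation

__all__ = ["CalibrationResult", "calibrate_from_wedge", "color_value"]

DEFAULT_CRITICAL_HEIGHT_MM = 25.0


@dataclass(frozen=True)
class CalibrationResult:
    """Color-map upper limit and the wedge configuration that produced it."""

    c_crit: float
    critical_height: float
    tilt: float
    slice_index: int
    measured_height: float

    def __post_init__(self) -> None:
        if self.c_crit <= 0:
            raise ValueError("calibration constant must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationResult":
        return cls(**json.loads(Path(path).read_text()))


def calibrate_from_wedge(
    wedge: MetalMask,
    critical_height: float = DEFAULT_CRITICAL_HEIGHT_MM,
    protocol: ScanProtocol | None = None,
    spectrum: Spectrum | None = None,
    material: MaterialAttenuation | None = None,
    tilt: float = 0.0,
    ramp_axis: int = 2,
    impact: VoxelImpactMap | None = None,
) -> CalibrationResult:
    """Derive ``c_crit`` from a wedge scan at the given critical height.

    The wedge height at each slice along the ramp axis is measured from
    the mask itself (metal extent in voxels times voxel size), mirroring
    the in-image measurement of the protocol.  Passing a precomputed
    ``impact`` map skips the scan simulation.
    """
    if wedge.n_metal == 0:
        raise ValueError("wedge mask is empty")
    spectrum = spectrum or default_spectrum()
    material = material or material_attenuation("titanium")
    if spectrum.is_degenerate:
        raise ValueError(
            "degenerate (single-energy) spectrum: impact is identically zero, "
            "no calibration constant can be defined"
        )
    heights = np.array(
        [wedge_slice_height(wedge, i, axis=ramp_axis) for i in range(wedge.grid.shape[ramp_axis])]
    )
    present = heights > 0
    if not (heights[present].min() <= critical_height <= heights.max()):
        raise ValueError("critical height lies outside the wedge ramp")
    candidates = np.flatnonzero(present)
    sl = int(candidates[np.argmin(np.abs(heights[candidates] - critical_height))])

    if impact is None:
        protocol = protocol or ScanProtocol()
        impact = voxel_impact_map(wedge, protocol.trajectory(tilt), spectrum=spectrum, material=material)
    slice_metal = np.take(wedge.values, sl, axis=ramp_axis) > 0
    slice_impact = np.take(impact.values, sl, axis=ramp_axis)
    c_crit = float(slice_impact[slice_metal].mean())
    if c_crit <= 0:
        raise ValueError("wedge impact vanished at the critical slice; cannot calibrate")
    return CalibrationResult(
        c_crit=c_crit,
        critical_height=critical_height,
        tilt=tilt,
        slice_index=sl,
        measured_height=float(heights[sl]),
    )


def color_value(value, calibration: CalibrationResult):
    """Calibrated color in [0, 1]: clip(value / c_crit, 0, 1)."""
    return np.clip(np.asarray(value, dtype=float) / calibration.c_crit, 0.0, 1.0)
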