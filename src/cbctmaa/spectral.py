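"""Polyenergetic X-ray forward model and the per-pixel spectral shift.

The spectral shift is the beam-hardening bias proxy at the heart of the
artifact prediction: for a metal path length ``l`` it is the difference
between the monoenergetic and polyenergetic log-attenuation models,

    s(l) = mu_mono * l + log( sum_E w(E) * exp(-mu(E) * l) ),

with ``mu_mono = sum_E w(E) mu(E)``, the zero-thickness slope of the
polyenergetic curve.  By Jensen's inequality ``s`` is non-negative,
non-decreasing and convex, and vanishes identically for a single-energy
(degenerate) spectrum.

The default spectrum is a 10-bin filtered Kramers-form bremsstrahlung
shape over 40-110 keV (tungsten anode at 120 kVp behind 2.5 mm Al,
normalized); titanium attenuation comes from a small embedded NIST-style
mass-attenuation table times the density 4.506 g/cm^3.  Both are
configurable and loadable from CSV.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum",
    "MaterialAttenuation",
    "default_spectrum",
    "single_energy_spectrum",
    "material_attenuation",
    "poly_line_integral",
    "spectral_shift",
    "shift_stack",
    "polyenergetic_intensity",
    "load_spectrum_csv",
    "load_material_csv",
]


@dataclass(frozen=True)
class Spectrum:
    """Discrete X-ray spectrum: energy bins (keV) and normalized weights."""

    energies_kev: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_kev, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.ndim != 1 or e.shape != w.shape:
            raise ValueError("energies and weights must be 1D arrays of equal length")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("spectrum must carry positive total weight")
        object.__setattr__(self, "energies_kev", e)
        object.__setattr__(self, "weights", w / total)

    @property
    def n_bins(self) -> int:
        return len(self.energies_kev)

    @property
    def is_degenerate(self) -> bool:
        """True when effectively a single energy carries all the weight."""
        return int(np.count_nonzero(self.weights > 1e-12)) <= 1


@dataclass(frozen=True)
class MaterialAttenuation:
    """Linear attenuation mu(E) in mm^-1 sampled at arbitrary energies;
    evaluated at spectrum bins by log-log interpolation."""

    name: str
    energies_kev: np.ndarray
    mu_per_mm: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_kev, dtype=float)
        mu = np.asarray(self.mu_per_mm, dtype=float)
        if np.any(mu <= 0):
            raise ValueError("attenuation values must be positive")
        object.__setattr__(self, "energies_kev", e)
        object.__setattr__(self, "mu_per_mm", mu)

    def mu_at(self, energies_kev: np.ndarray) -> np.ndarray:
        e = np.asarray(energies_kev, dtype=float)
        return np.exp(
            np.interp(np.log(e), np.log(self.energies_kev), np.log(self.mu_per_mm))
        )


# ---------------------------------------------------------------------------
# Embedded material tables: NIST-style mass attenuation (cm^2/g) over the
# diagnostic range, converted to mm^-1 with the bulk density.

_TABLE_E_KEV = np.array([30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 120.0, 150.0])

# titanium, density 4.506 g/cm^3
_TI_MU_RHO = np.array([1.213, 0.5549, 0.3173, 0.2214, 0.1649, 0.1463, 0.1371, 0.1262])
# water (soft-tissue surrogate), density 1.0 g/cm^3
_WATER_MU_RHO = np.array([0.3756, 0.2683, 0.2269, 0.2059, 0.1837, 0.1707, 0.1614, 0.1505])
# aluminium (tube filtration), density 2.699 g/cm^3
_AL_MU_RHO = np.array([1.128, 0.5685, 0.3681, 0.2778, 0.2018, 0.1704, 0.1536, 0.1378])

_DENSITY = {"titanium": 4.506, "water": 1.0, "aluminium": 2.699}
_MU_RHO = {"titanium": _TI_MU_RHO, "water": _WATER_MU_RHO, "aluminium": _AL_MU_RHO}

# cortical-bone surrogate: water spectral shape scaled by a constant factor
_BONE_SCALE = 1.8


def material_attenuation(name: str) -> MaterialAttenuation:
    """Built-in materials: titanium, water, soft_tissue (= water),
    bone (1.8 x water), aluminium."""
    key = name.lower()
    if key in ("soft_tissue", "soft tissue"):
        key = "water"
    if key == "bone":
        mu = _WATER_MU_RHO * _DENSITY["water"] * _BONE_SCALE / 10.0
        return MaterialAttenuation("bone", _TABLE_E_KEV, mu)
    if key not in _MU_RHO:
        raise KeyError(f"unknown material: {name}")
    mu = _MU_RHO[key] * _DENSITY[key] / 10.0  # cm^-1 -> mm^-1
    return MaterialAttenuation(key, _TABLE_E_KEV, mu)


def default_spectrum(n_bins: int = 10, e_min: float = 40.0, e_max: float = 110.0,
                     kvp: float = 120.0, filter_mm_al: float = 2.5) -> Spectrum:
    """Filtered Kramers-form bremsstrahlung shape, normalized.

    w(E) ∝ max(kvp - E, 0) / E * exp(-mu_Al(E) * t_Al); a coarse tungsten
    anode approximation adequate for the qualitative beam-hardening model.
    """
    e = np.linspace(e_min, e_max, n_bins)
    al = material_attenuation("aluminium").mu_at(e)
    w = np.clip(kvp - e, 0.0, None) / e * np.exp(-al * filter_mm_al)
    return Spectrum(e, w)


def single_energy_spectrum(energy_kev: float = 70.0) -> Spectrum:
    """Degenerate (monoenergetic) spectrum — the no-beam-hardening control."""
    return Spectrum(np.array([energy_kev]), np.array([1.0]))


def mean_mu(spectrum: Spectrum, material: MaterialAttenuation) -> float:
    """Spectrum-weighted mean attenuation, the monoenergetic reference slope."""
    return float(spectrum.weights @ material.mu_at(spectrum.energies_kev))


def poly_line_integral(length_mm, spectrum: Spectrum, material: MaterialAttenuation):
    """Effective polyenergetic line integral -log(sum_E w exp(-mu l));
    concave and increasing in the path length."""
    l = np.asarray(length_mm, dtype=float)
    if np.any(l < 0):
        raise ValueError("path length must be non-negative")
    mu = material.mu_at(spectrum.energies_kev)
    att = np.tensordot(np.exp(-np.multiply.outer(mu, l)), spectrum.weights, axes=([0], [0]))
    # divide by the float sum of the weights so l = 0 maps to exactly 0
    out = -np.log(att / spectrum.weights.sum())
    return float(out) if np.isscalar(length_mm) else out


def spectral_shift(length_mm, spectrum: Spectrum, material: MaterialAttenuation):
    """Beam-hardening bias s(l) = mu_mono*l - poly_line_integral(l) >= 0."""
    l = np.asarray(length_mm, dtype=float)
    if np.any(l < 0):
        raise ValueError("path length must be non-negative")
    if spectrum.is_degenerate:  # s == 0 analytically: no beam hardening
        out = np.zeros_like(l)
    else:
        out = mean_mu(spectrum, material) * l - poly_line_integral(l, spectrum, material)
        out = np.maximum(out, 0.0)  # clamp -0.0 / rounding at l == 0
    return float(out) if np.isscalar(length_mm) else out


def shift_stack(paths, spectrum: Spectrum, material: MaterialAttenuation) -> np.ndarray:
    """Elementwise spectral shift of a path-length stack (pipeline step L2).

    Accepts a PathLengthStack or a bare array; returns an array of the same
    shape with s(l) per pixel."""
    arr = getattr(paths, "values", paths)
    return spectral_shift(np.asarray(arr, dtype=float), spectrum, material)


def polyenergetic_intensity(
    path_lengths_mm: dict[str, np.ndarray],
    spectrum: Spectrum,
    materials: dict[str, MaterialAttenuation] | None = None,
    photons: float | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Detector intensity and effective attenuation for multi-material paths.

    ``intensity = sum_E w(E) exp(-sum_m mu_m(E) l_m)`` (unit incident flux);
    ``effective attenuation = -log(intensity)``.  With ``photons`` set,
    Poisson noise at that incident photon count is applied (seeded).
    """
    if materials is None:
        materials = {name: material_attenuation(name) for name in path_lengths_mm}
    shapes = {np.asarray(v).shape for v in path_lengths_mm.values()}
    if len(shapes) > 1:
        raise ValueError("per-material path-length images must share a shape")
    shape = shapes.pop()
    intensity = np.zeros(shape, dtype=np.float64)
    for k, e in enumerate(spectrum.energies_kev):
        exponent = np.zeros(shape, dtype=np.float64)
        for name, l in path_lengths_mm.items():
            exponent += materials[name].mu_at(np.array([e]))[0] * np.asarray(l, dtype=float)
        intensity += spectrum.weights[k] * np.exp(-exponent)
    if photons is not None:
        rng = np.random.default_rng(seed)
        intensity = rng.poisson(np.maximum(intensity, 0.0) * photons) / photons
    attenuation = -np.log(np.maximum(intensity, 1e-12))
    return intensity, attenuation


# ---------------------------------------------------------------------------
# CSV interfaces

def load_spectrum_csv(path: str | Path) -> Spectrum:
    """Spectrum from a CSV with columns energy_kev, weight."""
    import pandas as pd

    df = pd.read_csv(path)
    return Spectrum(df["energy_kev"].to_numpy(), df["weight"].to_numpy())


def load_material_csv(path: str | Path, name: str | None = None) -> MaterialAttenuation:
    """Material from a CSV with columns energy_kev, mu_per_mm."""
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path)
    return MaterialAttenuation(name or path.stem, df["energy_kev"].to_numpy(), df["mu_per_mm"].to_numpy())
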