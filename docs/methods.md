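# Methods

## Model and assumptions

The package predicts beam-hardening metal artifacts for tilted circular
CBCT orbits from a binary metal mask.  The underlying physical
assumption is that the dominant, geometry-dependent component of metal
artifacts is the polyenergetic bias of rays traversing metal: a ray that
crosses `ℓ` millimetres of titanium under spectrum `w(E)` registers an
effective attenuation `−log Σ_E w(E) e^{−μ(E)ℓ}` instead of the linear
`μ̄ℓ` a monoenergetic beam would give.  The difference — the *spectral
shift* `s(ℓ)` — is used as a per-ray bias proxy.  A voxel whose
projections see a *constant* bias over the scan mostly suffers a benign
offset; a voxel whose projections see a strongly *varying* bias is where
streaks and blooming concentrate.  Hence both predictors are variances:

- **Global score** `Q(δ)`: variance across views of the per-view mean of
  `s` over all detector pixels.  The per-view mean includes zero pixels;
  this only rescales the curve and is removed by the min-max
  normalization over the evaluated tilt range.  Population (biased)
  variance is used, so a single view scores exactly 0.
- **Voxel impact** `m_δ(x,y,z)`: variance across views of `s` sampled at
  the voxel's projected detector position, computed only for metal
  voxels (zero elsewhere).  Sampling is bilinear; nearest-neighbour
  sampling aliases visibly at the default 244² detector resolution.
  The variance is accumulated with Welford's online algorithm,
  vectorized over voxels.  Voxels that project off the detector in some
  views are averaged over the views that do see them (cone-beam short
  scans truncate peripheral voxels); a voxel seen by no view keeps
  value 0 and a warning is logged.

Deliberately *not* modeled, and acknowledged as the main realism gap:
scatter, photon starvation/noise in the prediction path, patient
(soft-tissue) hardening — the shift is computed from metal path lengths
only, matching a pipeline whose input is just the metal mask — detector
energy response, and tube-setting dependence.

## Coordinate conventions

World frame: right-handed, millimetres, origin at the isocenter, `+z`
along the patient (cranio-caudal) axis.  The untilted orbit lies in the
x-y plane with θ = 0 the AP view; θ is sampled symmetrically,
`θ_i = −arc/2 + i·arc/(n−1)`.  The tilt δ rotates the whole orbital
plane about the world x axis (patient left-right), the cranio-caudal
C-arm tilt used in spine imaging; this axis choice is a convention of
this package, as is the symmetric arc placement.  Detector: `u` along
the rotation direction, `v` along the tilt axis, pixel (0,0) at the
center of the corner pixel, principal point at the image center.

## Defaults and parameters

| parameter | default | note |
|---|---|---|
| views / arc | 200 over 200° | short scan (arc > 180° + fan) |
| detector | 244² px, 1.3 mm pitch | flat panel |
| source–isocenter | 600 mm | typical mobile C-arm scale |
| source–detector | 1100 mm | magnification ≈ 1.83 |
| volume grid | 128³ at 1.2 mm | metal mask and impact maps |
| tilt range | −30° … 30°, 5° steps | 13 candidate orbits |
| spectrum | 10 bins, 40–110 keV | filtered Kramers shape, 120 kVp, 2.5 mm Al |
| titanium μ(E) | embedded table × 4.506 g/cm³ | NIST-style mass attenuation, log-log interpolated |
| wedge | 50 × 150 × 5 mm | calibration phantom, ramp along z |
| critical height | 25 mm | wedge height defining `c_crit` |
| screw diameter | 4.5 mm | pedicle-screw-like capsule |

The monoenergetic reference `μ̄` is the spectrum-weighted mean
attenuation — the `ℓ → 0` slope of the polyenergetic curve — which makes
`s(ℓ) ≥ 0` with equality only for a degenerate spectrum (a choice this
package fixes; any decreasing-μ spectrum gives the same qualitative
behavior, and both spectrum and material tables are loadable from CSV).
For a degenerate (single-energy) spectrum `s` is returned as exactly
zero rather than through the log/exp round trip.

## Synthetic scenes

The phantom generator rasterizes solids by a voxel-center-in-solid test,
so scenes are bit-reproducible and voxelization error is bounded by the
surface-voxel shell.  It provides: the titanium calibration wedge
(triangular prism, height ramp 0→50 mm along its 150 mm length);
pedicle-screw capsules (default 4.5 mm diameter); and a coarse
spine scene — soft-tissue ellipsoid, cylindrical bone column (1.8×
water), titanium screws, with titanium > bone > soft tissue precedence.
These emulate the geometry and contrast of an instrumented spine, not
anatomy: no vertebral shape, no screw threads, no heterogeneous tissue.
Consequently, passing tests demonstrate that the predictor orders tilts
correctly for metal of realistic size, spacing and inclination under an
idealized beam — not that it reproduces grading outcomes on real
patients or cadavers.

## Projector

Siddon ray tracing through the pixel centers (no supersampling),
treating voxels as axis-aligned boxes; half-open parametric intervals
attribute a grazed shared face to the voxel the ray enters.  Exact for
piecewise-constant volumes, verified against analytic chords (axis and
body-diagonal) to 1e−6 mm and dense 0.01-voxel ray marching to 0.5%.
The same kernel runs in three modes: line integral, maximum along the
ray (overlay projection), and per-material path lengths from a label
volume in a single traversal.  Kernels are numba-compiled and cached;
rays from a source inside the volume bounding box are rejected.

## Calibration

`c_crit` is the mean impact over the metal voxels of the wedge slice
whose measured height (metal extent in voxels × voxel size, the same
measurement a reader would make in the image) is closest to the critical
height.  The mean is taken over metal voxels only — impact is defined
only on metal.  An untilted default scan is used.  Degenerate spectra
are rejected (impact ≡ 0 admits no positive ceiling).  Calibration is
scale-consistent: scaling all impact values by `c` scales `c_crit` by
`c` and leaves every displayed color unchanged.

## Reconstruction and blooming measurement

FDK for circular short scans: cosine pre-weighting, generalized Parker
redundancy weights (overscan half-angle Γ = (arc − 180°)/2), Ram-Lak
ramp filter apodized by a Hann window, applied row-wise on the virtual
detector through the isocenter with zero-padding to the next power of
two, then voxel-driven backprojection with inverse-square distance
weighting via the view's projection matrix.  On a noiseless
single-energy water ellipsoid the interior is recovered to well under
5%.  Arcs shorter than 180° plus the fan angle warn and proceed.

FWHM blooming: profiles perpendicular to the annotated screw axis,
7 levels spaced 0.5 mm about the shaft midpoint × 18 directions in 10°
steps, sampled by trilinear interpolation at 0.1-voxel resolution.  The
half-maximum baseline is the mean of the outer 25% of profile samples
(robust to the soft-tissue pedestal, which is not zero); crossings are
located with sub-sample linear interpolation.  Rays without two
crossings are flagged NaN and excluded from the mean/std, with the
count reported.  Ground-truth screw endpoints stand in for the manual
head/tip annotation, and all synthetic volumes share one world frame,
so no co-registration step is needed.

## Problem sizes

Full scale (128³ mask, 200 views, 244² detector) is configurable
throughout; the test suite and the acceptance script run scaled-down
versions chosen as the smallest sizes at which each property is stable:
64³ masks with 40–100 views and 64²–128² detectors, 64³ reconstruction
grids at 0.9 mm, and a 100-view wedge scan on the full 244² panel (the
153.6 mm wedge must stay on the detector in every view).  The
blooming study uses the 8-tilt grid (−15° … 20°) on an 80³ two-screw
scene.

## Design choices where the design was open

- **Normalization polarity**: normalized `Q` has 0 = best (lowest
  shift variance), 1 = worst.  An all-equal raw curve normalizes to all
  zeros and is flagged `degenerate`.
- **Tie-breaking** in tilt recommendation: ties go to the smaller |δ|
  (prefer the mechanically simpler orbit), then to the smaller δ.
- **"Per unit volume"** impact normalization is interpreted as per-voxel
  evaluation with no extra scaling — the variance is already an
  intensive, location-wise quantity.
- **Interpolated geometries** blend intrinsics and translation linearly
  and the rotation by quaternion slerp of the relative rotation;
  blending rotation entries linearly would leave the manifold.  On
  ideal tilted-orbit geometry this reproduces the directly constructed
  intermediate tilt exactly, because the camera translation is
  independent of tilt in this parameterization.
- **Scout views** default to the AP and lateral views (θ = 0°, 90°) of
  the untilted geometry.
- **Validation correlation** is reported as the Spearman rank
  correlation between predicted mean calibrated color in the
  shaft-center ROI and measured mean FWHM, pooled over tilts and screws
  and per screw; only its sign is asserted, since its magnitude depends
  on the scene.

## Known limitations

Single-CPU Python/numba implementation (no GPU real-time updates); no
scatter or noise in the prediction path; bone modeled as scaled water;
blooming in the simulation is driven by beam hardening and filtering
alone, so absolute FWHM values undershoot clinical blooming; the
interactive human-in-the-loop step is replaced by a deterministic
ROI-argmin surrogate.
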