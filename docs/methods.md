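# Methods

This note documents the models, estimators, numerical choices and known
limitations of `leadorient`. Angles are degrees, distances millimetres,
intensities Hounsfield units (HU). World coordinates are RAS+ as encoded by
the NIfTI affine; all geometry is done in world space, so anisotropic or
oblique acquisitions need no special casing.

## Problem

A directional DBS lead's segmented contacts make stimulation direction a
clinical variable, but the implanted rotation ("yaw") deviates from the
intended orientation by tens of degrees and must be measured from
postoperative imaging. In CT, the lead's stereotactic marker and segmented
contacts generate metal artifacts whose angular structure encodes yaw — the
marker's hypodense streak axis modulo 180°, plus weaker asymmetries that
break the 180° tie.

## Pipeline

### Trajectory refinement

Inputs are two world points on the lead (tip and a proximal point). For
every native axial slice crossed by the shaft segment, the center of mass
of suprathreshold (> 2000 HU) intensity inside a 4 mm-radius disk around
the current axis estimate is computed, and ordinary least-squares lines
x(z) and y(z) are fitted and re-expressed as (tip, unit direction); the
step iterates until the tip moves < 0.01 mm (max 5 iterations). Two
accuracy-critical details:

* the fitted segment stops **below the marker band**
  (tip→`tip_to_marker_center − marker_half_length`): the marker's
  hyperdense mass is intentionally asymmetric — that asymmetry is the COM
  method's signal — and including it pulls the centerline toward the facing
  direction;
* slice COMs are evaluated on a 0.15 mm trilinear in-plane grid rather than
  raw voxel centers, because the ~1.3 mm shaft covers only a handful of
  voxels and voxel-center COMs alias at a substantial fraction of the voxel
  size. Even so, at 0.5 mm voxels the fitted *direction* is reliable only
  to roughly 0.2–1° depending on tilt; the tip (lateral position) is good
  to a few hundredths of a millimetre.

Because a small direction error grows into a lateral offset when
extrapolated to the marker (≈ 10.6 mm above the tip), the axis is then
**anchored**: the shaft's cross-section center is measured on 0.1 mm
perpendicular slices 2.5–3.5 mm below the marker band (where the
thresholded cross section is the symmetric shaft disk only) and the
trajectory is translated laterally through their mean. An off-center
sampling circle couples the marker's first-harmonic intensity asymmetry
into the second-harmonic phase at roughly (δ/R) radians per mm of offset
δ at sampling radius R, so this anchoring is what keeps the detected angle
within ~1° under tilt.

### Polar gate

The angle between the lead axis and the scanner z-axis ("polar angle")
controls artifact quality. Gate bands: ≤ 40° ok; 40–55° warn (results
carry reduced confidence); > 55° refuse (no orientation reported). The
bands follow the published imaging constraints for this family of
algorithms.

### Angular profiles and candidate detection

HU values are sampled on circles perpendicular to the refined axis
(trilinear interpolation; angle 0 = projected anterior, counterclockwise
viewed from superior). Because profiles are perpendicular to the *lead*
axis rather than native axial planes, no trigonometric polar-angle
correction of the measured angle is needed at any tilt.

The marker's streak axis is estimated from the phase of the second
circular harmonic, c₂ = Σₖ I(αₖ)e^{2iαₖ}, as θ_streak = arg(−c₂)/2 ∈
[0°, 180°), then offset by the lead profile's streak-to-face angle
(default 0°). This is chosen over discrete valley-picking for sub-degree
resolution, noise robustness, and analytic testability (a pure
100 − 50·cos(2(α−30°)) profile returns 30° to 1e-6). θ is quantized to a
2⁻³⁶-degree dyadic grid so that the inverse partner θ+180° is exactly
representable — the pair separation is exactly 180° in floating point.

On a single circle the harmonic phase is noise-limited: samples 0.05 mm
apart share voxels, so a 360-sample circle carries only ~40 independent
voxels and σ = 15 HU noise leaves ~1–2° of phase jitter. Profiles are
therefore averaged over a thin cylindrical shell — radii 2.5–4.5 mm
(outside the bloomed marker metal, inside the streak annulus) × axial
offsets ±1.5 mm (the marker's half-length; ±0.5 mm at contact levels) —
before harmonic analysis. A second-harmonic amplitude below 10 HU is
treated as "no usable artifact" (white noise at 15 HU yields ~1 HU).

The artifact slice itself is auto-selected by scanning ±1.5 mm along the
axis in 0.25 mm steps and maximizing the second-harmonic amplitude (third
harmonic for the 120°-periodic dark-star levels); ties break toward the
nominal level center, and an argmax at the search boundary emits a
truncated-search warning.

### Ambiguity resolution

All four methods choose between θ and θ+180°; margins are normalized so a
single floor (0.05) defines degeneracy across methods.

* **COM**: the marker's thresholded (> 2000 HU) hyperdense volume is
  resampled on a stack of perpendicular 0.1 mm slices covering the marker
  band (±1.5 mm, 0.25 mm steps, 10×10 mm extent); the center of mass's
  lateral deviation **d** from the axis is compared with the two candidate
  bearings and the closer one wins. Using the volume rather than a single
  zero-thickness cut matters: a single cut through a sub-voxel-thin metal
  band is dominated by voxel-sampling aliasing at large polar angles.
  Margin = |u_θ·d̂ − u_{θ+180}·d̂|/2 · |d|/0.1 mm; degenerate when
  |d| < 0.02 mm. The sign convention (COM shift points *toward* the facing
  direction, because the marker's angular window sits opposite it) is a
  single config flag (`com_points_toward_face`) applied consistently in
  detector and phantom.
* **COMsagittal**: one in-line 0.1 mm slice containing the axis and the
  candidate axis (marker ±1.5 mm along the lead, ±5 mm transverse),
  binarized at 2000 HU; the sign of the COM's transverse component decides.
* **ASM**: peak height h(θ) = max intensity within ±30° of each candidate
  bearing on the shell-averaged marker profile; the higher peak wins;
  margin is the height difference over the profile standard deviation.
* **STARS**: for each directional contact level the best slice is selected
  by third-harmonic amplitude; the score of a solution is the mean profile
  intensity minus the mean inside ±15° windows at the expected one-sided
  streak bearings θ + 60° + 120°·m (inter-segment gaps), over the profile
  standard deviation; scores are summed across levels. The score is exactly
  120°-periodic, so the two solutions (180° apart) genuinely differ.

**Combination policy**: the final orientation is COM's choice. If COM is
degenerate, the cascade COMsagittal → STARS → ASM applies and confidence
drops to "reduced" (the fallback order is this package's policy, ranked by
observed reliability). A mismatch flag is raised when any non-degenerate
method disagrees. If all four are degenerate the ambiguity is unresolved
and both candidates are reported with an error.

## Synthetic phantom

The phantom paints artifact *phenomenology*, not CT physics (no beam
hardening or photon transport): every detector consumes only HU geometry,
so angular intensity patterns with the right symmetries suffice. In the
lead frame the noise-free field is:

* soft-tissue background (40 HU);
* metal shaft cylinder (3000 HU, radius 0.65 mm, tip to marker top);
* marker band: a 3000 HU annulus (0.65–1.6 mm radius, ±1.5 mm axial)
  minus a 90° angular **window** centered opposite the facing direction —
  the missing mass shifts the thresholded COM toward the true yaw. The
  1.6 mm outer radius emulates CT blooming of the metal band; a band at
  its physical sub-voxel thickness would alias badly at 0.5 mm voxels;
* marker streak artifact, on an annular radial envelope (Gaussian around
  3 mm, σ 2 mm, zero inside the metal) × axial Gaussian envelope (σ 1.5 mm):
  two hypodense streaks of depth A2 = 150 HU (angular σ 10°) along yaw and
  yaw+180°, plus a first-harmonic asymmetry A1·cos(φ−yaw), A1 = 60 HU
  (ASM's signal);
* dark stars at each contact level (axial σ 0.75 mm): three one-sided
  streaks of depth A3 = 100 HU at yaw + 60° + 120°·m (STARS's signal).

Voxelization samples the field at voxel centers (0.5 mm default, honoring
the < 1 mm resolution recommendation); independent Gaussian noise
(default σ 15 HU) is added from a seeded generator; an optional 3D Gaussian
smoothing emulates reconstruction kernels. A1/A2/A3 and the window angle
are not published for real leads; the defaults are fixed once so that all
four methods have workable signal at 15 HU noise, and they are **shared**
between phantom and detector conventions (`marker_streak_offset_deg`,
`star_gap_offset_deg`, `com_points_toward_face`), so correctness on
phantoms is self-consistent rather than absolutely calibrated.

What the phantom does **not** model — and what passing tests therefore do
not show about real data: correlated streak noise, beam hardening from
neighboring anatomy (skull, a second lead), partial-volume averaging
(voxel values are point samples), patient motion, and the true angular
relation between the marker face and its streak axis. In particular,
artifact amplitude does not intrinsically degrade with polar angle in the
phantom (only through voxel-grid anisotropy), so phantom accuracy at 45°
overstates real-world accuracy there.

## Standard validation suite

The default suite crosses yaw 0–345° (15° steps) with polar {0°, 15°, 30°,
45°} at azimuth 30°: 96 phantoms, σ = 15 HU, 0.5 mm voxels, per-phantom
seed = base seed + index. On this suite all four methods currently resolve
the ambiguity in 100% of phantoms, and the final orientation is within
~1.3° of truth everywhere; tests assert the weaker documented floors
(COM 100%; others ≥ 90% at polar ≤ 30°; final error < 2° at polar ≤ 40°).
The suite size keeps the whole run under a minute on one CPU while covering
the full yaw circle at every gate-relevant tilt.

## Numerical choices and edge cases

* Interpolation is trilinear everywhere (exact on affine fields — the
  property the resampler's tests exploit); out-of-volume samples return a
  configurable fill (−1024 HU) because artifact circles may graze the
  volume edge.
* sform is preferred over qform; a file with neither is rejected, as are
  non-3D images, singular affines and non-finite voxels.
* The zero-bearing reference is the in-plane projection of world anterior;
  if the lead axis is parallel to anterior (polar 90°, far beyond the
  gate), the projection of world +X is used and a note is logged.
* Slice-wise refinement assumes the third voxel axis is the scanner z
  (axial) axis — true for scanner-space NIfTIs; strongly oblique affines
  would degrade the "native slice" interpretation but not the subsequent
  perpendicular-plane steps.
* `refine_trajectory` requires metal in ≥ 5 slices, else an
  insufficient-artifact error; an all-air volume fails there.
* Degenerate inputs raise typed errors (dimensionality, geometry, empty
  slice, degenerate trajectory, no artifact, unresolved ambiguity), which
  the CLI maps to stable exit codes.

## Known limitations

Geometry defaults for the Cartesia-style lead (marker center 10.6 mm,
contact levels 2.75/4.75 mm from tip, shaft radius 0.65 mm) are shipped as
a named profile and should be verified against manufacturer documentation
before clinical-style use; only the marker half-extent (±1.5 mm) is taken
from the published resampling span. Other lead families are configurable
but unvalidated, multiple leads per hemisphere are not modelled, and
automatic lead detection / registration is out of scope by design.
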