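"""Angular intensity profiles and candidate-orientation detection.

The stereotactic marker of a directional lead produces a hypodense streak
pattern in CT that is periodic with 180 degrees: its axis encodes the lead's
facing direction modulo 180.  We sample HU values on a circle perpendicular
to the (refined) lead axis and read the streak axis off the *phase of the
second circular Fourier harmonic* of that profile — sub-degree resolution,
robust to noise, and analytically testable, unlike discrete valley picking.

Because all profiles are sampled on planes perpendicular to the lead axis
(never native axial slices), no trigonometric polar-angle correction of the
measured angle is needed at any tilt.

Angle convention: 0 degrees = anterior (in-plane projection of world +Y),
increasing counterclockwise when viewed from superior, i.e. toward the
patient's left.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import NoArtifactError
from .lead_model import LeadSpec, Trajectory
from .volume_io import CTVolume, sample_trilinear

logger = logging.getLogger(__name__)


def ang_diff_deg(a, b):
    """Signed smallest angular difference a - b, wrapped to [-180, 180)."""
    return (np.asarray(a, dtype=np.float64) - b + 180.0) % 360.0 - 180.0


def perpendicular_frame(unit_dir: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane orthonormal frame (e1, e2) perpendicular to the lead axis.

    e1 is the in-plane projection of world anterior (+Y); e2 = axis x e1, so
    that bearings increase counterclockwise viewed from superior.  If the
    axis is (numerically) parallel to anterior, the projection of world +X
    is used instead and a note is logged.
    """
    u = np.asarray(unit_dir, dtype=np.float64)
    anterior = np.array([0.0, 1.0, 0.0])
    e1 = anterior - (anterior @ u) * u
    n = np.linalg.norm(e1)
    if n < 1e-6:
        logger.warning(
            "lead axis is parallel to anterior; using +X projection as the "
            "zero-bearing reference"
        )
        right = np.array([1.0, 0.0, 0.0])
        e1 = right - (right @ u) * u
        n = np.linalg.norm(e1)
    e1 = e1 / n
    e2 = np.cross(u, e1)
    e2 = e2 / np.linalg.norm(e2)
    return e1, e2


def anchor_axis(
    ct: CTVolume,
    traj: Trajectory,
    spec: LeadSpec,
    offsets_below_marker_mm=(-3.5, -3.0, -2.5),
    extent_mm: float = 4.0,
    resolution_mm: float = 0.1,
    threshold_hu: float = 2000.0,
) -> Trajectory:
    """Translate the trajectory through locally measured shaft centers.

    The slice-wise regression that refines the trajectory extrapolates from
    the shaft to the marker level, so a small slope error becomes a lateral
    offset of the sampling-circle center there — and an off-center circle
    couples the marker's first-harmonic intensity asymmetry into the
    second-harmonic phase that encodes the orientation.  This step measures
    the shaft's cross-section center on 0.1 mm perpendicular slices just
    below the marker band (where the thresholded cross section is the
    symmetric shaft disk only) and shifts the trajectory laterally through
    their mean; the direction is left unchanged.  If no metal is found at
    any anchor plane the trajectory is returned unchanged.
    """
    from .volume_io import PlaneSpec, resample_plane  # avoid cycles

    e1, e2 = perpendicular_frame(traj.unit_dir)
    corrections = []
    for off in offsets_below_marker_mm:
        s = spec.tip_to_marker_center_mm + off
        center = traj.tip_world + s * traj.unit_dir
        plane = PlaneSpec(
            center=center,
            basis_u=e1,
            basis_v=e2,
            extent_mm=(extent_mm, extent_mm),
            resolution_mm=resolution_mm,
        )
        try:
            sl = resample_plane(ct, plane)
        except Exception:
            continue
        mask = sl.values > threshold_hu
        if not mask.any():
            continue
        ii, jj = np.nonzero(mask)
        com = np.asarray(
            sl.pixel_to_world(float(ii.mean()), float(jj.mean()))
        ).reshape(3)
        corrections.append(com - center)
    if not corrections:
        return traj
    shift = np.mean(corrections, axis=0)
    shift = shift - (shift @ traj.unit_dir) * traj.unit_dir  # lateral only
    return Trajectory(tip_world=traj.tip_world + shift, unit_dir=traj.unit_dir)


@dataclass(frozen=True)
class AngularProfile:
    """HU intensities sampled on a circle perpendicular to the lead axis."""

    angles_deg: np.ndarray
    intensities_hu: np.ndarray
    radius_mm: float
    center_world: np.ndarray
    e1: np.ndarray
    e2: np.ndarray

    def __post_init__(self):
        if len(self.angles_deg) != len(self.intensities_hu):
            raise ValueError("angles and intensities must have equal length")

    def bearing_world(self, theta_deg: float) -> np.ndarray:
        """Unit world vector of an in-plane bearing."""
        t = np.radians(theta_deg)
        return np.cos(t) * self.e1 + np.sin(t) * self.e2


@dataclass(frozen=True)
class CandidatePair:
    """The two inverse orientation solutions from the symmetric marker artifact.

    ``theta_deg`` lies in [0, 180); the partner is exactly 180 degrees away.
    ``quality`` is the ratio of second-harmonic amplitude to the RMS of the
    profile after removing harmonics 0-2.
    """

    theta_deg: float
    second_harmonic_amplitude: float
    quality: float

    @property
    def partner_deg(self) -> float:
        return self.theta_deg + 180.0


def angular_profile(
    ct: CTVolume,
    traj: Trajectory,
    center,
    radius_mm: float = 3.0,
    n_angles: int = 360,
) -> AngularProfile:
    """Sample HU on a circle of ``radius_mm`` perpendicular to the lead axis."""
    center = np.asarray(center, dtype=np.float64)
    e1, e2 = perpendicular_frame(traj.unit_dir)
    angles = np.arange(n_angles) * (360.0 / n_angles)
    rad = np.radians(angles)
    pts = (
        center
        + radius_mm * np.outer(np.cos(rad), e1)
        + radius_mm * np.outer(np.sin(rad), e2)
    )
    vals = sample_trilinear(ct, pts)
    return AngularProfile(
        angles_deg=angles,
        intensities_hu=np.asarray(vals, dtype=np.float64),
        radius_mm=radius_mm,
        center_world=center,
        e1=e1,
        e2=e2,
    )


def mean_angular_profile(
    ct: CTVolume,
    traj: Trajectory,
    center,
    radii_mm=(2.0, 2.5, 3.0, 3.5, 4.0),
    n_angles: int = 360,
    axial_offsets_mm=(-1.0, -0.5, 0.0, 0.5, 1.0),
) -> AngularProfile:
    """Angular profile averaged over a thin cylindrical shell.

    Averages the circle profile over several radii and small axial offsets
    around ``center``. The streak artifacts extend radially and axially, so
    this keeps the angular signal while averaging voxel noise over many more
    independent voxels than a single circle touches — the phase of the
    circular harmonics (hence the detected orientation) is noise-limited on
    one circle at clinical noise levels.

    The returned profile carries the central circle's center and the mean
    radius.
    """
    center = np.asarray(center, dtype=np.float64)
    acc = None
    for dt in axial_offsets_mm:
        c = center + dt * traj.unit_dir
        for r in radii_mm:
            p = angular_profile(ct, traj, c, r, n_angles)
            acc = p.intensities_hu if acc is None else acc + p.intensities_hu
    n = len(radii_mm) * len(axial_offsets_mm)
    e1, e2 = perpendicular_frame(traj.unit_dir)
    return AngularProfile(
        angles_deg=np.arange(n_angles) * (360.0 / n_angles),
        intensities_hu=acc / n,
        radius_mm=float(np.mean(radii_mm)),
        center_world=center,
        e1=e1,
        e2=e2,
    )


def _harmonic(profile: AngularProfile, k: int) -> complex:
    """Complex k-th circular harmonic sum of the profile."""
    rad = np.radians(profile.angles_deg)
    return complex(np.sum(profile.intensities_hu * np.exp(1j * k * rad)))


def second_harmonic_amplitude(profile: AngularProfile) -> float:
    """Peak-to-center amplitude of the 180-degree-periodic component, in HU."""
    n = len(profile.angles_deg)
    return 2.0 * abs(_harmonic(profile, 2)) / n


def third_harmonic_amplitude(profile: AngularProfile) -> float:
    """Amplitude of the 120-degree-periodic component (dark-star signature)."""
    n = len(profile.angles_deg)
    return 2.0 * abs(_harmonic(profile, 3)) / n


def candidate_orientations(
    profile: AngularProfile,
    spec: LeadSpec,
    min_amplitude_hu: float = 10.0,
) -> CandidatePair:
    """Derive the two inverse candidate orientations from a marker profile.

    The dark-streak axis minimizes the 180-degree-periodic component of the
    profile: with c2 the second circular harmonic, the streak axis is
    ``arg(-c2)/2`` (the angle pair where intensity is lowest modulo 180).
    The candidate facing angle adds the lead's configured streak-to-face
    offset.  A second-harmonic amplitude below ``min_amplitude_hu`` means no
    usable marker artifact (typically: polar angle too large or the wrong
    level) and raises :class:`NoArtifactError`.
    """
    n = len(profile.angles_deg)
    c2 = _harmonic(profile, 2)
    amplitude = 2.0 * abs(c2) / n
    if amplitude < min_amplitude_hu:
        raise NoArtifactError(
            f"second-harmonic amplitude {amplitude:.2f} HU below "
            f"{min_amplitude_hu} HU: no usable marker artifact"
        )
    theta_streak = np.degrees(np.angle(-c2)) / 2.0 % 180.0
    theta = (theta_streak + spec.marker_streak_offset_deg) % 180.0
    # quantize to a dyadic grid (~1e-11 deg) so theta + 180 is exactly
    # representable and the inverse-pair separation is exactly 180 degrees
    theta = round(theta * 2**36) / 2**36

    # residual RMS after removing harmonics 0-2 -> quality ratio
    rad = np.radians(profile.angles_deg)
    resid = profile.intensities_hu.astype(np.float64).copy()
    for k in range(3):
        ck = np.sum(resid * np.exp(1j * k * rad)) / n
        basis = np.exp(1j * k * rad)
        resid = resid - (2.0 if k else 1.0) * np.real(np.conj(ck) * basis)
    rms = float(np.sqrt(np.mean(resid**2)))
    quality = amplitude / rms if rms > 1e-12 else float("inf")
    return CandidatePair(
        theta_deg=float(theta),
        second_harmonic_amplitude=float(amplitude),
        quality=quality,
    )


def select_slice(
    ct: CTVolume,
    traj: Trajectory,
    nominal_center,
    harmonic: int = 2,
    search_mm: float = 1.5,
    step_mm: float = 0.25,
    radius_mm: float = 3.0,
    n_angles: int = 360,
    min_amplitude_hu: float = 10.0,
    radii_mm=None,
    axial_offsets_mm=(0.0,),
) -> tuple[np.ndarray, float]:
    """Auto-select the artifact slice along the lead axis.

    Scans axial offsets in ``[-search_mm, +search_mm]`` around a nominal
    level center and returns the center (and amplitude) maximizing the given
    circular-harmonic amplitude of the angular profile. Ties break toward
    offset zero; an argmax at the search boundary emits a truncated-search
    warning.  When ``radii_mm`` is given, the shell-averaged profile of
    :func:`mean_angular_profile` is scored instead of a single circle.
    """
    nominal_center = np.asarray(nominal_center, dtype=np.float64)
    offsets = np.arange(-search_mm, search_mm + step_mm / 2, step_mm)
    # order by |offset| so ties resolve toward the nominal center
    order = np.argsort(np.abs(offsets), kind="stable")
    best_amp, best_t = -np.inf, 0.0

    def amp_fn(prof):
        return 2.0 * abs(_harmonic(prof, harmonic)) / len(prof.angles_deg)

    for t in offsets[order]:
        center = nominal_center + t * traj.unit_dir
        if radii_mm is None:
            prof = angular_profile(ct, traj, center, radius_mm, n_angles)
        else:
            prof = mean_angular_profile(
                ct, traj, center, radii_mm, n_angles, axial_offsets_mm
            )
        amp = amp_fn(prof)
        if amp > best_amp:
            best_amp, best_t = amp, float(t)
    if best_amp < min_amplitude_hu:
        raise NoArtifactError(
            f"no offset in +/-{search_mm} mm reaches the minimum "
            f"harmonic-{harmonic} amplitude of {min_amplitude_hu} HU"
        )
    if min_amplitude_hu > 0 and abs(abs(best_t) - search_mm) < 1e-9:
        warnings.warn(
            "artifact amplitude still increasing at the slice-search boundary; "
            "the selected slice may be truncated",
            stacklevel=2,
        )
    return nominal_center + best_t * traj.unit_dir, best_amp


def select_marker_slice(
    ct: CTVolume,
    traj: Trajectory,
    spec: LeadSpec,
    nominal_center,
    **kwargs,
) -> np.ndarray:
    """Refined marker-center world point (maximal 180-degree streak signal)."""
    center, _ = select_slice(ct, traj, nominal_center, harmonic=2, **kwargs)
    return center


def star_similarity(
    profile: AngularProfile,
    theta_deg: float,
    spec: LeadSpec,
    window_deg: float = 15.0,
) -> float:
    """Similarity between observed contact-level streaks and a solution's template.

    Under solution ``theta`` the three one-sided dark-star streaks are
    expected at ``theta + star_gap_offset + 60 + 120*m`` (m = 0, 1, 2), the
    inter-segment gap bearings. The score is the mean profile intensity
    minus the mean intensity inside windows of half-width ``window_deg``
    around the expected bearings, normalized by the profile's standard
    deviation: darker-than-average intensity at the expected streaks gives a
    larger score.  By construction the score is exactly 120-degree periodic
    in ``theta``.
    """
    intens = profile.intensities_hu
    sd = float(np.std(intens))
    if sd < 1e-12:
        return 0.0
    expected = theta_deg + spec.star_gap_offset_deg + 60.0 + 120.0 * np.arange(3)
    in_window = np.zeros(len(intens), dtype=bool)
    for phi in expected:
        in_window |= np.abs(ang_diff_deg(profile.angles_deg, phi)) <= window_deg
    if not in_window.any():
        return 0.0
    return float((np.mean(intens) - np.mean(intens[in_window])) / sd)
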