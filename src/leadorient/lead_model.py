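"""Directional-lead geometry, trajectory refinement and polar-angle gating.

A directional DBS lead is modelled as a straight segment: the tip, two
segmented (three-contact) levels a few millimetres above it, and an
asymmetric stereotactic marker band further up.  The user supplies two
world-coordinate points on the trajectory; the true centerline is then
refined from the hyperdense metal artifact in the CT, because orientation
detection samples sub-millimetre circles around the axis and a lateral error
of a few tenths of a millimetre already biases the center-of-mass methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateTrajectoryError,
    InsufficientArtifactError,
)
from .volume_io import CTVolume, voxel_to_world, world_to_voxel


def _norm_angle_half_open(a: float) -> float:
    """Normalize an angle in degrees to (-180, 180]."""
    a = float(a) % 360.0
    if a > 180.0:
        a -= 360.0
    return a


@dataclass(frozen=True)
class LeadSpec:
    """Geometry of a directional lead, all distances from the physical tip.

    ``marker_streak_offset_deg`` is the angle between the dark-streak axis of
    the marker artifact and the marker's facing direction;
    ``star_gap_offset_deg`` is the offset of the first expected dark-star
    streak from the facing direction (streaks sit at the inter-segment gaps,
    60 degrees from the facing contact by default).
    """

    name: str = "cartesia"
    tip_to_marker_center_mm: float = 10.6
    tip_to_directional_levels_mm: tuple[float, ...] = (2.75, 4.75)
    marker_streak_offset_deg: float = 0.0
    star_gap_offset_deg: float = 0.0
    shaft_radius_mm: float = 0.65
    marker_half_length_mm: float = 1.5

    def __post_init__(self):
        levels = tuple(float(d) for d in self.tip_to_directional_levels_mm)
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ConfigurationError("directional levels must be strictly increasing")
        if any(d <= 0 for d in levels) or self.tip_to_marker_center_mm <= 0:
            raise ConfigurationError("level distances must be positive")
        if any(d >= self.tip_to_marker_center_mm for d in levels):
            raise ConfigurationError("directional levels must lie below the marker")
        if self.shaft_radius_mm <= 0 or self.marker_half_length_mm <= 0:
            raise ConfigurationError("radii and lengths must be positive")
        object.__setattr__(self, "tip_to_directional_levels_mm", levels)
        object.__setattr__(
            self,
            "marker_streak_offset_deg",
            _norm_angle_half_open(self.marker_streak_offset_deg),
        )
        object.__setattr__(
            self,
            "star_gap_offset_deg",
            _norm_angle_half_open(self.star_gap_offset_deg),
        )


#: Default Cartesia-style geometry profile. The marker half-extent (1.5 mm)
#: follows the published resampling span; the remaining constants are
#: configuration and should be checked against manufacturer documentation
#: before clinical-style use.
CARTESIA = LeadSpec()


@dataclass(frozen=True)
class Trajectory:
    """Tip point plus superior-pointing unit direction of the lead axis.

    The polar angle is the angle between the axis and the scanner z-axis,
    in degrees in [0, 90].
    """

    tip_world: np.ndarray
    unit_dir: np.ndarray

    def __post_init__(self):
        tip = np.asarray(self.tip_world, dtype=np.float64)
        d = np.asarray(self.unit_dir, dtype=np.float64)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise DegenerateTrajectoryError("zero-length direction vector")
        d = d / n
        if d[2] < 0:
            d = -d
        object.__setattr__(self, "tip_world", tip)
        object.__setattr__(self, "unit_dir", d)

    @property
    def polar_deg(self) -> float:
        return float(np.degrees(np.arccos(np.clip(self.unit_dir[2], -1.0, 1.0))))


def make_trajectory(tip, proximal) -> Trajectory:
    """Build a trajectory from the tip and a proximal point on the lead."""
    tip = np.asarray(tip, dtype=np.float64)
    proximal = np.asarray(proximal, dtype=np.float64)
    if np.linalg.norm(proximal - tip) < 1e-9:
        raise DegenerateTrajectoryError("tip and proximal points coincide")
    return Trajectory(tip_world=tip, unit_dir=proximal - tip)


@dataclass(frozen=True)
class RefineConfig:
    """Settings for CT-based trajectory refinement."""

    metal_threshold_hu: float = 2000.0  # reuses the marker binarization level
    roi_radius_mm: float = 4.0  # excludes skull / a second lead
    grid_mm: float = 0.15  # in-plane COM sampling grid (sub-voxel)
    tol_mm: float = 0.01
    max_iter: int = 5
    min_slices: int = 5


def level_center(traj: Trajectory, spec: LeadSpec, level) -> np.ndarray:
    """World-space center of a lead level.

    ``level`` is ``"marker"`` or an integer index into the directional
    levels (0 = most distal).
    """
    if level == "marker":
        d = spec.tip_to_marker_center_mm
    elif isinstance(level, (int, np.integer)) and not isinstance(level, bool):
        if not 0 <= level < len(spec.tip_to_directional_levels_mm):
            raise ConfigurationError(
                f"directional level index {level} out of range "
                f"(lead has {len(spec.tip_to_directional_levels_mm)} levels)"
            )
        d = spec.tip_to_directional_levels_mm[level]
    else:
        raise ConfigurationError(f"unknown lead level {level!r}")
    return traj.tip_world + d * traj.unit_dir


def check_polar(traj: Trajectory, warn_deg: float = 40.0, refuse_deg: float = 55.0) -> str:
    """Gate on the angle between lead axis and scanner z-axis.

    The marker and star artifacts degrade as the lead tilts away from the
    scanner axis: below ``warn_deg`` results are reliable ("ok"), between
    ``warn_deg`` and ``refuse_deg`` they carry reduced confidence ("warn"),
    above ``refuse_deg`` detection is refused ("refuse").
    """
    p = traj.polar_deg
    if p > refuse_deg:
        return "refuse"
    if p > warn_deg:
        return "warn"
    return "ok"


def _slicewise_coms(
    ct: CTVolume, traj: Trajectory, spec: LeadSpec, cfg: RefineConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centers of mass of suprathreshold HU on native axial slices.

    Returns (z, x_com, y_com) for every k-slice crossed by the shaft segment
    that contains metal within the ROI disk around the current trajectory
    estimate. Two deliberate choices:

    * the segment stops *below* the marker band — the marker's hyperdense
      mass is intentionally asymmetric (that asymmetry is the COM method's
      signal), so including it would bias the centerline fit toward the
      facing direction;
    * each slice's COM is computed on a sub-voxel (``grid_mm``) trilinear
      in-plane resampling rather than on raw voxel centers: the shaft cross
      section covers only a handful of voxels, and voxel-center COMs are
      aliasing-limited to a fraction of the voxel size.
    """
    from .volume_io import sample_trilinear  # local to avoid cycle at import

    shaft_len = spec.tip_to_marker_center_mm - spec.marker_half_length_mm
    seg_lo = traj.tip_world
    seg_hi = traj.tip_world + shaft_len * traj.unit_dir
    k_lo = world_to_voxel(ct, seg_lo)[2]
    k_hi = world_to_voxel(ct, seg_hi)[2]
    k0 = max(int(np.ceil(min(k_lo, k_hi))), 0)
    k1 = min(int(np.floor(max(k_lo, k_hi))), ct.shape[2] - 1)
    if k1 < k0:
        raise InsufficientArtifactError("lead segment does not cross the volume")

    r = cfg.roi_radius_mm
    n_grid = int(round(2 * r / cfg.grid_mm)) + 1
    gx, gy = np.meshgrid(
        np.linspace(-r, r, n_grid), np.linspace(-r, r, n_grid), indexing="ij"
    )
    in_disk = (gx**2 + gy**2) <= r**2
    gx, gy = gx[in_disk], gy[in_disk]

    uz = traj.unit_dir[2]
    zs, xs, ys = [], [], []
    for k in range(k0, k1 + 1):
        z_k = voxel_to_world(ct, np.array([0.0, 0.0, float(k)]))[2]
        # trajectory intersection with this axial plane
        t = (z_k - traj.tip_world[2]) / uz
        if t < 0 or t > shaft_len / uz:
            continue
        c = traj.tip_world + t * traj.unit_dir
        pts = np.column_stack(
            [c[0] + gx, c[1] + gy, np.full(gx.size, z_k)]
        )
        vals = np.asarray(sample_trilinear(ct, pts))
        mask = vals > cfg.metal_threshold_hu
        # a tilted lead puts marker-band voxels into the upper slices'
        # in-plane ROI; keep only samples whose along-axis coordinate is
        # below the marker band
        axial = (pts - traj.tip_world) @ traj.unit_dir
        mask &= axial <= shaft_len
        if not mask.any():
            continue
        com = pts[mask].mean(axis=0)
        zs.append(z_k)
        xs.append(com[0])
        ys.append(com[1])
    return np.array(zs), np.array(xs), np.array(ys)


def refine_trajectory(
    ct: CTVolume, init: Trajectory, spec: LeadSpec = CARTESIA,
    cfg: RefineConfig = RefineConfig(),
) -> Trajectory:
    """Refine a trajectory from the lead's hyperdense CT artifact.

    For each axial slice crossed by the tip-to-marker segment, the center of
    mass of metal voxels (> ``metal_threshold_hu``) within a cylinder of
    ``roi_radius_mm`` around the current estimate is computed; ordinary
    least-squares lines x(z) and y(z) are fitted and re-expressed as a
    trajectory whose tip keeps the initial tip's z-coordinate. The step is
    iterated until the tip moves less than ``tol_mm`` or ``max_iter`` is
    reached.
    """
    traj = init
    for _ in range(cfg.max_iter):
        z, x, y = _slicewise_coms(ct, traj, spec, cfg)
        if len(z) < cfg.min_slices:
            raise InsufficientArtifactError(
                f"only {len(z)} slices contain metal above "
                f"{cfg.metal_threshold_hu} HU (need {cfg.min_slices})"
            )
        mx, bx = np.polyfit(z, x, 1)
        my, by = np.polyfit(z, y, 1)
        z0 = traj.tip_world[2]
        new_tip = np.array([mx * z0 + bx, my * z0 + by, z0])
        new_dir = np.array([mx, my, 1.0])
        moved = float(np.linalg.norm(new_tip - traj.tip_world))
        traj = Trajectory(tip_world=new_tip, unit_dir=new_dir)
        if moved < cfg.tol_mm:
            break
    return traj
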