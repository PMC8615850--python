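"""Resolution of the 180-degree orientation ambiguity.

The marker streak pattern is symmetric, so candidate detection yields two
inverse solutions (theta, theta + 180).  Four independent methods pick one:

* **COM** — the thresholded (> 2000 HU) marker mass on a slice perpendicular
  to the lead axis has a center of mass that deviates from the geometric
  lead center toward the true facing direction, because the marker band is
  asymmetric.
* **COMsagittal** — the same decision on an "in line" slice containing the
  lead axis and the candidate axis, spanning the whole marker vertically.
* **ASM** — asymmetric sampling of the marker: the bright peak of the
  angular intensity profile is higher toward the true orientation than
  toward the inverse one.
* **STARS** — the one-sided "dark star" streaks at the segmented-contact
  levels match the streak template of the true solution better than that of
  the inverse solution.

COM was the most reliable method on patient data, so the final orientation
is based on it alone; the other methods serve as cross-checks and any
disagreement is flagged for review.  Decision margins are normalized (by a
deviation scale in mm, or the profile standard deviation) so a single
``margin_floor`` defines degeneracy across methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DetectionConfig
from .errors import LevelOutOfVolumeError, NoMarkerError, UnresolvedAmbiguityError
from .lead_model import LeadSpec, Trajectory, level_center
from .orientation_core import (
    AngularProfile,
    CandidatePair,
    ang_diff_deg,
    angular_profile,
    mean_angular_profile,
    perpendicular_frame,
    select_slice,
    star_similarity,
)
from .volume_io import CTVolume, PlaneSpec, resample_plane, world_to_voxel


@dataclass(frozen=True)
class MethodResult:
    """One method's choice between the two inverse solutions."""

    method: str
    chosen_theta_deg: float
    margin: float
    degenerate: bool

    def agrees_with(self, theta_deg: float) -> bool:
        return abs(float(ang_diff_deg(self.chosen_theta_deg, theta_deg))) < 1e-9


@dataclass(frozen=True)
class Resolution:
    """Combined decision of the four methods."""

    final_theta_deg: float
    methods: tuple[MethodResult, ...]
    mismatch: bool
    confidence: str  # "ok" | "reduced"

    def method(self, name: str) -> MethodResult:
        for m in self.methods:
            if m.method == name:
                return m
        raise KeyError(name)


def _pick(
    method: str,
    pair: CandidatePair,
    score_theta: float,
    score_partner: float,
    margin: float,
    floor: float,
) -> MethodResult:
    """Choose the candidate with the larger score; flag small margins."""
    if score_theta >= score_partner:
        chosen = pair.theta_deg % 360.0
    else:
        chosen = pair.partner_deg % 360.0
    return MethodResult(
        method=method,
        chosen_theta_deg=float(chosen),
        margin=float(abs(margin)),
        degenerate=bool(abs(margin) < floor),
    )


def _binarized_com(slice2d, threshold_hu: float) -> tuple[np.ndarray, int]:
    """Pixel-index center of mass of suprathreshold pixels."""
    mask = slice2d.values > threshold_hu
    n = int(mask.sum())
    if n == 0:
        raise NoMarkerError(
            f"no pixels above {threshold_hu} HU in the resampled marker slice"
        )
    ii, jj = np.nonzero(mask)
    return np.array([ii.mean(), jj.mean()]), n


def _marker_volume_com(
    ct: CTVolume,
    traj: Trajectory,
    marker_center: np.ndarray,
    e1: np.ndarray,
    e2: np.ndarray,
    cfg: DetectionConfig,
) -> np.ndarray:
    """World COM of the marker's thresholded hyperdense volume.

    The marker band extends axially, so the center of mass is taken over a
    stack of perpendicular 0.1 mm slices covering the whole band rather
    than a single zero-thickness cut: a single cut through a sub-voxel-thin
    metal band is dominated by voxel-sampling aliasing at large polar
    angles, while the slab average is not.
    """
    offsets = np.arange(
        -cfg.com_slab_half_mm,
        cfg.com_slab_half_mm + cfg.com_slab_step_mm / 2,
        cfg.com_slab_step_mm,
    )
    pos_sum = np.zeros(3)
    n_total = 0
    for t in offsets:
        plane = PlaneSpec(
            center=marker_center + t * traj.unit_dir,
            basis_u=e1,
            basis_v=e2,
            extent_mm=(cfg.com_extent_mm, cfg.com_extent_mm),
            resolution_mm=cfg.resample_resolution_mm,
        )
        sl = resample_plane(ct, plane, fill=cfg.fill_hu)
        mask = sl.values > cfg.threshold_hu
        n = int(mask.sum())
        if n == 0:
            continue
        ii, jj = np.nonzero(mask)
        pts = sl.pixel_to_world(ii.astype(float), jj.astype(float))
        pos_sum += np.asarray(pts).reshape(-1, 3).sum(axis=0)
        n_total += n
    if n_total == 0:
        raise NoMarkerError(
            f"no voxels above {cfg.threshold_hu} HU in the marker slab"
        )
    return pos_sum / n_total


def com_method(
    ct: CTVolume,
    traj: Trajectory,
    marker_center,
    pair: CandidatePair,
    cfg: DetectionConfig = DetectionConfig(),
) -> MethodResult:
    """Center-of-mass method on the marker's hyperdense volume.

    Resamples perpendicular slices covering the marker band (0.1 mm in-plane
    resolution), binarizes at 2000 HU, and compares the direction in which
    the center of mass deviates from the lead axis against the two candidate
    bearings; the closer one wins.
    """
    marker_center = np.asarray(marker_center, dtype=np.float64)
    e1, e2 = perpendicular_frame(traj.unit_dir)
    com_world = _marker_volume_com(ct, traj, marker_center, e1, e2, cfg)

    # deviation of the COM from the lead axis, projected into the
    # perpendicular plane
    d3 = com_world - traj.tip_world
    d3 = d3 - (d3 @ traj.unit_dir) * traj.unit_dir
    d = d3
    d_norm = float(np.linalg.norm(d))
    sign = 1.0 if cfg.com_points_toward_face else -1.0
    if d_norm < 1e-15:
        return MethodResult("COM", pair.theta_deg % 360.0, 0.0, True)
    d_hat = sign * d / d_norm

    def bearing(theta):
        t_ = np.radians(theta)
        return np.cos(t_) * e1 + np.sin(t_) * e2

    a_theta = float(bearing(pair.theta_deg) @ d_hat)
    a_partner = float(bearing(pair.partner_deg) @ d_hat)
    margin = abs(a_theta - a_partner) / 2.0 * (d_norm / cfg.deviation_scale_mm)
    res = _pick("COM", pair, a_theta, a_partner, margin, cfg.margin_floor)
    if d_norm < cfg.min_deviation_mm:
        res = MethodResult(res.method, res.chosen_theta_deg, res.margin, True)
    return res


def com_deviation(
    ct: CTVolume,
    traj: Trajectory,
    marker_center,
    cfg: DetectionConfig = DetectionConfig(),
) -> tuple[float, float]:
    """(bearing_deg, magnitude_mm) of the marker-volume COM deviation.

    Diagnostic companion of :func:`com_method`; the bearing uses the same
    0 = anterior, counterclockwise-from-superior convention as candidates.
    """
    marker_center = np.asarray(marker_center, dtype=np.float64)
    e1, e2 = perpendicular_frame(traj.unit_dir)
    com_world = _marker_volume_com(ct, traj, marker_center, e1, e2, cfg)
    d3 = com_world - traj.tip_world
    d3 = d3 - (d3 @ traj.unit_dir) * traj.unit_dir
    bearing = float(np.degrees(np.arctan2(d3 @ e2, d3 @ e1)) % 360.0)
    return bearing, float(np.linalg.norm(d3))


def com_sagittal_method(
    ct: CTVolume,
    traj: Trajectory,
    marker_center,
    pair: CandidatePair,
    cfg: DetectionConfig = DetectionConfig(),
) -> MethodResult:
    """Center-of-mass method on an in-line ("sagittal") marker slice.

    The slice contains the lead axis and the candidate axis: it spans the
    marker center +/- 1.5 mm along the lead and +/- ``sag_half_width_mm``
    along the in-plane bearing of candidate theta, resampled at 0.1 mm.  The
    sign of the thresholded center of mass's transverse component decides:
    toward theta -> theta, away -> partner.
    """
    marker_center = np.asarray(marker_center, dtype=np.float64)
    e1, e2 = perpendicular_frame(traj.unit_dir)
    t_ = np.radians(pair.theta_deg)
    v = np.cos(t_) * e1 + np.sin(t_) * e2  # toward candidate theta
    plane = PlaneSpec(
        center=marker_center,
        basis_u=traj.unit_dir,
        basis_v=v,
        extent_mm=(2 * cfg.sag_half_length_mm, 2 * cfg.sag_half_width_mm),
        resolution_mm=cfg.resample_resolution_mm,
    )
    sl = resample_plane(ct, plane, fill=cfg.fill_hu)
    com_px, _ = _binarized_com(sl, cfg.threshold_hu)
    com_world = np.asarray(sl.pixel_to_world(com_px[0], com_px[1])).reshape(3)
    sign = 1.0 if cfg.com_points_toward_face else -1.0
    v_comp = sign * float((com_world - marker_center) @ v)
    margin = abs(v_comp) / cfg.deviation_scale_mm
    res = _pick("COMsagittal", pair, v_comp, -v_comp, margin, cfg.margin_floor)
    if abs(v_comp) < cfg.min_deviation_mm:
        res = MethodResult(res.method, res.chosen_theta_deg, res.margin, True)
    return res


def asm_method(
    profile: AngularProfile,
    pair: CandidatePair,
    cfg: DetectionConfig = DetectionConfig(),
) -> MethodResult:
    """Asymmetric sampling of the marker.

    Intensities within the marker artifact are greater toward the true
    orientation, so the heights of the two bright peaks of the angular
    profile are compared: peak height h(theta) is the maximum intensity
    within +/- ``peak_window_deg`` of the bearing, and the candidate with
    the larger peak wins. The margin is the height difference in units of
    the profile standard deviation.
    """
    intens = profile.intensities_hu

    def peak(theta):
        m = np.abs(ang_diff_deg(profile.angles_deg, theta)) <= cfg.peak_window_deg
        return float(intens[m].max()) if m.any() else float("-inf")

    h_theta = peak(pair.theta_deg)
    h_partner = peak(pair.partner_deg)
    sd = float(np.std(intens))
    margin = abs(h_theta - h_partner) / sd if sd > 1e-12 else 0.0
    return _pick("ASM", pair, h_theta, h_partner, margin, cfg.margin_floor)


def stars_method(
    ct: CTVolume,
    traj: Trajectory,
    spec: LeadSpec,
    pair: CandidatePair,
    cfg: DetectionConfig = DetectionConfig(),
) -> MethodResult:
    """Dark-star streak-template comparison at the segmented-contact levels.

    For each directional level the best artifact slice is auto-selected by
    maximizing the 120-degree-periodic third-harmonic amplitude, then the
    streak-similarity score of each candidate is computed and summed across
    levels; the larger total wins.
    """
    s_theta, s_partner = 0.0, 0.0
    n_levels = 0
    for idx in range(len(spec.tip_to_directional_levels_mm)):
        nominal = level_center(traj, spec, idx)
        vox = world_to_voxel(ct, nominal)
        if np.any(vox < 0) or np.any(vox > np.array(ct.shape) - 1):
            continue
        center, _ = select_slice(
            ct,
            traj,
            nominal,
            harmonic=3,
            search_mm=cfg.slice_search_mm,
            step_mm=cfg.slice_search_step_mm,
            radius_mm=cfg.profile_radius_mm,
            n_angles=cfg.n_angles,
            min_amplitude_hu=0.0,  # degenerate handling is by margin, not error
            radii_mm=cfg.profile_radii_mm,
            axial_offsets_mm=cfg.star_axial_offsets_mm,
        )
        prof = mean_angular_profile(
            ct, traj, center, cfg.profile_radii_mm, cfg.n_angles,
            cfg.star_axial_offsets_mm,
        )
        s_theta += star_similarity(prof, pair.theta_deg, spec, cfg.star_window_deg)
        s_partner += star_similarity(prof, pair.partner_deg, spec, cfg.star_window_deg)
        n_levels += 1
    if n_levels == 0:
        raise LevelOutOfVolumeError(
            "no directional contact level lies inside the CT volume"
        )
    margin = abs(s_theta - s_partner)
    return _pick("STARS", pair, s_theta, s_partner, margin, cfg.margin_floor)


#: Fallback order when COM is degenerate.
_FALLBACK_ORDER = ("COMsagittal", "STARS", "ASM")


def resolve(
    ct: CTVolume,
    traj: Trajectory,
    spec: LeadSpec,
    marker_center,
    pair: CandidatePair,
    cfg: DetectionConfig = DetectionConfig(),
    marker_profile: AngularProfile | None = None,
) -> Resolution:
    """Run all four methods and combine them into a final orientation.

    The final orientation is the COM method's choice.  If COM is degenerate
    the fallback cascade COMsagittal -> STARS -> ASM applies and confidence
    drops to "reduced".  A mismatch flag is set when any non-degenerate
    method disagrees with the final choice.  If all four methods are
    degenerate the ambiguity is unresolved and an error carrying both
    candidates is raised.
    """
    if marker_profile is None:
        marker_profile = mean_angular_profile(
            ct, traj, marker_center, cfg.profile_radii_mm, cfg.n_angles,
            cfg.marker_axial_offsets_mm,
        )
    results = (
        com_method(ct, traj, marker_center, pair, cfg),
        com_sagittal_method(ct, traj, marker_center, pair, cfg),
        asm_method(marker_profile, pair, cfg),
        stars_method(ct, traj, spec, pair, cfg),
    )
    by_name = {r.method: r for r in results}
    confidence = "ok"
    final = None
    if not by_name["COM"].degenerate:
        final = by_name["COM"].chosen_theta_deg
    else:
        for name in _FALLBACK_ORDER:
            if not by_name[name].degenerate:
                final = by_name[name].chosen_theta_deg
                confidence = "reduced"
                break
    if final is None:
        raise UnresolvedAmbiguityError(
            "all ambiguity-resolution methods are degenerate; both inverse "
            f"candidates remain: {pair.theta_deg:.2f} / {pair.partner_deg:.2f} deg",
            candidates=(pair.theta_deg, pair.partner_deg),
        )
    mismatch = any(
        not r.degenerate and not r.agrees_with(final) for r in results
    )
    return Resolution(
        final_theta_deg=float(final % 360.0),
        methods=results,
        mismatch=mismatch,
        confidence=confidence,
    )
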