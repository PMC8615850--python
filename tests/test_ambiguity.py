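"""The four 180-degree ambiguity-resolution methods and the combination policy."""

import numpy as np
import pytest

from leadorient.ambiguity import (
    asm_method,
    com_method,
    com_sagittal_method,
    resolve,
    stars_method,
)
from leadorient.config import DetectionConfig
from leadorient.errors import UnresolvedAmbiguityError
from leadorient.lead_model import CARTESIA, make_trajectory
from leadorient.orientation_core import AngularProfile, CandidatePair
from leadorient.phantom import PhantomSpec, generate_phantom, hu_field
from leadorient.volume_io import CTVolume


def angdiff(a, b):
    return abs((a - b + 180.0) % 360.0 - 180.0)


def make_pair(theta):
    return CandidatePair(theta_deg=theta % 180.0, second_harmonic_amplitude=50.0,
                         quality=5.0)


def make_profile(vals):
    n = len(vals)
    return AngularProfile(
        angles_deg=np.arange(n) * (360.0 / n),
        intensities_hu=np.asarray(vals, dtype=float),
        radius_mm=3.0,
        center_world=np.zeros(3),
        e1=np.array([0.0, 1.0, 0.0]),
        e2=np.array([-1.0, 0.0, 0.0]),
    )


def blob_volume(blob_bearing_deg=None):
    """Vertical metal cylinder at the volume center, optional off-center blob.

    The blob sits at 2 mm from the axis at the marker level, at the given
    bearing (0 = anterior = +Y, counterclockwise from superior).
    """
    nx, nz = 80, 100
    vox = np.full((nx, nx, nz), 40.0)
    aff = np.diag([0.5, 0.5, 0.5, 1.0])
    aff[:3, 3] = [-20.0 + 0.25, -20.0 + 0.25, -5.0 + 0.25]
    ii = np.arange(nx) * 0.5 + aff[0, 3]
    gx, gy = np.meshgrid(ii, ii, indexing="ij")
    shaft = (gx**2 + gy**2) <= 0.65**2
    kz = np.arange(nz) * 0.5 + aff[2, 3]
    zmask = (kz >= 0.0) & (kz <= 12.0)
    for k in np.nonzero(zmask)[0]:
        vox[:, :, k][shaft] = 3000.0
    if blob_bearing_deg is not None:
        b = np.radians(blob_bearing_deg)
        bx, by = -2.0 * np.sin(b), 2.0 * np.cos(b)  # bearing 0 = +Y, CCW to -X
        blob = ((gx - bx) ** 2 + (gy - by) ** 2) <= 0.6**2
        for k in np.nonzero((kz >= 9.6) & (kz <= 11.6))[0]:
            vox[:, :, k][blob] = 3000.0
    return CTVolume(vox, aff)


VERT_TRAJ = make_trajectory((0.0, 0.0, 0.0), (0.0, 0.0, 10.0))
MARKER = np.array([0.0, 0.0, 10.6])


class TestComMethod:
    def test_off_center_blob_decides(self):
        ct = blob_volume(blob_bearing_deg=30.0)
        res = com_method(ct, VERT_TRAJ, MARKER, make_pair(30.0))
        assert res.chosen_theta_deg == pytest.approx(30.0)
        assert not res.degenerate

    def test_symmetric_mass_is_degenerate(self):
        ct = blob_volume(blob_bearing_deg=None)
        res = com_method(ct, VERT_TRAJ, MARKER, make_pair(30.0))
        assert res.degenerate

    def test_phantom_truth(self):
        spec = PhantomSpec(yaw_true_deg=75.0, polar_deg=20.0,
                           tilt_azimuth_deg=30.0, noise_sigma_hu=15.0, seed=7)
        ct, truth = generate_phantom(spec)
        tip = np.asarray(truth.tip_world)
        traj = make_trajectory(tip, tip + 10 * np.asarray(truth.unit_dir))
        res = com_method(ct, traj, np.asarray(truth.marker_center_world),
                         make_pair(75.0))
        assert angdiff(res.chosen_theta_deg, 75.0) < 1e-9

    def test_margin_invariant_under_volume_translation(self):
        ct = blob_volume(blob_bearing_deg=30.0)
        res = com_method(ct, VERT_TRAJ, MARKER, make_pair(30.0))
        aff = ct.affine.copy()
        shift = np.array([7.0, -3.0, 2.0])
        aff[:3, 3] += shift
        moved = CTVolume(ct.voxels, aff)
        traj2 = make_trajectory(shift, shift + np.array([0.0, 0.0, 10.0]))
        res2 = com_method(moved, traj2, MARKER + shift, make_pair(30.0))
        assert res2.margin == pytest.approx(res.margin, rel=1e-9)

    def test_swapped_pair_gives_same_world_bearing(self):
        ct = blob_volume(blob_bearing_deg=210.0)
        a = com_method(ct, VERT_TRAJ, MARKER, make_pair(30.0))
        swapped = CandidatePair(theta_deg=210.0, second_harmonic_amplitude=50.0,
                                quality=5.0)
        b = com_method(ct, VERT_TRAJ, MARKER, swapped)
        assert angdiff(a.chosen_theta_deg, b.chosen_theta_deg) < 1e-9


class TestComSagittalMethod:
    def test_blob_toward_candidate_chooses_it(self):
        ct = blob_volume(blob_bearing_deg=30.0)
        res = com_sagittal_method(ct, VERT_TRAJ, MARKER, make_pair(30.0))
        assert res.chosen_theta_deg == pytest.approx(30.0)

    def test_blob_away_from_candidate_chooses_partner(self):
        ct = blob_volume(blob_bearing_deg=210.0)
        res = com_sagittal_method(ct, VERT_TRAJ, MARKER, make_pair(30.0))
        assert res.chosen_theta_deg == pytest.approx(210.0)

    def test_symmetric_mass_is_degenerate(self):
        ct = blob_volume(blob_bearing_deg=None)
        res = com_sagittal_method(ct, VERT_TRAJ, MARKER, make_pair(30.0))
        assert res.degenerate


class TestAsmMethod:
    def _two_peak_profile(self, theta=40.0, a1=20.0, a2=50.0):
        alpha = np.radians(np.arange(360.0))
        t = np.radians(theta)
        return make_profile(100.0 + a1 * np.cos(alpha - t)
                            + a2 * np.cos(2 * (alpha - t)))

    def test_higher_peak_wins_closed_form(self):
        # the first harmonic raises the peak at 40 over the one at 220
        res = asm_method(self._two_peak_profile(), make_pair(40.0))
        assert res.chosen_theta_deg == pytest.approx(40.0)
        assert not res.degenerate

    def test_zero_first_harmonic_is_degenerate(self):
        res = asm_method(self._two_peak_profile(a1=0.0), make_pair(40.0))
        assert res.degenerate

    def test_margin_invariant_under_affine_rescaling(self):
        prof = self._two_peak_profile()
        base = asm_method(prof, make_pair(40.0))
        rescaled = make_profile(2.5 * prof.intensities_hu - 300.0)
        res = asm_method(rescaled, make_pair(40.0))
        assert res.margin == pytest.approx(base.margin, rel=1e-9)

    def test_phantom_truth(self, tilted_noisy_phantom):
        from leadorient.orientation_core import mean_angular_profile

        ct, truth = tilted_noisy_phantom
        tip = np.asarray(truth.tip_world)
        traj = make_trajectory(tip, tip + 10 * np.asarray(truth.unit_dir))
        prof = mean_angular_profile(ct, traj, np.asarray(truth.marker_center_world))
        res = asm_method(prof, make_pair(truth.yaw_true_deg))
        assert angdiff(res.chosen_theta_deg, truth.yaw_true_deg) < 1e-9


class TestStarsMethod:
    def test_phantom_truth(self):
        spec = PhantomSpec(yaw_true_deg=120.0, polar_deg=10.0, noise_sigma_hu=0.0,
                           seed=0)
        ct, truth = generate_phantom(spec)
        tip = np.asarray(truth.tip_world)
        traj = make_trajectory(tip, tip + 10 * np.asarray(truth.unit_dir))
        res = stars_method(ct, traj, CARTESIA, make_pair(120.0))
        assert res.chosen_theta_deg == pytest.approx(120.0)
        assert not res.degenerate

    def test_artifact_free_levels_degenerate(self):
        spec = PhantomSpec(yaw_true_deg=120.0, polar_deg=0.0, noise_sigma_hu=0.0,
                           a3_hu=0.0, seed=0)
        ct, truth = generate_phantom(spec)
        tip = np.asarray(truth.tip_world)
        traj = make_trajectory(tip, tip + 10 * np.asarray(truth.unit_dir))
        res = stars_method(ct, traj, CARTESIA, make_pair(120.0))
        assert res.degenerate


class TestResolve:
    def _detect(self, ct, truth, cfg=DetectionConfig()):
        from leadorient.lead_model import level_center, refine_trajectory
        from leadorient.orientation_core import (
            anchor_axis,
            candidate_orientations,
            mean_angular_profile,
            select_marker_slice,
        )

        tip = np.asarray(truth.tip_world)
        traj = refine_trajectory(ct, make_trajectory(
            tip, tip + 10 * np.asarray(truth.unit_dir)))
        traj = anchor_axis(ct, traj, CARTESIA)
        nominal = level_center(traj, CARTESIA, "marker")
        center = select_marker_slice(ct, traj, CARTESIA, nominal,
                                     radii_mm=cfg.profile_radii_mm,
                                     axial_offsets_mm=cfg.marker_axial_offsets_mm)
        prof = mean_angular_profile(ct, traj, center, cfg.profile_radii_mm,
                                    cfg.n_angles, cfg.marker_axial_offsets_mm)
        pair = candidate_orientations(prof, CARTESIA)
        return traj, center, prof, pair

    def test_agreement_has_no_mismatch(self, tilted_noisy_phantom):
        ct, truth = tilted_noisy_phantom
        traj, center, prof, pair = self._detect(ct, truth)
        res = resolve(ct, traj, CARTESIA, center, pair, marker_profile=prof)
        assert not res.mismatch
        assert res.confidence == "ok"
        assert angdiff(res.final_theta_deg, truth.yaw_true_deg) < 2.0
        assert res.final_theta_deg in (
            pair.theta_deg % 360.0, pair.partner_deg % 360.0
        )

    def test_disagreeing_asm_sets_mismatch_but_final_follows_com(self):
        # craft a volume whose first-harmonic brightness points AWAY from
        # the marker window's center-of-mass shift: ASM then disagrees
        spec = PhantomSpec(yaw_true_deg=60.0, polar_deg=0.0, noise_sigma_hu=0.0,
                           a1_hu=0.0, seed=0)
        ct, truth = generate_phantom(spec)
        base = PhantomSpec(yaw_true_deg=240.0, polar_deg=0.0, noise_sigma_hu=0.0,
                           window_angle_deg=0.0, a2_hu=0.0, a3_hu=0.0,
                           background_hu=0.0, metal_hu=2100.0, a1_hu=60.0, seed=0)
        # add only the first-harmonic artifact term of the reversed phantom
        idx = np.indices(ct.shape).astype(float).reshape(3, -1).T
        pts = idx * 0.5 + ct.affine[:3, 3]
        extra = hu_field(base, pts) - base.background_hu
        extra = np.asarray(extra).reshape(ct.shape)
        # strip the metal contributions of the helper field, keep the cosine
        extra[extra > 1000] = 0.0
        combined = CTVolume(ct.voxels + extra, ct.affine)
        traj, center, prof, pair = self._detect(combined, truth)
        res = resolve(combined, traj, CARTESIA, center, pair, marker_profile=prof)
        assert angdiff(res.final_theta_deg, 60.0) < 2.0  # COM still rules
        assert res.method("ASM").chosen_theta_deg != res.method("COM").chosen_theta_deg
        assert res.mismatch

    def test_com_degenerate_falls_back_with_reduced_confidence(self):
        # no window -> both COM methods degenerate; stars still decisive
        spec = PhantomSpec(yaw_true_deg=150.0, polar_deg=0.0, noise_sigma_hu=0.0,
                           window_angle_deg=0.0, a1_hu=0.0, seed=0)
        ct, truth = generate_phantom(spec)
        traj, center, prof, pair = self._detect(ct, truth)
        res = resolve(ct, traj, CARTESIA, center, pair, marker_profile=prof)
        assert res.method("COM").degenerate
        assert res.confidence == "reduced"
        assert angdiff(res.final_theta_deg, 150.0) < 2.0

    def test_full_symmetry_is_unresolvable(self, symmetric_phantom):
        ct, truth = symmetric_phantom
        traj, center, prof, pair = self._detect(ct, truth)
        with pytest.raises(UnresolvedAmbiguityError) as exc:
            resolve(ct, traj, CARTESIA, center, pair, marker_profile=prof)
        assert exc.value.candidates is not None
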