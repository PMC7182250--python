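"""CGM kinematic chain: frames, joint centres, angles, calibration."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import cgmsens as cs
from cgmsens import cgm
from cgmsens.datamodel import MarkerTrial, PerturbationSpec
from cgmsens.geometry import GeometryError

from conftest import rigid_transform


def pelvis_trial(lasi, rasi, lpsi, rpsi):
    return MarkerTrial(
        markers={
            "LASI": np.atleast_2d(lasi).astype(float),
            "RASI": np.atleast_2d(rasi).astype(float),
            "LPSI": np.atleast_2d(lpsi).astype(float),
            "RPSI": np.atleast_2d(rpsi).astype(float),
        },
        kind="static",
    )


class TestPelvisFrame:
    def test_canonical_pose_gives_lab_identity(self):
        trial = pelvis_trial([0, 120, 900], [0, -120, 900], [-150, 40, 900], [-150, -40, 900])
        frame = cgm.pelvis_frame(trial, 0)
        np.testing.assert_allclose(frame.origin, [0, 0, 900], atol=1e-12)
        np.testing.assert_allclose(frame.axes, np.eye(3), atol=1e-12)

    def test_equivariance_under_lab_rotation(self):
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        pts = [np.array(p, float) for p in ([0, 120, 900], [0, -120, 900], [-150, 40, 900], [-150, -40, 900])]
        frame = cgm.pelvis_frame(pelvis_trial(*pts), 0)
        frame_rot = cgm.pelvis_frame(pelvis_trial(*[R @ p for p in pts]), 0)
        np.testing.assert_allclose(frame_rot.axes, R @ frame.axes, atol=1e-9)
        np.testing.assert_allclose(frame_rot.origin, R @ frame.origin, atol=1e-9)

    def test_random_quadrilateral_orthonormal(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            pts = [rng.uniform(-200, 200, 3) for _ in range(4)]
            pts[0][1] += 250  # keep ASIS separated
            frame = cgm.pelvis_frame(pelvis_trial(*pts), 0)
            gram = frame.axes.T @ frame.axes
            np.testing.assert_allclose(gram, np.eye(3), atol=1e-9)

    def test_coincident_asis_rejected(self):
        with pytest.raises(GeometryError):
            cgm.pelvis_frame(pelvis_trial([0, 0, 900], [0, 0, 900], [-150, 40, 900], [-150, -40, 900]), 0)


class TestHipJointCentre:
    def test_davis_regression_against_independent_transcription(self):
        # independent, test-local transcription of the regression
        leg, iad, r_m = 800.0, 220.0, 6.25
        C = 0.115 * leg - 15.3
        d_at = 0.1288 * leg - 48.56
        theta, beta = 0.5, 0.314
        expected = np.array(
            [
                C * math.cos(theta) * math.sin(beta) - (d_at + r_m) * math.cos(beta),
                (iad / 2.0) - C * math.sin(theta),
                -C * math.cos(theta) * math.cos(beta) - (d_at + r_m) * math.sin(beta),
            ]
        )
        got = cgm.davis_hip_offset(leg, iad, r_m, "left")
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert got[0] < 0 and got[2] < 0  # posterior and inferior of mid-ASIS

    def test_left_right_mirror_symmetry(self, child_anthro):
        trial = pelvis_trial([0, 120, 900], [0, -120, 900], [-150, 40, 900], [-150, -40, 900])
        pelvis = cgm.pelvis_frame(trial, 0)
        left = cgm.hip_joint_centre(pelvis, child_anthro, "left")
        right = cgm.hip_joint_centre(pelvis, child_anthro, "right")
        np.testing.assert_allclose(left * [1, -1, 1], right, atol=1e-12)

    def test_translation_equivariance(self, child_anthro):
        t = np.array([10.0, -40.0, 25.0])
        trial = pelvis_trial([0, 120, 900], [0, -120, 900], [-150, 40, 900], [-150, -40, 900])
        trial_t = rigid_transform(trial, np.eye(3), t)
        hjc = cgm.hip_joint_centre(cgm.pelvis_frame(trial, 0), child_anthro, "left")
        hjc_t = cgm.hip_joint_centre(cgm.pelvis_frame(trial_t, 0), child_anthro, "left")
        np.testing.assert_allclose(hjc_t, hjc + t, atol=1e-9)

    def test_nonpositive_leg_length_rejected(self):
        with pytest.raises(ValueError):
            cgm.davis_hip_offset(0.0, 220.0, 6.25, "left")


class TestThighShankFootFrames:
    HJC = np.array([0.0, 0.0, 350.0])
    KNE = np.array([0.0, 51.25, 0.0])
    WAND = np.array([0.0, 140.0, 120.0])

    def test_straight_leg_canonical_pose(self):
        frame, kjc = cgm.thigh_frame(self.HJC, self.KNE, self.WAND, 51.25, "left")
        np.testing.assert_allclose(kjc, [0, 0, 0], atol=1e-9)
        np.testing.assert_allclose(frame.z, [0, 0, 1], atol=1e-9)
        np.testing.assert_allclose(frame.axes, np.eye(3), atol=1e-9)

    def test_wand_in_plane_displacement_leaves_frame_unchanged(self):
        frame, kjc = cgm.thigh_frame(self.HJC, self.KNE, self.WAND, 51.25, "left")
        wand2 = self.WAND + np.array([0.0, -30.0, 55.0])  # stays in x=0 coronal plane
        frame2, kjc2 = cgm.thigh_frame(self.HJC, self.KNE, wand2, 51.25, "left")
        np.testing.assert_allclose(frame2.axes, frame.axes, atol=1e-9)
        np.testing.assert_allclose(kjc2, kjc, atol=1e-9)

    def test_anterior_kne_shift_rotates_axially_origin_height_second_order(self):
        _, kjc0 = cgm.thigh_frame(self.HJC, self.KNE, self.WAND, 51.25, "left")
        heights, yaws = [], []
        for eps in (1.0, 2.0):
            frame, kjc = cgm.thigh_frame(
                self.HJC, self.KNE + [eps, 0, 0], self.WAND, 51.25, "left"
            )
            yaw = np.degrees(np.arctan2(frame.y[0], frame.y[1]))
            yaws.append(abs(yaw))
            heights.append(abs(kjc[2] - kjc0[2]))
        assert yaws[0] > 0.1  # axial (int/ext) rotation appears at first order
        assert yaws[1] / yaws[0] == pytest.approx(2.0, rel=0.05)  # ~linear in eps
        assert heights[1] / max(heights[0], 1e-12) > 3.0  # height change ~eps^2

    def test_kjc_displacement_propagates_to_ajc(self):
        ank = np.array([0.0, 36.25, -300.0])
        tib = np.array([0.0, 90.0, -200.0])
        kjc = np.array([0.0, 0.0, 0.0])
        _, ajc0 = cgm.shank_frame(kjc, ank, tib, 36.25, "left")
        _, ajc1 = cgm.shank_frame(kjc + [5.0, 0, 0], ank, tib, 36.25, "left")
        assert np.linalg.norm(ajc1 - ajc0) > 0.01  # hierarchical top-down dependence

    def test_shank_rigid_transform_equivariance(self):
        ank = np.array([0.0, 36.25, -300.0])
        tib = np.array([0.0, 90.0, -200.0])
        kjc = np.array([0.0, 0.0, 0.0])
        R = Rotation.random(random_state=3).as_matrix()
        t = np.array([100.0, -50.0, 30.0])
        frame, ajc = cgm.shank_frame(kjc, ank, tib, 36.25, "left")
        frame_t, ajc_t = cgm.shank_frame(R @ kjc + t, R @ ank + t, R @ tib + t, 36.25, "left")
        np.testing.assert_allclose(frame_t.axes, R @ frame.axes, atol=1e-9)
        np.testing.assert_allclose(ajc_t, R @ ajc + t, atol=1e-9)

    def test_flat_foot_long_axis_horizontal(self):
        ajc = np.array([0.0, 0.0, 52.0])
        toe = np.array([112.0, 0.0, 25.0])
        hee = np.array([-35.0, 0.0, 25.0])
        frame = cgm.foot_frame(ajc, toe, hee)
        assert abs(frame.z[2]) < 1e-12  # longitudinal axis has no vertical part
        np.testing.assert_allclose(frame.z, [-1, 0, 0], atol=1e-12)

    def test_toe_out_rotation_rotates_foot_frame(self):
        ajc = np.array([0.0, 0.0, 52.0])
        toe = np.array([112.0, 0.0, 25.0])
        hee = np.array([-35.0, 0.0, 25.0])
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        frame = cgm.foot_frame(ajc, toe, hee)
        frame_r = cgm.foot_frame(R @ ajc, R @ toe, R @ hee)
        np.testing.assert_allclose(frame_r.axes, R @ frame.axes, atol=1e-9)


class TestClinicalAngles:
    @pytest.mark.parametrize("joint", ["hip", "knee", "ankle"])
    @pytest.mark.parametrize("side", ["left", "right"])
    def test_clinical_mapping_roundtrip(self, joint, side):
        rng = np.random.default_rng(17)
        for _ in range(20):
            flex, add, rot = rng.uniform(-60, 60, 3)
            R = cgm.clinical_to_matrix(flex, add, rot, joint, side)
            got = cgm.cardan_angles(R, joint, side)
            np.testing.assert_allclose(got, [flex, add, rot], atol=1e-10)

    @pytest.mark.parametrize("side", ["left", "right"])
    def test_flexed_poses_read_positive_on_both_sides(self, child_subject, typical_curves, side):
        """A 30 deg hip-flexed / 40 deg knee-flexed standing pose must
        yield positive flexion with near-zero other angles."""
        static, _ = cs.generate_trial(
            child_subject,
            typical_curves,
            static_pose={"hip": (30.0, 0.0, 0.0), "knee": (40.0, 0.0, 0.0)},
        )
        neutral, _ = cs.generate_trial(child_subject, typical_curves)
        calib = cgm.static_calibration(neutral, child_subject.anthropometry)
        series = cgm.joint_angle_series(static, calib, child_subject.anthropometry, side)
        assert np.allclose(series[("hip", "flexion")], 30.0, atol=1e-6)
        assert np.allclose(series[("knee", "flexion")], 40.0, atol=1e-6)
        assert np.allclose(series[("hip", "adduction")], 0.0, atol=1e-6)
        assert np.allclose(series[("knee", "rotation")], 0.0, atol=1e-6)


class TestStaticCalibration:
    def test_neutral_static_gives_zero_offsets(self, child_session):
        calib = cgm.static_calibration(child_session.static, child_session.anthropometry)
        for side in ("left", "right"):
            offs = calib.foot_offsets_deg[side]
            assert abs(offs["plantarflexion"]) < 1e-6
            assert abs(offs["rotation"]) < 1e-6

    def test_knee_offset_arithmetic(self):
        a = cs.Anthropometry(leg_length=800, knee_width=100, ankle_width=70, height=1500, mass=40)
        trialless = a.knee_offset
        assert trialless == 56.25

    def test_plantarflexed_static_recovers_offset(self, child_subject, typical_curves):
        static, _ = cs.generate_trial(
            child_subject, typical_curves, static_pose={"ankle": (-10.0, 0.0, 0.0)}
        )
        calib = cgm.static_calibration(static, child_subject.anthropometry)
        for side in ("left", "right"):
            assert calib.foot_offsets_deg[side]["plantarflexion"] == pytest.approx(10.0, abs=0.1)


class TestTimeNormalize:
    def test_constant_and_ramp(self):
        const = cgm.time_normalize(np.full(120, 7.5), (0, 100))
        np.testing.assert_allclose(const, 7.5)
        ramp = cgm.time_normalize(np.arange(201, dtype=float), (0, 200))
        np.testing.assert_allclose(ramp, np.linspace(0, 200, 101), atol=1e-9)

    def test_sine_interpolation_error_below_005deg(self):
        frames = np.arange(121)
        series = 30.0 * np.sin(2 * np.pi * frames / 120.0)
        curve = cgm.time_normalize(series, (0, 120))
        analytic = 30.0 * np.sin(2 * np.pi * np.linspace(0, 1, 101))
        assert np.max(np.abs(curve - analytic)) < 0.05

    def test_cycle_outside_trial_rejected(self):
        with pytest.raises(ValueError):
            cgm.time_normalize(np.zeros(50), (0, 60))


class TestComputeKinematics:
    def test_roundtrip_recovery_single_subject(self, child_session, typical_curves):
        calib = cgm.static_calibration(child_session.static, child_session.anthropometry)
        for side in ("left", "right"):
            recovered = cgm.compute_kinematics(
                child_session.gait, calib, child_session.anthropometry, side
            )
            for key in recovered.keys():
                err = np.max(np.abs(recovered[key] - typical_curves[key]))
                assert err <= 0.5, f"{key}: {err}"

    def test_whole_lab_rigid_transform_invariance(self, child_session):
        anthro = child_session.anthropometry
        R = Rotation.from_euler("zyx", [40, 5, -3], degrees=True).as_matrix()
        t = np.array([500.0, -200.0, 80.0])
        calib = cgm.static_calibration(child_session.static, anthro)
        ref = cgm.compute_kinematics(child_session.gait, calib, anthro, "left")
        static_t = rigid_transform(child_session.static, R, t)
        gait_t = rigid_transform(child_session.gait, R, t)
        calib_t = cgm.static_calibration(static_t, anthro)
        moved = cgm.compute_kinematics(gait_t, calib_t, anthro, "left")
        for key in ref.keys():
            np.testing.assert_allclose(moved[key], ref[key], atol=1e-9)

    def test_frames_orthonormal_throughout_trial(self, child_session):
        frames = cgm.segment_frames(child_session.gait, child_session.anthropometry, "left")
        for name, frame in frames.items():
            gram = frame.axes @ np.swapaxes(frame.axes, -1, -2)
            assert np.max(np.abs(gram - np.eye(3))) < 1e-9, name

    def test_chord_constraints_hold_on_trial_joint_centres(self, child_session):
        anthro = child_session.anthropometry
        trial = child_session.gait
        pelvis = cgm.pelvis_frame(trial)
        hjc = cgm.hip_joint_centre(pelvis, anthro, "left")
        _, kjc = cgm.thigh_frame(hjc, trial.markers["LKNE"], trial.markers["LTHI"], anthro.knee_offset, "left")
        d = np.linalg.norm(kjc - trial.markers["LKNE"], axis=-1)
        np.testing.assert_allclose(d, anthro.knee_offset, atol=1e-9)
        dot = np.sum((hjc - kjc) * (trial.markers["LKNE"] - kjc), axis=-1)
        assert np.max(np.abs(dot)) < 1e-6

    def test_hierarchy_kne_touches_all_foot_touches_ankle_only(self, child_session):
        anthro = child_session.anthropometry
        calib = cgm.static_calibration(child_session.static, anthro)
        ref = cgm.compute_kinematics(child_session.gait, calib, anthro, "left")

        kne_trial = child_session.gait.copy()
        kne_trial.markers["LKNE"] = kne_trial.markers["LKNE"] + [6.0, 0, 0]
        kne = cgm.compute_kinematics(kne_trial, calib, anthro, "left")
        for joint in ("hip", "knee", "ankle"):
            assert any(
                np.max(np.abs(kne[(joint, p, "left")] - ref[(joint, p, "left")])) > 0.05
                for p in ("flexion", "adduction", "rotation")
            ), joint

        toe_trial = child_session.gait.copy()
        toe_trial.markers["LTOE"] = toe_trial.markers["LTOE"] + [0, 6.0, 0]
        toe = cgm.compute_kinematics(toe_trial, calib, anthro, "left")
        for joint in ("hip", "knee"):
            for p in ("flexion", "adduction", "rotation"):
                np.testing.assert_allclose(
                    toe[(joint, p, "left")], ref[(joint, p, "left")], atol=1e-9
                )
        assert any(
            np.max(np.abs(toe[("ankle", p, "left")] - ref[("ankle", p, "left")])) > 0.05
            for p in ("flexion", "adduction", "rotation")
        )

    def test_no_complete_cycle_rejected(self, child_session, child_anthro):
        calib = cgm.static_calibration(child_session.static, child_anthro)
        trial = child_session.gait.copy()
        trial.events = trial.events[:1]
        with pytest.raises(ValueError):
            cgm.compute_kinematics(trial, calib, child_anthro, "left")
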