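"""Joint angles, gait events, stride length and phase symmetry."""

import numpy as np
import pytest

from gaitpose.gait import (CameraIntrinsics, InsufficientDataError, LegLengths,
                           NormativeConstants, UndefinedAngleError,
                           detect_gait_events, gait_report, hip_angle,
                           knee_angle, phase_symmetry, phase_symmetry_index,
                           pixel_to_camera, segment_angles_from_keypoints,
                           stride_length)
from gaitpose.synthetic import WalkerParams, render_frames, simulate_gait

CAM = CameraIntrinsics(500.0, 500.0)


class TestBackprojection:
    def test_optical_axis(self):
        np.testing.assert_allclose(pixel_to_camera((0, 0), 2.5, CAM),
                                   [0, 0, 2.5])

    def test_direct_substitution(self):
        np.testing.assert_allclose(pixel_to_camera((100, 50), 2.0, CAM),
                                   [0.4, 0.2, 2.0])

    def test_linearity_in_depth(self):
        a = pixel_to_camera((33, 77), 1.0, CAM)
        b = pixel_to_camera((33, 77), 3.0, CAM)
        np.testing.assert_allclose(b[:2], 3 * a[:2])

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            pixel_to_camera((0, 0), 0.0, CAM)


class TestAngles:
    def test_vertical_thigh_zero(self):
        assert hip_angle((100, 100), (100, 160), CAM) == pytest.approx(0.0)

    def test_isotropic_45_degrees(self):
        assert abs(hip_angle((0, 0), (10, 10), CAM)) == pytest.approx(45.0)

    def test_sign_follows_walking_direction(self):
        fwd = hip_angle((0, 0), (10, 10), CAM, walking_sign=1.0)
        bwd = hip_angle((0, 0), (10, 10), CAM, walking_sign=-1.0)
        assert fwd == pytest.approx(45.0) and bwd == pytest.approx(-45.0)

    def test_intrinsic_scale_invariance(self):
        cam2 = CameraIntrinsics(1000.0, 1000.0)
        assert hip_angle((5, 9), (42, 77), CAM) == pytest.approx(
            hip_angle((5, 9), (42, 77), cam2))
        assert knee_angle((5, 9), (42, 77), (60, 150), CAM) == pytest.approx(
            knee_angle((5, 9), (42, 77), (60, 150), cam2))

    def test_collinear_straight_leg(self):
        assert knee_angle((0, 0), (3, 30), (6, 60), CAM) == pytest.approx(0.0)

    def test_orthogonal_90(self):
        assert knee_angle((0, 0), (0, 10), (10, 10), CAM) == pytest.approx(90.0)

    def test_coincident_joints_raise(self):
        with pytest.raises(UndefinedAngleError):
            hip_angle((5, 5), (5, 5), CAM)
        with pytest.raises(UndefinedAngleError):
            knee_angle((0, 0), (0, 0), (1, 1), CAM)

    def test_equals_explicit_3d_backprojection(self, rng):
        """Pixel-form angle == back-project at arbitrary depth, then measure
        the 3-D angle (depth cancels; anisotropic intrinsics included)."""
        cam = CameraIntrinsics(431.0, 612.0)
        for _ in range(50):
            hip, knee, ankle = rng.uniform(-200, 200, (3, 2))
            z = rng.uniform(0.5, 10.0)
            a3 = pixel_to_camera(knee, z, cam) - pixel_to_camera(hip, z, cam)
            b3 = pixel_to_camera(ankle, z, cam) - pixel_to_camera(knee, z, cam)
            oracle = np.degrees(np.arccos(np.clip(
                a3 @ b3 / (np.linalg.norm(a3) * np.linalg.norm(b3)), -1, 1)))
            assert knee_angle(hip, knee, ankle, cam) == pytest.approx(
                oracle, abs=1e-6)
            oracle_hip = np.degrees(np.arccos(np.clip(
                a3[1] / np.linalg.norm(a3[:2]), -1, 1)))
            assert abs(hip_angle(hip, knee, cam)) == pytest.approx(
                oracle_hip, abs=1e-6)

    def test_segment_angles_forward_kinematics(self):
        """Thigh 20 deg forward and calf 20 deg forward reconstruct
        exactly from keypoints built by forward kinematics."""
        f, z = 500.0, 3.0
        th = np.radians(20.0)
        hip = np.array([0.1, 0.2])
        knee = hip + 0.4 * np.array([np.sin(th), np.cos(th)])
        ankle = knee + 0.4 * np.array([np.sin(th), np.cos(th)])
        to_px = lambda p: (f * p / z)
        theta, phi = segment_angles_from_keypoints(
            to_px(hip), to_px(knee), to_px(ankle), CAM)
        assert theta == pytest.approx(20.0, abs=1e-9)
        assert phi == pytest.approx(20.0, abs=1e-9)


class TestStrideLength:
    LEGS = LegLengths(0.4, 0.4, 0.4, 0.4)

    def test_zero_angles(self):
        assert stride_length(0, 0, 0, 0, self.LEGS) == 0.0

    def test_direct_substitution(self):
        d = stride_length(-20, -20, 20, 20, self.LEGS)
        assert d == pytest.approx(1.6 * np.sin(np.radians(20)), abs=1e-12)
        assert d == pytest.approx(0.54723, abs=1e-5)

    def test_swapping_legs_negates(self):
        d1 = stride_length(-15, -10, 25, 20, self.LEGS)
        d2 = stride_length(25, 20, -15, -10, self.LEGS)
        assert d1 == pytest.approx(-d2)


class TestPhaseSymmetry:
    def test_fully_symmetric_normative(self):
        assert phase_symmetry_index(0.744, 0.744, 0.456, 0.456, 1.2) == \
            pytest.approx(1.0, abs=1e-12)

    def test_slow_cycle_sqrt_factor(self):
        assert phase_symmetry_index(0.744, 0.744, 0.456, 0.456, 4.8) == \
            pytest.approx(0.5, abs=1e-12)

    def test_weighted_ratio_combination(self):
        # stance ratio 0.5, swing ratio 1.0: 0.62*0.5 + 0.38*1.0
        assert phase_symmetry_index(0.4, 0.8, 0.456, 0.456, 1.2) == \
            pytest.approx(0.69, abs=1e-12)

    def test_bounded_for_slow_cycles(self, rng):
        """For T >= T0 the index lies in (0, 1]; 1 iff symmetric at T0."""
        for _ in range(200):
            st = rng.uniform(0.1, 2.0, 2)
            sw = rng.uniform(0.1, 2.0, 2)
            t = rng.uniform(1.2, 5.0)
            v = phase_symmetry_index(*st, *sw, t)
            assert 0 < v <= 1.0 + 1e-12

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            phase_symmetry_index(0.0, 0.7, 0.4, 0.4, 1.2)


class TestEventDetection:
    def test_sinusoid_cycle_recovery(self):
        fps, period = 60.0, 1.2
        t = np.arange(int(6 * fps)) / fps
        x = 30 * np.cos(2 * np.pi * (t - 0.1) / period)
        ev = detect_gait_events(x, -x, fps)
        assert np.mean(ev.cycle_times("L")) == pytest.approx(period,
                                                             abs=1 / fps)

    def test_four_complete_cycles_in_6p2_seconds(self):
        fps, period = 60.0, 1.5
        t = np.arange(int(6.2 * fps)) / fps
        x = 30 * np.cos(2 * np.pi * (t - 0.1) / period)
        ev = detect_gait_events(x, -x, fps)
        assert len(ev.cycle_times("L")) == 4

    def test_constant_trajectory_raises(self):
        with pytest.raises(InsufficientDataError):
            detect_gait_events(np.zeros(600), np.zeros(600), 60.0)

    def test_stance_swing_partition_cycle(self):
        fps, period = 100.0, 1.2
        t = np.arange(int(8 * fps)) / fps
        x = 30 * np.cos(2 * np.pi * t / period + 0.3)
        ev = detect_gait_events(x, -x, fps)
        st_l, st_r, sw_l, sw_r, cyc = ev.mean_durations()
        assert st_l + sw_l == pytest.approx(cyc, abs=2 / fps)


class TestGaitReport:
    LEGS = LegLengths(0.42, 0.40, 0.42, 0.40)

    def _report(self, **kw):
        p = WalkerParams(image_size=256, seed=1, **kw)
        traj = simulate_gait(p, duration_s=6.0)
        _, _, kps = render_frames(traj, p)
        return traj, gait_report(kps, p.camera, self.LEGS, p.fps)

    def test_symmetric_walker_dps_near_one(self):
        _, rep = self._report()
        assert rep.cycle_time_s == pytest.approx(1.2, abs=1 / 60)
        assert rep.phase_symmetry == pytest.approx(1.0, abs=0.02)
        assert not rep.short_cycle_flag

    def test_asymmetric_stance_lowers_dps(self):
        _, rep = self._report(asymmetry=2.0)
        assert rep.phase_symmetry < 0.9

    def test_stride_matches_generator_angles(self):
        """Report stride equals the closed-form combination of the
        generator's segment angles at right heel strike (phase 0)."""
        traj, rep = self._report()
        th_r = traj.hip_r[0]
        ph_r = traj.hip_r[0] - traj.knee_r[0]
        # left leg is half a cycle on: use its angles at t=0 as trailing leg
        th_l = traj.hip_l[0]
        ph_l = traj.hip_l[0] - traj.knee_l[0]
        expected = stride_length(th_l, ph_l, th_r, ph_r, self.LEGS)
        assert rep.stride_length_m == pytest.approx(expected, rel=0.05)
        assert rep.speed_m_s == pytest.approx(
            rep.stride_length_m / rep.cycle_time_s)

    def test_static_pose_raises(self):
        p = WalkerParams(image_size=128, seed=1)
        traj = simulate_gait(p, n_frames=240)
        traj.positions[:] = traj.positions[0]
        _, _, kps = render_frames(traj, p)
        with pytest.raises(InsufficientDataError):
            gait_report(kps, p.camera, self.LEGS, p.fps)

    def test_phase_symmetry_from_events_matches_index(self):
        _, rep = self._report()
        assert phase_symmetry(rep.events) == pytest.approx(rep.phase_symmetry)
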