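import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import pitchchain as pc
from pitchchain.kinematics import (
    SegmentFrameSeries,
    angular_velocity,
    build_segment_frames,
    external_rotation_angle,
)
from pitchchain.preprocess import preprocess_trial
from pitchchain.trial_io import MarkerTrajectory, Trial


def _rigid_rotate(trial, Q):
    markers = {
        lab: MarkerTrajectory(lab, traj.positions @ Q.T, traj.valid_mask.copy())
        for lab, traj in trial.markers.items()
    }
    return trial.with_markers(markers)


class TestFrameConstruction:
    def test_recovers_generating_frames_exactly(self, clean_pitch):
        trial, truth = clean_pitch
        frames = build_segment_frames(trial)
        for seg in frames:
            np.testing.assert_allclose(frames[seg].R, truth.R[seg], atol=1e-9)

    def test_equivariant_under_rigid_rotation(self, clean_pitch):
        trial, _ = clean_pitch
        Q = Rotation.from_euler("zyx", [31.0, -12.0, 7.0], degrees=True).as_matrix()
        base = build_segment_frames(trial)
        rotated = build_segment_frames(_rigid_rotate(trial, Q))
        for seg in base:
            np.testing.assert_allclose(rotated[seg].R, Q @ base[seg].R, atol=1e-9)

    def test_noise_propagation_stays_bounded(self, noisy_pitch):
        # 0.5 mm noise; orientation error scales as noise / marker baseline,
        # so the short-baseline arm segments tolerate more than the pelvis.
        trial, truth = noisy_pitch
        frames = build_segment_frames(preprocess_trial(trial))
        bounds = {"pelvis": 0.5, "trunk": 0.5, "upper_arm": 0.5,
                  "forearm": 1.2, "hand": 1.2}
        for seg, lim in bounds.items():
            Rrel = np.einsum("tji,tjk->tik", truth.R[seg], frames[seg].R)
            tr = np.trace(Rrel, axis1=1, axis2=2)
            ang = np.degrees(np.arccos(np.clip((tr - 1) / 2, -1, 1)))
            rms = np.sqrt(np.mean(ang**2))
            assert rms < lim, f"{seg}: RMS orientation error {rms:.2f} deg"

    def test_degenerate_geometry_reported_with_frame(self, clean_pitch):
        trial, _ = clean_pitch
        markers = {lab: MarkerTrajectory(lab, t.positions.copy(), t.valid_mask.copy())
                   for lab, t in trial.markers.items()}
        markers["RASI"].positions[7] = markers["LASI"].positions[7]  # collinear
        bad = trial.with_markers(markers)
        with pytest.raises(ValueError, match="frame 7"):
            build_segment_frames(bad)


def _const_rotation_series(axis, deg_s, T=100, rate=400.0):
    t = np.arange(T) / rate
    R = Rotation.from_rotvec(np.outer(np.radians(deg_s) * t, axis)).as_matrix()
    return SegmentFrameSeries("pelvis", R, np.zeros((T, 3)), rate)


class TestAngularVelocity:
    def test_constant_rotation_about_z(self):
        # sampled densely so the O((Ωh)²) central-difference bias is below
        # the closed-form tolerance
        series = _const_rotation_series([0, 0, 1], 90.0, T=100, rate=20000.0)
        omega = angular_velocity(series)
        interior = slice(1, -1)
        expected = np.tile([0.0, 0.0, np.radians(90.0)], (98, 1))
        np.testing.assert_allclose(omega.omega[interior], expected, atol=1e-6)
        np.testing.assert_allclose(omega.omega_norm_deg[interior], 90.0, atol=1e-6)

    def test_static_frames_give_zero(self):
        R = np.tile(np.eye(3), (50, 1, 1))
        series = SegmentFrameSeries("trunk", R, np.zeros((50, 3)), 400.0)
        omega = angular_velocity(series)
        np.testing.assert_allclose(omega.omega_norm, 0.0, atol=1e-9)

    def test_compound_motion_matches_analytic(self):
        # R(t) = Rz(α) Rx(β), polynomial angles; ω = α̇ ẑ + β̇ Rz(α) x̂
        # (sampled at 2 kHz so the finite-difference bias sits below 1e-4)
        rate, T = 2000.0, 240
        t = np.arange(T) / rate
        alpha = 2.0 * t + 3.0 * t**2
        beta = 1.0 * t - 2.0 * t**3
        dalpha = 2.0 + 6.0 * t
        dbeta = 1.0 - 6.0 * t**2
        Rz = Rotation.from_euler("z", alpha[:, None]).as_matrix()
        Rx = Rotation.from_euler("x", beta[:, None]).as_matrix()
        R = np.einsum("tij,tjk->tik", Rz, Rx)
        omega = angular_velocity(SegmentFrameSeries("trunk", R, np.zeros((T, 3)), rate))
        xhat = Rz @ np.array([1.0, 0.0, 0.0])
        expected = dalpha[:, None] * np.array([0, 0, 1.0]) + dbeta[:, None] * xhat
        np.testing.assert_allclose(omega.omega[2:-2], expected[2:-2], atol=1e-4)

    def test_norm_integral_equals_total_angle(self):
        # single-axis rotation: ∫‖ω‖ dt equals the swept angle within 0.1%
        total_deg = 130.0
        T, rate = 400, 400.0
        t = np.arange(T) / rate
        ang = np.radians(total_deg) * (t / t[-1]) ** 2  # smooth ramp
        R = Rotation.from_euler("y", ang[:, None]).as_matrix()
        omega = angular_velocity(SegmentFrameSeries("pelvis", R, np.zeros((T, 3)), rate))
        swept = np.degrees(np.trapezoid(omega.omega_norm, dx=1 / rate))
        assert swept == pytest.approx(total_deg, rel=1e-3)

    def test_frame_consistency_of_omega(self, clean_pitch):
        # rotating ω into the segment frame and back reproduces it exactly
        trial, _ = clean_pitch
        frames = build_segment_frames(trial)["upper_arm"]
        omega = angular_velocity(frames)
        local = np.einsum("tji,tj->ti", frames.R, omega.omega)
        back = np.einsum("tij,tj->ti", frames.R, local)
        np.testing.assert_allclose(back, omega.omega, atol=1e-12)

    def test_non_orthonormal_input_rejected(self):
        R = np.tile(np.eye(3), (20, 1, 1))
        R[5, 0, 0] = 1.1
        with pytest.raises(ValueError, match="orthonormal"):
            angular_velocity(SegmentFrameSeries("hand", R, np.zeros((20, 3)), 400.0))


class TestExternalRotation:
    def _trunk(self, T, rate=400.0):
        return SegmentFrameSeries("trunk", np.tile(np.eye(3), (T, 1, 1)),
                                  np.zeros((T, 3)), rate)

    def test_identical_frames_give_zero(self):
        T = 50
        trunk = self._trunk(T)
        ua = SegmentFrameSeries("upper_arm", trunk.R.copy(), trunk.origin.copy(), 400.0)
        angle, flags = external_rotation_angle(ua, trunk)
        np.testing.assert_allclose(angle, 0.0, atol=1e-9)

    def test_prescribed_axial_ramp_recovered(self):
        # humerus abducted (elevation 90°, the canonical Y-X-Y branch),
        # axial ramp 0 → 170°
        T, rate = 200, 400.0
        trunk = self._trunk(T, rate)
        gamma = np.linspace(0.0, 170.0, T)
        R = Rotation.from_euler(
            "YXY", np.stack([np.zeros(T), np.full(T, 90.0), gamma], axis=1),
            degrees=True,
        ).as_matrix()
        ua = SegmentFrameSeries("upper_arm", R, np.zeros((T, 3)), rate)
        angle, flags = external_rotation_angle(ua, trunk)
        assert not flags[5:].any()
        assert abs(angle.max() - 170.0) < 0.1
        # decomposition inverts the prescription along the whole ramp
        np.testing.assert_allclose(angle[5:], gamma[5:], atol=0.1)

    def test_decompose_recompose_round_trip(self, clean_pitch):
        trial, _ = clean_pitch
        frames = build_segment_frames(trial)
        R_rel = np.einsum(
            "tji,tjk->tik", frames["trunk"].R, frames["upper_arm"].R
        )
        ang = Rotation.from_matrix(R_rel).as_euler("YXY")
        rebuilt = Rotation.from_euler("YXY", ang).as_matrix()
        np.testing.assert_allclose(rebuilt, R_rel, atol=1e-9)

    def test_mer_frame_matches_generator(self, clean_pitch):
        trial, truth = clean_pitch
        frames = build_segment_frames(trial)
        angle, _ = external_rotation_angle(frames["upper_arm"], frames["trunk"])
        k, t_mer = pc.detect_mer(angle, trial.rate)
        assert abs(t_mer - truth.mer_time) <= 1.0 / trial.rate
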