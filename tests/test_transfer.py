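"""Load-case preparation: wrench/pose registration, scaling, periodisation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation as Rot

from kneetwin.jcs import RigidPose, jcs_from_pose
from kneetwin.synthetic import generate_load_case, generate_recording
from kneetwin.transfer import (CHANNELS, LOAD_CHANNELS, POSITION_CHANNELS,
                               FrameRegistration, LoadCaseTrack,
                               ScalingConfig, default_innex_to_pfc_registration,
                               periodise, prepare_load_case, register_pose,
                               register_wrench, scale_loads)
from kneetwin.wrench import FrameMismatchError, Wrench


def random_registration(rng, source="A", target="B"):
    axis = rng.normal(size=3)
    return FrameRegistration.from_axis_angle(
        axis, float(rng.uniform(-90, 90)), rng.uniform(-20, 20, 3),
        source, target)


def adjoint_oracle(reg: FrameRegistration) -> np.ndarray:
    """Independent 6×6 adjoint matrix acting on stacked (F, M[N·mm])."""
    r = reg.origin_shift_mm
    skew = np.array([[0, -r[2], r[1]], [r[2], 0, -r[0]], [-r[1], r[0], 0]])
    Q = reg.rotation
    return np.block([[Q, np.zeros((3, 3))], [skew @ Q, Q]])


class TestRegisterWrench:
    def test_identity_registration_is_identity(self):
        w = Wrench([1.0, -2.0, 3.0], [0.5, 0.0, -0.25], "A")
        w2 = register_wrench(w, FrameRegistration.identity("A", "B"))
        assert np.array_equal(w2.force_N, w.force_N)
        assert np.array_equal(w2.moment_Nm, w.moment_Nm)

    def test_pure_origin_shift_hand_cross_product(self):
        w = Wrench([0.0, 0.0, 100.0], [0.0, 0.0, 0.0], "A")
        reg = FrameRegistration(np.eye(3), [10.0, 0.0, 0.0], "A", "B")
        w2 = register_wrench(w, reg)
        assert np.allclose(w2.moment_Nm, [0.0, -1.0, 0.0], atol=1e-15)
        assert np.allclose(w2.force_N, w.force_N)

    def test_rotation_preserves_force_norm_and_invariant(self, rng):
        reg = default_innex_to_pfc_registration()
        for _ in range(20):
            w = Wrench(rng.uniform(-2000, 2000, 3), rng.uniform(-50, 50, 3),
                       "INNEX")
            w2 = register_wrench(w, reg)
            assert np.linalg.norm(w2.force_N) == pytest.approx(
                np.linalg.norm(w.force_N), abs=1e-12)

    def test_agrees_with_adjoint_matrix_oracle(self, rng):
        worst = 0.0
        for _ in range(1000):
            reg = random_registration(rng)
            w = Wrench(rng.uniform(-2000, 2000, 3), rng.uniform(-80, 80, 3),
                       "A")
            w2 = register_wrench(w, reg)
            got = np.concatenate([w2.force_N, w2.moment_Nm * 1e3])
            exp = adjoint_oracle(reg) @ np.concatenate(
                [w.force_N, w.moment_Nm * 1e3])
            scale = max(np.abs(exp).max(), 1.0)
            worst = max(worst, np.abs(got - exp).max() / scale)
        assert worst <= 1e-9

    def test_inverse_registration_round_trip(self, rng):
        for _ in range(50):
            reg = random_registration(rng)
            w = Wrench(rng.uniform(-1000, 1000, 3), rng.uniform(-50, 50, 3),
                       "A")
            back = register_wrench(register_wrench(w, reg), reg.inverse())
            assert np.allclose(back.force_N, w.force_N, atol=1e-12)
            assert np.allclose(back.moment_Nm, w.moment_Nm, atol=1e-12)

    def test_frame_mismatch_rejected(self):
        w = Wrench([1, 0, 0], [0, 0, 0], "C")
        with pytest.raises(FrameMismatchError):
            register_wrench(w, FrameRegistration.identity("A", "B"))

    def test_default_registration_recovers_printed_slope(self):
        reg = default_innex_to_pfc_registration()
        assert reg.angle_deg() == pytest.approx(6.5, abs=1e-12)
        assert np.linalg.norm(reg.origin_shift_mm) <= 1.0


class TestRegisterPose:
    def test_identity_registrations_leave_pose_unchanged(self, rng):
        p = RigidPose(Rot.random(random_state=1).as_matrix(),
                      rng.uniform(-20, 20, 3))
        p2 = register_pose(p, FrameRegistration.identity())
        assert np.allclose(p2.rotation, p.rotation, atol=1e-15)
        assert np.allclose(p2.translation, p.translation, atol=1e-15)

    def test_matches_homogeneous_matrix_oracle(self, rng):
        def homog(R, t):
            T = np.eye(4)
            T[:3, :3], T[:3, 3] = R, t
            return T

        for _ in range(100):
            p = RigidPose(Rot.from_rotvec(rng.normal(size=3)).as_matrix(),
                          rng.uniform(-20, 20, 3))
            rf = random_registration(rng)
            rt = random_registration(rng)
            p2 = register_pose(p, rf, rt)
            T = homog(rf.rotation, rf.origin_shift_mm) @ \
                homog(p.rotation, p.translation) @ \
                np.linalg.inv(homog(rt.rotation, rt.origin_shift_mm))
            assert np.allclose(p2.rotation, T[:3, :3], atol=1e-9)
            assert np.allclose(p2.translation, T[:3, 3], atol=1e-9)

    def test_inverse_registrations_round_trip(self, rng):
        p = RigidPose(Rot.from_rotvec(rng.normal(size=3)).as_matrix(),
                      rng.uniform(-20, 20, 3))
        reg = random_registration(rng)
        back = register_pose(register_pose(p, reg), reg.inverse())
        assert np.allclose(back.rotation, p.rotation, atol=1e-12)
        assert np.allclose(back.translation, p.translation, atol=1e-12)


class TestScaling:
    def test_unit_ratio_is_identity(self):
        track = generate_load_case("squat", 64, seed=0)
        out = scale_loads(track, ScalingConfig(75.0, 75.0))
        assert out == track

    def test_load_channels_scale_kinematics_do_not(self):
        track = generate_load_case("squat", 64, seed=0)
        out = scale_loads(track, ScalingConfig(75.0, 100.0))
        for c in LOAD_CHANNELS:
            assert np.allclose(out.channels[c], 0.75 * track.channels[c])
        for c in POSITION_CHANNELS:
            assert np.array_equal(out.channels[c], track.channels[c])
        assert out.frequency_hz == track.frequency_hz

    def test_hand_value(self):
        # −2000 N axial sample at 100 → 75 kg becomes −1500 N
        assert -2000.0 * ScalingConfig(75.0, 100.0).ratio == -1500.0

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            ScalingConfig(0.0, 75.0)

    def test_scaling_commutes_with_registration(self, rng):
        reg = random_registration(rng, "A", "B")
        cfg = ScalingConfig(75.0, 92.0)
        w = Wrench(rng.uniform(-1000, 1000, 3), rng.uniform(-40, 40, 3), "A")
        a = register_wrench(Wrench(w.force_N * cfg.ratio,
                                   w.moment_Nm * cfg.ratio, "A"), reg)
        b = register_wrench(w, reg)
        assert np.allclose(a.force_N, b.force_N * cfg.ratio, atol=1e-12)
        assert np.allclose(a.moment_Nm, b.moment_Nm * cfg.ratio, atol=1e-12)


class TestPeriodise:
    def test_constant_channel_stays_constant(self):
        n = 60
        t = np.arange(n) * 0.01
        channels = {c: np.full(n, 3.5) for c in CHANNELS}
        track = LoadCaseTrack("squat", t, channels, 1.0)
        out = periodise(track)
        for c in CHANNELS:
            assert np.allclose(out.channels[c], 3.5)
            assert out.channels[c][0] == out.channels[c][-1]

    def test_linear_ramp_sample_count_and_endpoint(self):
        n = 100
        t = np.arange(n) * 0.01
        ramp = np.linspace(0.0, 10.0, n)
        channels = {c: ramp.copy() for c in CHANNELS}
        out = periodise(LoadCaseTrack("squat", t, channels, 1.0))
        assert out.n_samples == 115
        for c in CHANNELS:
            assert out.channels[c][0] == out.channels[c][114]

    def test_duration_extends_by_fifteen_percent(self):
        track = generate_load_case("level_walking", 100, seed=0)
        out = periodise(track)
        assert out.duration_s / track.duration_s == pytest.approx(1.15,
                                                                  abs=1e-12)

    def test_original_samples_preserved_bitwise(self):
        track = generate_load_case("downhill_walking", 80, seed=1)
        out = periodise(track)
        for c in CHANNELS:
            assert np.array_equal(out.channels[c][:80], track.channels[c])

    def test_periodic_channel_extension_stays_in_envelope(self):
        n = 100
        t = np.arange(n) * 0.01
        u = np.arange(n) / n
        y = np.sin(2 * np.pi * u)          # periodic with matching slopes
        channels = {c: y.copy() for c in CHANNELS}
        out = periodise(LoadCaseTrack("squat", t, channels, 1.0))
        seg = out.channels["is_N"][n:]
        eps = 1e-9 * np.ptp(y)
        assert seg.min() >= y.min() - eps
        assert seg.max() <= y.max() + eps

    def test_junction_slope_continuity(self):
        track = generate_load_case("squat", 100, seed=2)
        out = periodise(track)
        n, dt = 100, track.dt
        for c in CHANNELS:
            y = out.channels[c]
            before = (y[n - 1] - y[n - 2]) / dt
            after = (y[n] - y[n - 1]) / dt
            scale = max(np.ptp(y) / track.duration_s, 1.0)
            assert abs(after - before) <= 0.2 * scale + 1e-9

    def test_idempotent_on_harmonised_output(self):
        track = generate_load_case("stairs_down", 80, seed=3)
        once = periodise(track)
        twice = periodise(once)
        mismatch = max(abs(twice.channels[c][0] - twice.channels[c][-1])
                       for c in CHANNELS)
        assert mismatch < 1e-12

    def test_degenerate_track_rejected(self):
        t = np.arange(3) * 0.01
        channels = {c: np.zeros(3) for c in CHANNELS}
        with pytest.raises(ValueError, match="4 samples"):
            periodise(LoadCaseTrack("squat", t, channels, 1.0))


class TestPrepareLoadCase:
    def test_identity_pipeline_matches_plain_jcs_conversion(self):
        rec = generate_recording("squat", 64, seed=4,
                                 overrides={"endpoint_mismatch": 0.0})
        reg = FrameRegistration.identity("INNEX", "INNEX")
        track = prepare_load_case(rec, reg, ScalingConfig())
        # original samples must be the untouched JCS conversion
        for i in (0, 10, 40, 63):
            coords = jcs_from_pose(rec.pose(i))
            assert track.channels["fe_deg"][i] == pytest.approx(
                coords.flexion_deg, abs=1e-9)

    def test_prepared_track_is_periodic_on_all_load_channels(self):
        rec = generate_recording("downhill_walking", 80, seed=5)
        track = prepare_load_case(rec, default_innex_to_pfc_registration(),
                                  ScalingConfig())
        assert track.is_periodic()
        assert track.n_samples == 92

    def test_origin_shift_moves_moments_not_force_magnitudes(self):
        rec = generate_recording("squat", 64, seed=6)
        reg_shift = FrameRegistration(np.eye(3), [1.0, 0.0, 0.0],
                                      "INNEX", "X")
        w = Wrench(rec.force_N[30], rec.moment_Nm[30], "INNEX")
        w2 = register_wrench(w, reg_shift)
        dm = np.linalg.norm(w2.moment_Nm - w.moment_Nm)
        assert np.linalg.norm(w2.force_N) == pytest.approx(
            np.linalg.norm(w.force_N), abs=1e-12)
        # |Δmoment| ≤ |r||F|; with 1 mm and ≈2 kN that is ≤ ≈2 N·m
        assert dm <= 1e-3 * np.linalg.norm(w.force_N) + 1e-12

    def test_stage_name_in_errors(self):
        rec = generate_recording("squat", 64, seed=7)
        reg = FrameRegistration.identity("WRONG", "X")
        with pytest.raises(FrameMismatchError, match="stage register"):
            prepare_load_case(rec, reg)
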