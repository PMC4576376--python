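"""Axis alignment, static/dynamic split, pitch/roll, tilt compensation, heading."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ddkit.attitude import (
    AxisMap,
    apply_axis_map,
    heading,
    moving_average,
    pitch_roll,
    static_acceleration,
    tilt_compensate,
)
from ddkit.io import ChannelSchema, SensorTable


def rot_x(phi):
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[1, 0, 0], [0, c, s], [0, -s, c]])


def rot_y(th):
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, 0, -s], [0, 1, 0], [s, 0, c]])


def rot_z(ps):
    c, s = math.cos(ps), math.sin(ps)
    return np.array([[c, s, 0], [-s, c, 0], [0, 0, 1]])


def body_vectors(pitch_deg, roll_deg, yaw_deg, v_earth):
    """Rotation oracle: earth-frame vector seen in the body frame."""
    R = rot_x(math.radians(roll_deg)) @ rot_y(math.radians(pitch_deg)) @ rot_z(math.radians(yaw_deg))
    return R @ v_earth


class TestAxisMap:
    def make_table(self, acc, mag):
        df = pd.DataFrame(
            {"ax": acc[:, 0], "ay": acc[:, 1], "az": acc[:, 2], "mx": mag[:, 0], "my": mag[:, 1], "mz": mag[:, 2]}
        )
        return SensorTable(df, ChannelSchema.infer(df.columns), rate_hz=1.0)

    def test_identity_map_unchanged(self, rng):
        acc, mag = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        out = apply_axis_map(self.make_table(acc, mag), AxisMap())
        np.testing.assert_array_equal(out.column("mx_al"), mag[:, 0])
        np.testing.assert_array_equal(out.column("ax_al"), acc[:, 0])

    def test_map_then_inverse_restores(self, rng):
        acc, mag = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        swap_flip = np.array([[0, 1, 0], [1, 0, 0], [0, 0, -1]], dtype=float)
        amap = AxisMap(mag_to_accel=swap_flip)
        mag_mapped = mag @ amap.mag_matrix.T
        restored = mag_mapped @ amap.inverse().mag_matrix.T
        np.testing.assert_allclose(restored, mag, atol=1e-15)

    def test_non_permutation_rejected(self):
        with pytest.raises(ValueError, match="signed permutation"):
            AxisMap(mag_to_accel=np.eye(3) * 0.5)
        with pytest.raises(ValueError, match="signed permutation"):
            AxisMap(mounting=np.ones((3, 3)))

    def test_mounting_rotation_reproduces_heading(self):
        """A device mounted yawed 90 deg right still yields the true heading
        once its AxisMap is applied."""
        yaw_true = 40.0
        f_e = np.array([-math.cos(math.radians(66)), 0.0, math.sin(math.radians(66))])
        # mounted frame = device frame rotated by +90 deg about z
        mount = rot_z(math.radians(90.0))
        n = 8
        mag_dev = np.array([body_vectors(0, 0, yaw_true, f_e) for _ in range(n)])
        mag_mounted = mag_dev @ mount.T
        acc_mounted = np.tile(np.array([0.0, 0.0, 1.0]), (n, 1))
        amap = AxisMap(mounting=np.round(mount.T))
        table = TestAxisMap.make_table(self, acc_mounted, mag_mounted)
        out = apply_axis_map(table, amap)
        mag_aligned = out.data[["mx_al", "my_al", "mz_al"]].to_numpy()
        H = heading(mag_aligned, 0.0)
        np.testing.assert_allclose(H, yaw_true, atol=1e-9)

    def test_file_round_trip(self, tmp_path):
        amap = AxisMap(mag_to_accel=np.array([[0, 1, 0], [1, 0, 0], [0, 0, -1]], dtype=float))
        p = tmp_path / "axes.txt"
        amap.to_file(p)
        loaded = AxisMap.from_file(p)
        np.testing.assert_array_equal(loaded.mag_to_accel, amap.mag_to_accel)
        np.testing.assert_array_equal(loaded.mounting, amap.mounting)


class TestStaticAcceleration:
    def test_constant_signal(self):
        raw = np.tile([0.0, 0.0, 1.0], (50, 1))
        static, dynamic = static_acceleration(raw, 11)
        np.testing.assert_array_equal(static, raw)
        np.testing.assert_array_equal(dynamic, 0.0)

    def test_window_one_is_identity(self, rng):
        raw = rng.normal(size=(20, 3))
        static, dynamic = static_acceleration(raw, 1)
        np.testing.assert_array_equal(static, raw)
        np.testing.assert_array_equal(dynamic, 0.0)

    def test_sine_attenuation_follows_moving_average_gain(self):
        """A sine of period P through a P-sample centred mean is annihilated
        (the Dirichlet gain sin(pi f w)/(w sin(pi f)) vanishes at w = P)."""
        P = 25
        n = 500
        x = np.sin(2 * np.pi * np.arange(n) / P)
        sm = moving_average(x, P if P % 2 == 1 else P + 1)
        assert np.abs(sm[P:-P]).max() < 1e-12

    def test_even_or_oversized_window_rejected(self, rng):
        raw = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="odd"):
            static_acceleration(raw, 4)
        with pytest.raises(ValueError, match="exceeds"):
            static_acceleration(raw, 11)

    @given(st.integers(0, 2**31 - 1))
    def test_static_plus_dynamic_recomposes(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.normal(size=(30, 3))
        static, dynamic = static_acceleration(raw, 5)
        # dynamic is the exact residual by definition; recomposition is
        # exact up to one rounding of the final addition
        np.testing.assert_array_equal(dynamic, raw - static)
        np.testing.assert_allclose(static + dynamic, raw, rtol=0, atol=1e-14)


class TestPitchRoll:
    def test_level_device(self):
        pitch, roll = pitch_roll(np.array([[0.0, 0.0, 1.0]]))
        assert pitch[0] == 0.0 and roll[0] == 0.0

    def test_nose_up_90(self):
        pitch, roll = pitch_roll(np.array([[-1.0, 0.0, 0.0]]))
        assert pitch[0] == pytest.approx(90.0)
        assert roll[0] == 0.0  # gimbal convention

    def test_recovery_from_known_euler_angles(self, rng):
        g_earth = np.array([0.0, 0.0, 1.0])
        for _ in range(50):
            p_true = rng.uniform(-80, 80)
            r_true = rng.uniform(-170, 170)
            y_true = rng.uniform(0, 360)
            static = body_vectors(p_true, r_true, y_true, g_earth)[None, :]
            pitch, roll = pitch_roll(static)
            assert abs(pitch[0] - p_true) < 1e-9
            assert abs(roll[0] - r_true) < 1e-9

    def test_zero_vector_yields_null(self):
        pitch, roll = pitch_roll(np.zeros((1, 3)))
        assert np.isnan(pitch[0]) and np.isnan(roll[0])


class TestTiltCompensation:
    def test_zero_attitude_unchanged(self, rng):
        mag = rng.normal(size=(6, 3))
        out = tilt_compensate(mag, np.zeros(6), np.zeros(6))
        np.testing.assert_allclose(out, mag, atol=1e-15)

    def test_recovers_level_frame_vector(self, rng):
        f_e = np.array([-0.4, 0.0, 0.9])
        for _ in range(30):
            p, r, y = rng.uniform(-80, 80), rng.uniform(-170, 170), rng.uniform(0, 360)
            m_body = body_vectors(p, r, y, f_e)[None, :]
            level = tilt_compensate(m_body, np.array([p]), np.array([r]))
            expected = rot_z(math.radians(y)) @ f_e
            np.testing.assert_allclose(level[0], expected, atol=1e-12)

    def test_gimbal_pitch_90_is_finite(self):
        out = tilt_compensate(np.array([[0.3, 0.2, 0.1]]), np.array([90.0]), np.array([0.0]))
        assert np.all(np.isfinite(out))

    def test_null_attitude_propagates(self):
        out = tilt_compensate(np.ones((1, 3)), np.array([np.nan]), np.array([0.0]))
        assert np.all(np.isnan(out[0, (0, 2)]))


class TestHeading:
    def test_printed_ratio_at_north(self):
        assert heading(np.array([[-1.0, 0.0, 0.5]]))[0] == 0.0

    def test_quadrants(self):
        assert heading(np.array([[0.0, 1.0, 0.0]]))[0] == pytest.approx(90.0)
        assert heading(np.array([[1.0, 0.0, 0.0]]))[0] == pytest.approx(180.0)
        assert heading(np.array([[0.0, -1.0, 0.0]]))[0] == pytest.approx(270.0)

    @given(st.floats(-180, 180), st.floats(0, 359.999))
    def test_declination_shifts_heading_exactly(self, dec, h):
        m = np.array([[-math.cos(math.radians(h)), math.sin(math.radians(h)), 0.3]])
        base = heading(m, 0.0)[0]
        shifted = heading(m, dec)[0]
        assert abs((shifted - base - dec + 180) % 360 - 180) < 1e-9

    def test_scale_invariance(self, rng):
        m = rng.normal(size=(10, 3))
        np.testing.assert_allclose(heading(m), heading(m * 7.3), atol=1e-12)

    def test_vanishing_horizontal_component_is_null(self):
        assert np.isnan(heading(np.array([[0.0, 0.0, 1.0]]))[0])

    def test_declination_range_checked(self):
        with pytest.raises(ValueError, match="declination"):
            heading(np.array([[1.0, 0.0, 0.0]]), 200.0)


class TestEndToEndAttitude:
    def test_forward_simulated_heading_recovery(self, rng):
        """Known attitude + field -> pitch/roll/tilt-compensated heading all
        recovered to numerical precision."""
        inc = math.radians(66.0)
        f_e = np.array([-math.cos(inc), 0.0, math.sin(inc)])
        g_e = np.array([0.0, 0.0, 1.0])
        for _ in range(40):
            p, r, y = rng.uniform(-60, 60), rng.uniform(-60, 60), rng.uniform(0, 360)
            acc = body_vectors(p, r, y, g_e)[None, :]
            mag = body_vectors(p, r, y, f_e)[None, :]
            pitch, roll = pitch_roll(acc)
            H = heading(tilt_compensate(mag, pitch, roll), 0.0)
            assert abs(pitch[0] - p) < 1e-9
            assert abs(roll[0] - r) < 1e-9
            assert abs((H[0] - y + 180) % 360 - 180) < 1e-6
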