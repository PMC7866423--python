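"""EKF orientation fusion: initializer, predict/update steps, whole streams."""

import numpy as np
import pytest

from strokekin.fusion import (
    DEG,
    GRAVITY,
    EkfConfig,
    EkfState,
    SensorStream,
    ekf_predict,
    ekf_update,
    initial_euler,
    initial_state,
    measurement_jacobian,
    predict_measurement,
    run_fusion,
)
from strokekin.quat import (
    EulerAngles,
    orientation_distance,
    quat_from_axis_angle,
    quat_from_euler,
    quat_identity,
)
from strokekin.simulate import StrokeParams, simulate_imu


CFG = EkfConfig()


def static_stream(q, n, params, seed=0, fs=400.0):
    orient = np.tile(np.asarray(q, dtype=float), (n, 1))
    return simulate_imu(orient, params, "test", np.random.default_rng(seed))


def noise_params(**kw):
    base = dict(n_cycles=1, sample_rate_hz=400.0)
    base.update(kw)
    return StrokeParams(**base)


def quiet_params(**kw):
    return noise_params(gyro_noise_deg_s=1e-12, accel_noise_g=1e-12,
                        mag_noise_gauss=1e-12, **kw)


class TestInitialEuler:
    def test_level_facing_north(self):
        e = initial_euler(np.array([0.0, 0, GRAVITY]), CFG.mag_reference)
        np.testing.assert_allclose([e.pitch, e.roll, e.yaw], 0, atol=1e-12)

    def test_known_roll_recovered(self):
        roll = 0.4  # rotation about body y
        q = quat_from_euler(EulerAngles(0.0, roll, 0.0))
        z = predict_measurement(q, CFG)
        e = initial_euler(z[3:], z[:3])
        assert e.roll == pytest.approx(roll, abs=1e-9)
        assert e.pitch == pytest.approx(0, abs=1e-9)

    def test_random_attitudes_roundtrip(self, rng):
        for _ in range(30):
            e = EulerAngles(pitch=rng.uniform(-1.2, 1.2),
                            roll=rng.uniform(-np.pi, np.pi),
                            yaw=rng.uniform(-np.pi, np.pi))
            q = quat_from_euler(e)
            z = predict_measurement(q, CFG)
            e2 = initial_euler(z[3:], z[:3])
            np.testing.assert_allclose(
                [e2.pitch, e2.roll, e2.yaw], [e.pitch, e.roll, e.yaw],
                atol=1e-6)

    def test_non_static_warns(self):
        with pytest.warns(UserWarning, match="static"):
            initial_euler(np.array([0.0, 0, 3 * GRAVITY]), CFG.mag_reference)

    def test_zero_horizontal_field_rejected(self):
        with pytest.raises(ValueError, match="yaw"):
            initial_euler(np.array([0.0, 0, GRAVITY]), np.zeros(3))


class TestInitialState:
    def test_zero_euler(self):
        s = initial_state(EulerAngles(0, 0, 0), CFG)
        np.testing.assert_allclose(s.quat, quat_identity())
        np.testing.assert_allclose(s.gyro_bias, 0)
        s.validate()

    def test_pure_yaw(self):
        s = initial_state(EulerAngles(0, 0, np.pi / 2), CFG)
        np.testing.assert_allclose(
            s.quat, [np.cos(np.pi / 4), 0, 0, np.sin(np.pi / 4)], atol=1e-12)


class TestPredict:
    def test_zero_gyro_keeps_quaternion_and_grows_covariance(self):
        s = initial_state(EulerAngles(0.1, 0.2, 0.3), CFG)
        s2 = ekf_predict(s, np.zeros(3), CFG)
        np.testing.assert_allclose(s2.quat, s.quat, atol=1e-12)
        assert np.trace(s2.P) > np.trace(s.P)
        s2.validate()

    def test_constant_rate_matches_axis_angle_integration(self):
        # 90 deg/s about z for 1 s at 400 Hz -> 90 deg about z
        s = initial_state(EulerAngles(0, 0, 0), CFG)
        gyro = np.array([0.0, 0.0, 90.0 * DEG])
        for _ in range(400):
            s = ekf_predict(s, gyro, CFG)
        target = quat_from_axis_angle([0, 0, 1], np.pi / 2)
        err = orientation_distance(s.quat, target)
        assert np.degrees(err) < 0.2

    def test_bias_exactly_cancels_gyro(self):
        s = initial_state(EulerAngles(0, 0, 0), CFG)
        s.x[4:] = np.array([0.1, -0.2, 0.3])
        s2 = ekf_predict(s, s.x[4:].copy(), CFG)
        np.testing.assert_allclose(s2.quat, s.quat, atol=1e-12)

    def test_rejects_non_finite_gyro(self):
        s = initial_state(EulerAngles(0, 0, 0), CFG)
        with pytest.raises(ValueError):
            ekf_predict(s, np.array([np.inf, 0, 0]), CFG)


class TestMeasurementModel:
    def test_identity_orientation(self):
        z = predict_measurement(quat_identity(), CFG)
        hx, _, hz = CFG.mag_reference
        np.testing.assert_allclose(z, [hx, 0, hz, 0, 0, GRAVITY], atol=1e-12)

    def test_yaw_rotation_swaps_mag_leaves_gravity(self):
        q = quat_from_axis_angle([0, 0, 1], np.pi / 2)
        z = predict_measurement(q, CFG)
        hx, _, hz = CFG.mag_reference
        # body sees the earth field rotated the opposite way
        np.testing.assert_allclose(z[:3], [0, -hx, hz], atol=1e-12)
        np.testing.assert_allclose(z[3:], [0, 0, GRAVITY], atol=1e-12)

    def test_block_norms_are_invariant(self, rng):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        z = predict_measurement(q, CFG)
        assert np.linalg.norm(z[:3]) == pytest.approx(
            np.linalg.norm(CFG.mag_reference), rel=1e-9)
        assert np.linalg.norm(z[3:]) == pytest.approx(GRAVITY, rel=1e-9)

    def test_jacobian_matches_central_differences(self, rng):
        eps = 1e-7
        for _ in range(50):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            H = measurement_jacobian(q, CFG)
            num = np.empty((6, 4))
            for k in range(4):
                dq = np.zeros(4)
                dq[k] = eps
                num[:, k] = (predict_measurement(q + dq, CFG)
                             - predict_measurement(q - dq, CFG)) / (2 * eps)
            assert np.max(np.abs(H[:, :4] - num)) < 1e-6

    def test_bias_columns_zero_and_gravity_linearity(self, rng):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        H = measurement_jacobian(q, CFG)
        np.testing.assert_allclose(H[:, 4:], 0)
        cfg2 = EkfConfig(gravity_g=2 * GRAVITY)
        H2 = measurement_jacobian(q, cfg2)
        np.testing.assert_allclose(H2[3:, :4], 2 * H[3:, :4], rtol=1e-12)


class TestUpdate:
    def test_zero_innovation_leaves_state(self, rng):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        s = EkfState(x=np.concatenate([q, np.zeros(3)]),
                     P=np.diag([1e-4] * 4 + [1e-3] * 3))
        z = predict_measurement(q, CFG)
        s2 = ekf_update(s, z, CFG)
        assert np.max(np.abs(s2.x - s.x)) < 1e-12
        s2.validate()

    def test_static_convergence_from_offset_attitude(self, rng):
        from strokekin.quat import quat_multiply, quat_normalize

        truth = quat_from_euler(EulerAngles(0.3, -0.4, 1.0))
        stream = static_stream(truth, 2000, noise_params(), seed=5)
        # start the filter 10 degrees off
        offset = quat_from_axis_angle(rng.normal(size=3), np.radians(10))
        x0 = np.concatenate(
            [quat_normalize(quat_multiply(offset, truth)), np.zeros(3)])
        s = EkfState(x=x0, P=np.diag([1e-2] * 4 + [1e-3] * 3))
        for i in range(len(stream)):
            s = ekf_predict(s, stream.gyro[i], CFG)
            s = ekf_update(s, np.concatenate(
                [stream.mag[i], stream.accel[i]]), CFG)
        assert np.degrees(orientation_distance(s.quat, truth)) < 1.0

    def test_gyro_bias_recovery(self):
        # 60 s of mixed static/slow-rotation data with 0.5 deg/s bias/axis
        fs, dur = 400.0, 60.0
        n = int(fs * dur)
        t = np.arange(n) / fs
        angle = np.radians(20) * np.sin(2 * np.pi * 0.25 * t)
        orient = np.asarray(quat_from_axis_angle([0, 1, 0], angle))
        params = noise_params(gyro_bias_deg_s=np.array([0.5, 0.5, 0.5]))
        stream = simulate_imu(orient, params, "n", np.random.default_rng(2))
        _, final = run_fusion(stream, CFG, return_state=True)
        np.testing.assert_allclose(
            final.gyro_bias, 0.5 * DEG, rtol=0.10)


class TestRunFusion:
    def test_static_stream_low_drift(self):
        truth = quat_from_euler(EulerAngles(0.2, 0.1, -0.7))
        stream = static_stream(truth, int(30 * 400), noise_params(), seed=9)
        q = run_fusion(stream, CFG)
        err = np.degrees(orientation_distance(q, np.asarray(truth)))
        assert err[-1] < 1.0 and np.max(err[400:]) < 1.0

    def test_sinusoidal_rotation_tracking(self):
        fs = 400.0
        n = int(10 * fs)
        t = np.arange(n) / fs
        # static first second for initialization, then 0.5 Hz oscillation
        angle = np.where(t < 1.0, 0.0,
                         np.radians(30) * np.sin(2 * np.pi * 0.5 * (t - 1.0)))
        orient = np.asarray(quat_from_axis_angle([0, 1, 0], angle))
        stream = simulate_imu(orient, noise_params(), "n",
                              np.random.default_rng(4))
        q = run_fusion(stream, CFG)
        err = np.degrees(orientation_distance(q, orient))
        assert len(q) == n
        assert np.sqrt(np.mean(err[400:] ** 2)) < 2.0

    def test_matches_initializer_when_noise_vanishes(self):
        truth = quat_from_euler(EulerAngles(0.3, 0.5, 0.9))
        stream = static_stream(truth, 800, quiet_params(), seed=1)
        q = run_fusion(stream, CFG)
        e = initial_euler(stream.accel[0], stream.mag[0])
        q_init = quat_from_euler(e)
        assert np.degrees(orientation_distance(q[-1], q_init)) < 1e-3

    def test_yaw_offset_equivariance(self):
        # rotating the whole trajectory in yaw must not change the error
        fs = 400.0
        n = int(5 * fs)
        t = np.arange(n) / fs
        angle = np.where(t < 1.0, 0.0,
                         np.radians(25) * np.sin(2 * np.pi * 0.5 * (t - 1.0)))
        base = np.asarray(quat_from_axis_angle([1, 0, 0], angle))
        errs = []
        from strokekin.quat import quat_multiply
        for yaw in (0.0, 1.1):
            offset = quat_from_axis_angle([0, 0, 1], yaw)
            orient = np.asarray(quat_multiply(
                np.tile(offset, (n, 1)), base))
            stream = simulate_imu(orient, noise_params(), "n",
                                  np.random.default_rng(8))
            q = run_fusion(stream, CFG)
            err = np.degrees(orientation_distance(q, orient))
            errs.append(np.sqrt(np.mean(err[400:] ** 2)))
        assert errs[0] == pytest.approx(errs[1], abs=0.1)

    def test_empty_and_zero_mag_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            run_fusion(SensorStream("n", np.empty(0), np.empty((0, 3)),
                                    np.empty((0, 3)), np.empty((0, 3))), CFG)
        stream = static_stream(quat_identity(), 100, quiet_params())
        stream.mag[:] = 0.0
        with pytest.raises(ValueError, match="magnetometer"):
            run_fusion(stream, CFG)


def test_invariants_over_long_randomized_run(rng):
    """Unit quaternion norm and covariance symmetry/PSD over 10,000 steps."""
    s = initial_state(EulerAngles(0.1, -0.2, 0.5), CFG)
    for i in range(10_000):
        gyro = rng.normal(0, 1.0, 3)
        s = ekf_predict(s, gyro, CFG)
        z = predict_measurement(s.quat, CFG) + rng.normal(0, 0.02, 6)
        s = ekf_update(s, z, CFG)
        assert abs(np.linalg.norm(s.quat) - 1.0) < 1e-9
        if i % 200 == 0:
            assert np.max(np.abs(s.P - s.P.T)) < 1e-9
            assert np.min(np.linalg.eigvalsh(s.P)) > -1e-9


def test_stream_validation():
    t = np.array([0.0, 0.01, 0.005])
    with pytest.raises(ValueError, match="strictly increasing"):
        SensorStream("n", t, np.zeros((3, 3)), np.zeros((3, 3)),
                     np.zeros((3, 3)), sample_rate_hz=100.0)
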