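"""Unit, oracle, and property tests for the strapdown + error-state filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm
from scipy.spatial.transform import Rotation

from zuptgait import (
    GRAVITY,
    ArtifactSpec,
    EskfConfig,
    GaitSpec,
    NavState,
    attitude_update,
    detect_zero_velocity,
    inject_artifacts,
    predict_covariance,
    run_eskf,
    strapdown_step,
    synth_stationary,
    synth_walk_trajectory,
    trajectory_to_imu,
    zupt_correct,
)
from zuptgait.errors import (
    ConfigurationError,
    DataLossError,
    InitializationError,
)
from zuptgait.imu_records import ImuRecording, ImuSample
from zuptgait.zupt_eskf import EskfMatrices, H_MATRIX, skew


def _random_psd(rng, n=9):
    A = rng.normal(size=(n, n))
    return A @ A.T


class TestAttitudeUpdate:
    def test_zero_rate_identity(self, rng):
        R = Rotation.random(random_state=3).as_matrix()
        out = attitude_update(R, np.zeros(3), 0.01)
        np.testing.assert_allclose(out, R, atol=1e-12)

    def test_quarter_turn_about_z(self):
        out = attitude_update(np.eye(3), np.array([0.0, 0.0, np.pi / 2]), 1.0)
        np.testing.assert_allclose(out[:, 0], [0.0, 1.0, 0.0], atol=1e-12)
        oracle = expm(skew([0.0, 0.0, np.pi / 2]))
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_matches_matrix_exponential_oracle(self, rng):
        for _ in range(200):
            omega = rng.normal(0, 5, 3)
            dt = rng.uniform(1e-4, 0.1)
            R0 = Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix()
            ours = attitude_update(R0, omega, dt)
            oracle = R0 @ expm(skew(omega * dt))
            assert np.linalg.norm(ours - oracle) < 1e-9

    def test_small_angle_series_branch(self):
        omega = np.array([1e-10, 0.0, 0.0])
        out = attitude_update(np.eye(3), omega, 1.0)
        oracle = expm(skew(omega))
        np.testing.assert_allclose(out, oracle, atol=1e-15)

    @given(
        wx=st.floats(-20, 20), wy=st.floats(-20, 20), wz=st.floats(-20, 20),
        dt=st.floats(1e-6, 0.1),
    )
    @settings(max_examples=50, deadline=None)
    def test_result_is_rotation(self, wx, wy, wz, dt):
        out = attitude_update(np.eye(3), np.array([wx, wy, wz]), dt)
        np.testing.assert_allclose(out.T @ out, np.eye(3), atol=1e-9)
        assert np.linalg.det(out) == pytest.approx(1.0, abs=1e-9)


class TestStrapdownStep:
    def test_rest_is_fixed_point(self):
        state = NavState()
        sample = ImuSample(0.0, np.array([0.0, 0.0, GRAVITY]), np.zeros(3))
        out = strapdown_step(state, sample, 0.01)
        np.testing.assert_allclose(out.v, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.s, 0.0, atol=1e-14)

    def test_constant_force_euler_sum(self):
        state = NavState()
        f = np.array([1.0, 0.0, GRAVITY])
        dt = 0.01
        for i in range(100):
            state = strapdown_step(state, ImuSample(i * dt, f, np.zeros(3)), dt)
        assert state.v[0] == pytest.approx(100 * dt * 1.0, rel=1e-12)


class TestPredictCovariance:
    def test_zero_noise_zero_p_fixed_point(self):
        mats = EskfMatrices(P=np.zeros((9, 9)), Sigma_w=np.zeros((9, 9)))
        out = predict_covariance(mats, np.eye(3), np.array([0.0, 0.0, GRAVITY]), 0.01)
        assert np.all(out.P == 0.0)

    def test_transition_block_is_dt_skew_rf(self):
        mats = EskfMatrices()
        f = np.array([0.0, 0.0, 9.80665])
        out = predict_covariance(mats, np.eye(3), f, 0.01)
        np.testing.assert_allclose(out.F[3:6, 0:3], 0.01 * skew(f), atol=1e-15)
        np.testing.assert_allclose(out.F[6:9, 3:6], 0.01 * np.eye(3), atol=1e-15)
        # remaining structure: identity diagonal, zero elsewhere
        np.testing.assert_allclose(out.F[0:3, 0:3], np.eye(3))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_trace_nondecreasing_without_correction(self, seed):
        rng = np.random.default_rng(seed)
        R = Rotation.random(random_state=seed).as_matrix()
        f = rng.normal(0, 10, 3)
        sw = np.diag(np.abs(rng.normal(0, 1e-4, 9)))
        mats = EskfMatrices(P=np.zeros((9, 9)), Sigma_w=sw)
        prev = 0.0
        for _ in range(100):
            mats = predict_covariance(mats, R, f, 0.01)
            tr = np.trace(mats.P)
            assert tr >= prev - 1e-15
            prev = tr

    def test_symmetry_preserved(self, rng):
        mats = EskfMatrices(P=_random_psd(rng), Sigma_w=np.eye(9) * 1e-6)
        out = predict_covariance(mats, np.eye(3), rng.normal(0, 5, 3), 0.01)
        np.testing.assert_allclose(out.P, out.P.T, atol=1e-12)
        assert np.linalg.eigvalsh(out.P)[0] > -1e-9


class TestZuptCorrect:
    def test_zero_velocity_no_change(self, rng):
        mats = EskfMatrices(P=_random_psd(rng))
        state = NavState(v=np.zeros(3), s=np.array([1.0, 2.0, 3.0]))
        _, out = zupt_correct(mats, state)
        np.testing.assert_allclose(out.v, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.s, state.s, atol=1e-12)
        np.testing.assert_allclose(out.R, state.R, atol=1e-12)

    def test_zero_measurement_noise_pins_velocity(self):
        mats = EskfMatrices(P=np.eye(9), Sigma_v=np.zeros((3, 3)))
        state = NavState(v=np.array([0.3, -0.2, 0.1]))
        _, out = zupt_correct(mats, state)
        np.testing.assert_allclose(out.v, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_velocity_never_grows_block_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        blocks = [_random_psd(rng, 3) for _ in range(3)]
        P = np.zeros((9, 9))
        for b, blk in enumerate(blocks):
            P[3 * b:3 * b + 3, 3 * b:3 * b + 3] = blk
        mats = EskfMatrices(P=P)
        state = NavState(v=rng.normal(0, 0.5, 3))
        _, out = zupt_correct(mats, state)
        assert np.linalg.norm(out.v) <= np.linalg.norm(state.v) + 1e-12

    def test_joseph_form_equivalence(self, rng):
        mats = EskfMatrices(P=_random_psd(rng))
        state = NavState(v=rng.normal(0, 1, 3))
        out, _ = zupt_correct(mats, state)
        joseph = (np.eye(9) - out.K @ H_MATRIX) @ mats.P
        np.testing.assert_allclose(out.P, 0.5 * (joseph + joseph.T), atol=1e-10)

    def test_covariance_contracts(self, rng):
        mats = EskfMatrices(P=_random_psd(rng))
        state = NavState(v=rng.normal(0, 1, 3))
        out, _ = zupt_correct(mats, state)
        assert np.trace(out.P) <= np.trace(mats.P)
        assert np.linalg.eigvalsh(out.P)[0] > -1e-9


class TestDetectZeroVelocity:
    def test_pure_rest_all_true(self):
        rec = synth_stationary(5.0, 100.0)
        mask = detect_zero_velocity(rec)
        assert mask.stationary.all()

    def test_continuous_rotation_all_false(self):
        n = 500
        t = np.arange(n) / 100.0
        rec = ImuRecording(
            t=t, f=np.tile([0.0, 0.0, GRAVITY], (n, 1)),
            omega=np.tile([0.0, 0.0, 2.0], (n, 1)), fs_configured=100.0,
        )
        mask = detect_zero_velocity(rec)
        assert not mask.stationary.any()

    def test_matches_truth_stance_segments(self, clean_walk):
        _, traj, rec = clean_walk
        mask = detect_zero_velocity(rec)
        edge = 0.06  # half window + one sample
        for i, t in enumerate(rec.t):
            inside = any(a + edge < t < b - edge for a, b in traj.truth_stance_intervals)
            in_swing = not any(a - edge <= t <= b + edge for a, b in traj.truth_stance_intervals)
            if inside:
                assert mask.stationary[i], f"stance sample {t} not flagged"
            if in_swing:
                assert not mask.stationary[i], f"swing sample {t} flagged stationary"

    def test_window_too_short(self, clean_walk):
        _, _, rec = clean_walk
        with pytest.raises(ConfigurationError):
            detect_zero_velocity(rec, window=0.001)


class TestRunEskf:
    def test_noiseless_walk_recovers_positions(self, clean_walk):
        _, traj, rec = clean_walk
        est, mask, diag = run_eskf(rec)
        assert np.abs(est.s - traj.position).max() < 1e-3
        assert diag["min_covariance_eigenvalue"] >= -1e-9

    def test_rest_only_recording_stays_put(self):
        rec = synth_stationary(5.0, 100.0)
        est, _, _ = run_eskf(rec)
        assert np.linalg.norm(est.s, axis=1).max() < 1e-3

    def test_no_initial_rest_raises(self, clean_walk):
        _, traj, rec = clean_walk
        # chop off everything before mid-swing of the first stride
        i0 = np.searchsorted(rec.t, 2.8)
        chopped = ImuRecording(
            t=rec.t[i0:] - rec.t[i0], f=rec.f[i0:], omega=rec.omega[i0:],
            fs_configured=rec.fs_configured,
        )
        with pytest.raises(InitializationError):
            run_eskf(chopped)

    def test_oversized_gap_aborts_with_intervals(self, clean_walk):
        _, _, rec = clean_walk
        keep = np.ones(rec.n_samples, bool)
        keep[500:520] = False
        gapped = ImuRecording(
            t=rec.t[keep], f=rec.f[keep], omega=rec.omega[keep],
            fs_configured=rec.fs_configured,
        )
        with pytest.raises(DataLossError) as exc_info:
            run_eskf(gapped)
        assert len(exc_info.value.gap_intervals) == 1

    def test_small_gaps_tolerated_without_bridging(self, clean_walk):
        _, traj, rec = clean_walk
        keep = np.ones(rec.n_samples, bool)
        keep[[400, 401, 700]] = False  # worst gap 3 dt, under the 3.5 dt abort
        gapped = ImuRecording(
            t=rec.t[keep], f=rec.f[keep], omega=rec.omega[keep],
            fs_configured=rec.fs_configured,
        )
        est, _, _ = run_eskf(gapped)
        assert np.abs(est.s[-1] - traj.position[-1]).max() < 0.1

    def test_bridging_flag(self, clean_walk):
        _, traj, rec = clean_walk
        keep = np.ones(rec.n_samples, bool)
        keep[600:603] = False  # 3 missing samples -> 4 dt gap, aborts by default
        gapped = ImuRecording(
            t=rec.t[keep], f=rec.f[keep], omega=rec.omega[keep],
            fs_configured=rec.fs_configured,
        )
        with pytest.raises(DataLossError):
            run_eskf(gapped)
        est, _, _ = run_eskf(gapped, EskfConfig(bridge_gaps=True))
        assert np.abs(est.s[-1] - traj.position[-1]).max() < 0.05

    def test_zupt_efficacy_drift_ratio(self):
        spec = GaitSpec(n_strides=55, seed=21)
        traj = synth_walk_trajectory(spec)
        rec = inject_artifacts(trajectory_to_imu(traj), ArtifactSpec(seed=23))
        assert rec.duration > 55.0
        est_on, _, diag = run_eskf(rec)
        est_off, _, _ = run_eskf(rec, EskfConfig(apply_zupt=False, check_psd=False))
        drift_on = np.linalg.norm(est_on.s[-1] - traj.position[-1])
        drift_off = np.linalg.norm(est_off.s[-1] - traj.position[-1])
        assert drift_off / drift_on > 10.0
        assert diag["min_covariance_eigenvalue"] >= -1e-9
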