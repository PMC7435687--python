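"""ZUPT-aided error-state Kalman filter over strapdown integration.

Attitude is propagated with the Rodrigues rotation formula (the closed
form of the SO(3) exponential map), velocity and displacement with the
explicit Euler scheme.  A 9-dimensional error state (attitude error,
velocity error, position error) is tracked by a Kalman filter whose
correction stage runs whenever the foot is detected stationary, using the
pseudo-measurement that foot velocity is zero during stance.

The stationary detector is a windowed test on gyro magnitude and on the
deviation of the specific-force magnitude from standard gravity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import maximum_filter1d

from zuptgait.errors import (
    ConfigurationError,
    DataLossError,
    InitializationError,
    InsufficientDataError,
    NumericalStateError,
)
from zuptgait.imu_records import GRAVITY, ImuRecording, ImuSample, detect_gaps

G_VEC = np.array([0.0, 0.0, -GRAVITY])

_I3 = np.eye(3)
_I9 = np.eye(9)

#: Measurement selector: keeps only the velocity block of the error state.
H_MATRIX = np.hstack([np.zeros((3, 3)), np.eye(3), np.zeros((3, 3))])

#: Tolerance on negative covariance eigenvalues before the filter aborts.
PSD_TOL = 1e-9


def skew(v) -> np.ndarray:
    """Skew-symmetric (cross-product) matrix of a 3-vector."""
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def _orthonormalize(R: np.ndarray) -> np.ndarray:
    """Re-orthonormalize a near-rotation matrix.

    One step of the symmetric Newton iteration ``R(3I - R^T R)/2`` — a
    quadratically convergent projection toward the polar factor, ample
    for the tiny per-step drift of the Rodrigues update.  Falls back to
    an SVD polar projection if the input has drifted far.
    """
    E = R.T @ R - _I3
    if abs(E).max() < 1e-4:
        return R @ (_I3 - 0.5 * E)
    U, _, Vt = np.linalg.svd(R)
    D = U @ Vt
    if np.linalg.det(D) < 0:
        U[:, -1] = -U[:, -1]
        D = U @ Vt
    return D


@dataclass
class NavState:
    """Attitude, velocity and displacement of the foot at one instant."""

    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    v: np.ndarray = field(default_factory=lambda: np.zeros(3))
    s: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def copy(self) -> "NavState":
        return NavState(self.R.copy(), self.v.copy(), self.s.copy())


@dataclass
class EskfMatrices:
    """Covariance and noise matrices of the 9-state error filter.

    Error-state ordering: attitude error, velocity error, position error
    (three components each).
    """

    P: np.ndarray = field(default_factory=lambda: np.zeros((9, 9)))
    Sigma_w: np.ndarray = field(default_factory=lambda: np.zeros((9, 9)))
    Sigma_v: np.ndarray = field(default_factory=lambda: 1e-4 * np.eye(3))
    H: np.ndarray = field(default_factory=lambda: H_MATRIX.copy())
    F: np.ndarray | None = None   # last transition matrix
    S: np.ndarray | None = None   # last skew(R f)
    K: np.ndarray | None = None   # last Kalman gain
    dx: np.ndarray | None = None  # last error-state estimate

    def copy(self) -> "EskfMatrices":
        return EskfMatrices(
            P=self.P.copy(), Sigma_w=self.Sigma_w.copy(),
            Sigma_v=self.Sigma_v.copy(), H=self.H.copy(),
            F=None if self.F is None else self.F.copy(),
            S=None if self.S is None else self.S.copy(),
            K=None if self.K is None else self.K.copy(),
            dx=None if self.dx is None else self.dx.copy(),
        )


@dataclass
class ZuptMask:
    """Per-sample stationary flags plus the detector parameters used."""

    stationary: np.ndarray
    window: float = 0.1
    gyro_threshold: float = 0.6
    accel_threshold: float = 0.8
    min_duration: float = 0.05

    def __len__(self) -> int:
        return len(self.stationary)


@dataclass
class EskfConfig:
    """All tunables of the stationary detector and the error filter."""

    # stationary detector
    zupt_window: float = 0.1            # s, centered
    gyro_threshold: float = 0.6         # rad/s
    accel_threshold: float = 0.8        # m/s^2
    min_duration: float = 0.05          # s
    # process / measurement noise
    sigma_gyro: float = 0.05            # rad/s, attitude random walk driver
    sigma_accel: float = 0.5            # m/s^2, velocity random walk driver
    sigma_zupt: float = 0.01            # m/s, zero-velocity measurement noise
    # initialization and gap policy
    init_rest_duration: float = 0.5     # s of stationary data required at start
    max_gap: float | None = None        # s; default 3.5 nominal intervals
    bridge_gaps: bool = False           # linearly interpolate gaps <= 3 samples
    check_psd: bool = True              # verify P stays PSD every step
    apply_zupt: bool = True             # disable for open-loop drift studies

    def sigma_w(self, dt: float) -> np.ndarray:
        """Default process-noise covariance: diagonal blocks
        (sigma_gyro^2 dt^2, sigma_accel^2 dt^2, 0) per axis."""
        d = np.concatenate([
            np.full(3, (self.sigma_gyro * dt) ** 2),
            np.full(3, (self.sigma_accel * dt) ** 2),
            np.zeros(3),
        ])
        return np.diag(d)

    def sigma_v(self) -> np.ndarray:
        return self.sigma_zupt**2 * np.eye(3)


@dataclass
class NavTrajectory:
    """Estimated state history; indexable as a sequence of NavState."""

    t: np.ndarray            # (n,)
    R: np.ndarray            # (n, 3, 3)
    v: np.ndarray            # (n, 3)
    s: np.ndarray            # (n, 3)

    def __len__(self) -> int:
        return len(self.t)

    def __getitem__(self, i) -> NavState:
        if isinstance(i, slice):
            return NavTrajectory(self.t[i], self.R[i], self.v[i], self.s[i])
        return NavState(self.R[i], self.v[i], self.s[i])


def detect_zero_velocity(
    rec: ImuRecording,
    window: float = 0.1,
    gyro_threshold: float = 0.6,
    accel_threshold: float = 0.8,
    min_duration: float = 0.05,
) -> ZuptMask:
    """Windowed stationary detector.

    Sample ``i`` is stationary iff over a centered window the maximum
    gyro magnitude stays below ``gyro_threshold`` and the maximum
    deviation of the specific-force magnitude from standard gravity stays
    below ``accel_threshold``.  Stationary runs shorter than
    ``min_duration`` are removed.
    """
    n = rec.n_samples
    if n < 2:
        raise InsufficientDataError("need at least 2 samples")
    win_samples = int(round(window * rec.fs_configured))
    if win_samples < 2:
        raise ConfigurationError("zupt window shorter than 2 samples")

    gyro_mag = np.linalg.norm(rec.omega, axis=1)
    accel_dev = np.abs(np.linalg.norm(rec.f, axis=1) - GRAVITY)
    gyro_max = maximum_filter1d(gyro_mag, size=win_samples, mode="nearest")
    accel_max = maximum_filter1d(accel_dev, size=win_samples, mode="nearest")
    mask = (gyro_max < gyro_threshold) & (accel_max < accel_threshold)

    min_run = max(1, int(round(min_duration * rec.fs_configured)))
    mask = _drop_short_runs(mask, min_run)
    return ZuptMask(
        stationary=mask, window=window, gyro_threshold=gyro_threshold,
        accel_threshold=accel_threshold, min_duration=min_duration,
    )


def _drop_short_runs(mask: np.ndarray, min_run: int) -> np.ndarray:
    mask = mask.copy()
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    for s, e in zip(starts, ends):
        if e - s < min_run:
            mask[s:e] = False
    return mask


def attitude_update(R_prev: np.ndarray, omega: np.ndarray, dt: float) -> np.ndarray:
    """Propagate attitude by one step of the Rodrigues rotation formula.

    Equals ``R_prev @ expm(skew(omega * dt))``; the small-angle branch
    uses the series ``sin(x)/x ~ 1 - x^2/6`` and
    ``(1-cos(x))/x^2 ~ 1/2 - x^2/24``.  The result is re-orthonormalized.
    """
    phi = np.asarray(omega, dtype=float) * dt
    sigma = float(np.linalg.norm(phi))
    B = skew(phi)
    if sigma < 1e-8:
        c1 = 1.0 - sigma**2 / 6.0
        c2 = 0.5 - sigma**2 / 24.0
    else:
        c1 = np.sin(sigma) / sigma
        c2 = (1.0 - np.cos(sigma)) / sigma**2
    R = R_prev @ (_I3 + c1 * B + c2 * (B @ B))
    return _orthonormalize(R)


def strapdown_step(state: NavState, sample: ImuSample, dt: float) -> NavState:
    """One explicit-Euler strapdown step.

    Attitude from the Rodrigues update, then gravity-compensated
    acceleration ``a = R f + g``, ``v += dt a``, ``s += dt v``.
    """
    R = attitude_update(state.R, sample.omega, dt)
    a = R @ sample.f + G_VEC
    v = state.v + dt * a
    s = state.s + dt * v
    return NavState(R=R, v=v, s=s)


def predict_covariance(
    mats: EskfMatrices, R: np.ndarray, f: np.ndarray, dt: float
) -> EskfMatrices:
    """Error-covariance prediction ``P <- F P F^T + Sigma_w``.

    ``F`` couples attitude error into velocity error through the skew
    matrix of the navigation-frame specific force ``R f``.
    """
    if mats.P.shape != (9, 9):
        raise NumericalStateError("P must be 9x9")
    if not np.allclose(mats.P, mats.P.T, atol=1e-8):
        raise NumericalStateError("P lost symmetry")
    S = skew(R @ f)
    F = _I9.copy()
    F[3:6, 0:3] = dt * S
    F[6:9, 3:6] = dt * _I3
    P = F @ mats.P @ F.T + mats.Sigma_w
    P = 0.5 * (P + P.T)
    out = mats.copy()
    out.P = P
    out.F = F
    out.S = S
    return out


def zupt_correct(mats: EskfMatrices, state: NavState) -> tuple[EskfMatrices, NavState]:
    """Zero-velocity correction stage.

    Gain ``K = P H^T (H P H^T + Sigma_v)^-1``, error estimate
    ``dx = K (0 - v)``, covariance ``P <- P - K H P``.  Velocity and
    position corrections are additive; the attitude-error sub-vector is
    applied as a small-angle rotation ``R <- (I - skew(dtheta)) R``
    (the sign that matches the ``+dt S`` coupling in the transition
    matrix), then re-orthonormalized.
    """
    P = mats.P
    Hm = mats.H
    innov_cov = Hm @ P @ Hm.T + mats.Sigma_v
    try:
        K = np.linalg.solve(innov_cov.T, (P @ Hm.T).T).T
    except np.linalg.LinAlgError as exc:
        raise NumericalStateError("singular innovation covariance") from exc
    dx = K @ (-state.v)
    P_new = P - K @ Hm @ P
    P_new = 0.5 * (P_new + P_new.T)

    dtheta, dv, ds = dx[0:3], dx[3:6], dx[6:9]
    R = _orthonormalize((_I3 - skew(dtheta)) @ state.R)
    new_state = NavState(R=R, v=state.v + dv, s=state.s + ds)

    out = mats.copy()
    out.P = P_new
    out.K = K
    out.dx = dx
    return out, new_state


def _initial_attitude(f_mean: np.ndarray) -> np.ndarray:
    """Roll/pitch from the gravity direction during initial rest; yaw = 0.

    Returns the minimal rotation mapping the mean specific force onto the
    global +z axis.
    """
    norm = np.linalg.norm(f_mean)
    if norm == 0:
        raise InitializationError("zero mean specific force during initial rest")
    a = f_mean / norm
    b = np.array([0.0, 0.0, 1.0])
    v = np.cross(a, b)
    c = float(a @ b)
    if c < -1.0 + 1e-12:
        raise InitializationError("device appears upside-down during initial rest")
    Vx = skew(v)
    R = _I3 + Vx + Vx @ Vx / (1.0 + c)
    return _orthonormalize(R)


def _bridge_small_gaps(rec: ImuRecording, max_missing: int = 3) -> ImuRecording:
    """Linearly interpolate gaps of at most ``max_missing`` samples."""
    dt = rec.nominal_dt
    t_new = [rec.t[0]]
    f_new = [rec.f[0]]
    w_new = [rec.omega[0]]
    for i in range(1, rec.n_samples):
        gap = rec.t[i] - rec.t[i - 1]
        n_missing = int(round(gap / dt)) - 1
        if 1 <= n_missing <= max_missing:
            for k in range(1, n_missing + 1):
                frac = k / (n_missing + 1)
                t_new.append(rec.t[i - 1] + frac * gap)
                f_new.append(rec.f[i - 1] + frac * (rec.f[i] - rec.f[i - 1]))
                w_new.append(rec.omega[i - 1] + frac * (rec.omega[i] - rec.omega[i - 1]))
        t_new.append(rec.t[i])
        f_new.append(rec.f[i])
        w_new.append(rec.omega[i])
    return replace(
        rec, t=np.array(t_new), f=np.array(f_new), omega=np.array(w_new)
    )


def run_eskf(
    rec: ImuRecording,
    config: EskfConfig | None = None,
    mask: ZuptMask | None = None,
) -> tuple[NavTrajectory, ZuptMask, dict]:
    """Run the full ZUPT-aided error-state Kalman filter over a recording.

    Initial attitude comes from the mean specific force over the initial
    stationary period (roll/pitch from gravity, yaw zero); initial
    velocity and position are zero.  Each sample is propagated with
    :func:`strapdown_step` and :func:`predict_covariance`; the zero-
    velocity correction is applied on samples flagged stationary.

    Gaps longer than ``config.max_gap`` abort with a
    :class:`~zuptgait.errors.DataLossError` listing the gap intervals;
    with ``config.bridge_gaps`` gaps of at most 3 samples are linearly
    interpolated first.

    Returns the estimated state history, the stationary mask used, and a
    diagnostics dict (ZUPT intervals, correction count, minimum
    covariance eigenvalue, gap report).
    """
    if config is None:
        config = EskfConfig()
    if rec.n_samples < 3:
        raise InsufficientDataError("recording too short")

    gap_report = detect_gaps(rec)
    if config.bridge_gaps and gap_report.n_gaps:
        rec = _bridge_small_gaps(rec)
        gap_report = detect_gaps(rec)
    max_gap = config.max_gap
    if max_gap is None:
        max_gap = 3.5 * rec.nominal_dt
    oversized = [
        (a, b) for (a, b) in gap_report.gap_intervals if (b - a) > max_gap
    ]
    if oversized:
        raise DataLossError(
            f"{len(oversized)} gaps exceed {max_gap:.4f} s; "
            "recording cannot be integrated reliably",
            gap_intervals=oversized,
        )

    if mask is None:
        mask = detect_zero_velocity(
            rec,
            window=config.zupt_window,
            gyro_threshold=config.gyro_threshold,
            accel_threshold=config.accel_threshold,
            min_duration=config.min_duration,
        )
    stationary = mask.stationary
    if len(stationary) != rec.n_samples:
        raise ConfigurationError("mask length does not match recording")

    # initial rest: leading stationary run
    if not stationary[0]:
        first_true = np.flatnonzero(stationary)
        raise InitializationError(
            "no stationary period at the start of the recording"
            + ("" if first_true.size else " (none found at all)")
        )
    init_end = int(np.argmin(stationary)) if not stationary.all() else rec.n_samples
    init_span = rec.t[init_end - 1] - rec.t[0]
    if init_span < config.init_rest_duration:
        raise InitializationError(
            f"initial rest of {init_span:.3f} s is shorter than the "
            f"required {config.init_rest_duration:.3f} s"
        )

    f_mean = rec.f[:init_end].mean(axis=0)
    R0 = _initial_attitude(f_mean)
    state = NavState(R=R0, v=np.zeros(3), s=np.zeros(3))

    n = rec.n_samples
    dt_nom = rec.nominal_dt
    mats = EskfMatrices(
        P=np.zeros((9, 9)),
        Sigma_w=config.sigma_w(dt_nom),
        Sigma_v=config.sigma_v(),
    )

    R_hist = np.empty((n, 3, 3))
    v_hist = np.empty((n, 3))
    s_hist = np.empty((n, 3))
    R_hist[0], v_hist[0], s_hist[0] = state.R, state.v, state.s

    n_corrections = 0
    min_eig = np.inf
    apply_zupt = config.apply_zupt
    check_psd = config.check_psd
    for i in range(1, n):
        dt = float(rec.t[i] - rec.t[i - 1])
        if dt <= 0:
            raise NumericalStateError(f"non-increasing timestamp at sample {i}")
        state = strapdown_step(state, rec.sample(i), dt)
        mats = predict_covariance(mats, state.R, rec.f[i], dt)
        if apply_zupt and stationary[i]:
            mats, state = zupt_correct(mats, state)
            n_corrections += 1
        if check_psd:
            eig = np.linalg.eigvalsh(mats.P)[0]
            if eig < min_eig:
                min_eig = eig
            if eig < -PSD_TOL:
                raise NumericalStateError(
                    f"covariance lost positive semidefiniteness at sample {i}"
                )
        R_hist[i], v_hist[i], s_hist[i] = state.R, state.v, state.s

    padded = np.concatenate(([False], stationary, [False]))
    d = np.diff(padded.astype(int))
    zupt_intervals = [
        (float(rec.t[s]), float(rec.t[e - 1]))
        for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1))
    ]
    diagnostics = {
        "n_corrections": n_corrections,
        "zupt_intervals": zupt_intervals,
        "min_covariance_eigenvalue": float(min_eig) if check_psd else None,
        "gap_report": gap_report,
        "initial_attitude": R0,
    }
    traj = NavTrajectory(t=rec.t.copy(), R=R_hist, v=v_hist, s=s_hist)
    return traj, mask, diagnostics
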