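"""Synthetic walking-data generator.

Builds ground-truth foot trajectories (position, velocity, attitude, and a
per-stride truth table), converts them into ideal IMU signals by inverting
the strapdown integration scheme, and injects vendor-style artifacts
(noise, bias, full-scale clipping, packet loss, timestamp jitter).

The trajectory alternates exactly-stationary stance segments with smooth
swing segments: minimum-jerk horizontal displacement, a C2 vertical
clearance arc, and a sagittal pitch profile whose angular velocity shows
the classic foot signature (negative lobes at foot-off and initial
contact, dominant positive peak at midswing).  Because the inverse uses
the discrete differences of the exact forward Euler scheme, integrating
the emitted signals open-loop from the exact initial state reproduces the
trajectory to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import truncnorm

from zuptgait.errors import SpecError
from zuptgait.imu_records import DEG2RAD, GRAVITY, ImuRecording, ReferenceStride

#: Global-frame gravity vector (z-up convention).
G_VEC = np.array([0.0, 0.0, -GRAVITY])


@dataclass
class GaitSpec:
    """Specification of a synthetic straight or turning walk.

    Stride lengths and times are drawn per stride from normal
    distributions truncated at +/-3 sd and at zero.  ``turn_every`` > 0
    inserts a 180-degree in-place turn during the stance that opens every
    ``turn_every``-th stride.
    """

    n_strides: int = 10
    stride_length_mean: float = 1.2
    stride_length_sd: float = 0.05
    stride_time_mean: float = 1.0
    stride_time_sd: float = 0.05
    clearance: float = 0.05
    stance_fraction: float = 0.6
    turn_every: int = 0
    fs: float = 100.0
    seed: int = 0
    foot: str = "right"
    lead_in: float = 2.0
    lead_out: float = 2.0
    midswing_peak_rate: float = 4.5  # rad/s, sagittal gyro peak at midswing

    def validate(self) -> None:
        if self.n_strides < 1:
            raise SpecError("n_strides must be >= 1")
        if self.stride_length_mean <= 0 or self.stride_time_mean <= 0:
            raise SpecError("stride length/time means must be positive")
        if self.stride_length_sd < 0 or self.stride_time_sd < 0:
            raise SpecError("stride length/time sds must be nonnegative")
        if not 0.0 < self.stance_fraction < 1.0:
            raise SpecError("stance_fraction must lie in (0, 1)")
        if self.fs <= 0:
            raise SpecError("fs must be positive")
        if self.clearance < 0:
            raise SpecError("clearance must be nonnegative")
        if self.lead_in <= 0 or self.lead_out <= 0:
            raise SpecError("lead_in and lead_out must be positive")


@dataclass
class ArtifactSpec:
    """Sensor artifact model.

    Applied in the order bias -> noise -> clip -> drop -> jitter
    (saturation acts on the analog sum of signal, bias and noise).
    Defaults model a decent consumer IMU; a zero/None spec is the
    identity.
    """

    accel_noise_sd: float = 0.02                 # m/s^2
    gyro_noise_sd: float = 0.2 * DEG2RAD         # rad/s
    accel_bias: tuple = (0.05, -0.03, 0.02)      # m/s^2
    gyro_bias: tuple = (0.002, -0.001, 0.0015)   # rad/s
    accel_scale: float = 1.0                     # miscalibration gain
    clip_accel_range: Optional[float] = None     # g units, None = no clipping
    packet_loss_fraction: float = 0.0
    jitter_sd: float = 0.0                       # s
    seed: int = 0

    @classmethod
    def none(cls) -> "ArtifactSpec":
        """An identity artifact spec (ideal sensor)."""
        return cls(
            accel_noise_sd=0.0,
            gyro_noise_sd=0.0,
            accel_bias=(0.0, 0.0, 0.0),
            gyro_bias=(0.0, 0.0, 0.0),
        )

    def validate(self) -> None:
        if self.accel_noise_sd < 0 or self.gyro_noise_sd < 0:
            raise SpecError("noise sds must be nonnegative")
        if self.clip_accel_range is not None and self.clip_accel_range <= 0:
            raise SpecError("clip_accel_range must be positive when set")
        if not 0.0 <= self.packet_loss_fraction < 1.0:
            raise SpecError("packet_loss_fraction must lie in [0, 1)")
        if self.jitter_sd < 0:
            raise SpecError("jitter_sd must be nonnegative")
        if self.accel_scale <= 0:
            raise SpecError("accel_scale must be positive")


@dataclass
class FootTrajectory:
    """Ground-truth rigid motion of the foot-mounted IMU."""

    t: np.ndarray                      # (n,) s
    position: np.ndarray               # (n, 3) m
    velocity: np.ndarray               # (n, 3) m/s
    attitude: np.ndarray               # (n, 3, 3) sensor->global rotation
    truth_strides: list                # list[ReferenceStride]
    truth_turn_strides: list           # indices into truth_strides
    truth_stance_intervals: list       # stationary (start_t, end_t); turns excluded
    fs: float
    foot: str = "right"
    final_ic_time: float = 0.0         # landing that closes the last stride


def _minjerk(u: np.ndarray) -> np.ndarray:
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


def _minjerk_d(u: np.ndarray) -> np.ndarray:
    return 30.0 * u**2 * (1.0 - u) ** 2


def _clearance_arc(u: np.ndarray) -> np.ndarray:
    # 64 u^3 (1-u)^3: peak 1 at u=1/2, value/slope/curvature all 0 at ends
    return 64.0 * u**3 * (1.0 - u) ** 3


def _clearance_arc_d(u: np.ndarray) -> np.ndarray:
    return 192.0 * u**2 * (1.0 - u) ** 2 * (1.0 - 2.0 * u)


def _pitch_angle(u: np.ndarray) -> np.ndarray:
    """Sagittal pitch over the swing, zero at both ends.

    The pitch rate (derivative) is -cos(2 pi u) + 0.2 cos(4 pi u): a
    dominant positive peak (1.2) at midswing and equal negative minima
    (-0.8) exactly at the swing boundaries, monotone in between -- the
    classic foot gyro signature with foot-off and initial-contact minima
    at the stance edges.
    """
    return -np.sin(2.0 * np.pi * u) / (2.0 * np.pi) + 0.2 * np.sin(4.0 * np.pi * u) / (4.0 * np.pi)


def _truncated_normal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws truncated at +/-3 sd and at zero."""
    if sd == 0.0:
        return np.full(size, mean)
    lo = max(mean - 3.0 * sd, 1e-9)
    hi = mean + 3.0 * sd
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _rot_zy(yaw: float, pitch: float) -> np.ndarray:
    """Yaw about global z composed with pitch about body y."""
    cy, sy = math.cos(yaw), math.sin(yaw)
    cp, sp = math.cos(pitch), math.sin(pitch)
    rz = np.array([[cy, -sy, 0.0], [sy, cy, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[cp, 0.0, sp], [0.0, 1.0, 0.0], [-sp, 0.0, cp]])
    return rz @ ry


def synth_walk_trajectory(spec: GaitSpec) -> FootTrajectory:
    """Generate a ground-truth walking trajectory from a :class:`GaitSpec`.

    The timeline is: lead-in rest, then per stride a stationary stance
    followed by a swing, then lead-out rest.  The initial contact of
    stride ``k`` is the instant its stance begins, so each truth stride
    has exactly the drawn stride time (stance + swing) and the drawn
    stride length (the swing displacement).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_strides
    lengths = _truncated_normal(rng, spec.stride_length_mean, spec.stride_length_sd, n)
    times = _truncated_normal(rng, spec.stride_time_mean, spec.stride_time_sd, n)

    turn_strides = []
    if spec.turn_every > 0:
        turn_strides = [k for k in range(1, n) if k % spec.turn_every == 0]

    # phase list: (kind, t_start, duration, params)
    phases = []
    t_cursor = 0.0
    pos = np.zeros(3)
    heading = 0.0
    phases.append(("rest", 0.0, spec.lead_in, {"pos": pos.copy(), "yaw": heading}))
    t_cursor = spec.lead_in

    ic_times = []
    stance_intervals = [(0.0, spec.lead_in)]
    for k in range(n):
        stance_dur = spec.stance_fraction * times[k]
        swing_dur = times[k] - stance_dur
        ic_times.append(t_cursor)
        if k in turn_strides:
            phases.append(
                ("turn", t_cursor, stance_dur,
                 {"pos": pos.copy(), "yaw0": heading, "dyaw": math.pi})
            )
            heading += math.pi
        else:
            phases.append(
                ("rest", t_cursor, stance_dur, {"pos": pos.copy(), "yaw": heading})
            )
            stance_intervals.append((t_cursor, t_cursor + stance_dur))
        t_cursor += stance_dur
        direction = np.array([math.cos(heading), math.sin(heading), 0.0])
        # peak pitch rate in u-units is 1.2 * gain / swing_dur
        pitch_gain = spec.midswing_peak_rate * swing_dur / 1.2
        phases.append(
            ("swing", t_cursor, swing_dur,
             {"pos": pos.copy(), "yaw": heading, "dir": direction,
              "length": lengths[k], "pitch_gain": pitch_gain})
        )
        pos = pos + direction * lengths[k]
        t_cursor += swing_dur
    final_ic = t_cursor
    phases.append(("rest", t_cursor, spec.lead_out, {"pos": pos.copy(), "yaw": heading}))
    stance_intervals.append((t_cursor, t_cursor + spec.lead_out))
    total = t_cursor + spec.lead_out

    dt = 1.0 / spec.fs
    n_samples = int(round(total * spec.fs)) + 1
    t = np.arange(n_samples) * dt

    position = np.zeros((n_samples, 3))
    velocity = np.zeros((n_samples, 3))
    attitude = np.zeros((n_samples, 3, 3))

    starts = np.array([p[1] for p in phases])
    phase_idx = np.searchsorted(starts, t, side="right") - 1
    phase_idx = np.clip(phase_idx, 0, len(phases) - 1)

    for j, (kind, t0, dur, prm) in enumerate(phases):
        sel = np.flatnonzero(phase_idx == j)
        if sel.size == 0:
            continue
        if kind == "rest":
            position[sel] = prm["pos"]
            R = _rot_zy(prm["yaw"], 0.0)
            attitude[sel] = R
        elif kind == "turn":
            u = (t[sel] - t0) / dur
            position[sel] = prm["pos"]
            yaws = prm["yaw0"] + prm["dyaw"] * _minjerk(u)
            for i, yaw in zip(sel, yaws):
                attitude[i] = _rot_zy(yaw, 0.0)
        else:  # swing
            u = (t[sel] - t0) / dur
            disp = _minjerk(u)[:, None] * prm["dir"] * prm["length"]
            disp[:, 2] += spec.clearance * _clearance_arc(u)
            position[sel] = prm["pos"] + disp
            vel = (_minjerk_d(u)[:, None] * prm["dir"] * prm["length"]) / dur
            vel[:, 2] += spec.clearance * _clearance_arc_d(u) / dur
            velocity[sel] = vel
            pitches = prm["pitch_gain"] * _pitch_angle(u)
            for i, pitch in zip(sel, pitches):
                attitude[i] = _rot_zy(prm["yaw"], pitch)

    foot = spec.foot
    truth = [
        ReferenceStride(
            foot=foot,
            ic_time=float(ic_times[k]),
            stride_length=float(lengths[k]),
            stride_time=float(times[k]),
        )
        for k in range(n)
    ]
    return FootTrajectory(
        t=t,
        position=position,
        velocity=velocity,
        attitude=attitude,
        truth_strides=truth,
        truth_turn_strides=turn_strides,
        truth_stance_intervals=stance_intervals,
        fs=spec.fs,
        foot=foot,
        final_ic_time=float(final_ic),
    )


def trajectory_to_imu(traj: FootTrajectory) -> ImuRecording:
    """Convert a ground-truth trajectory to ideal IMU signals.

    Inverts the forward Euler strapdown scheme: specific force is
    ``R_i^T (a_i - g)`` with ``a_i`` the discrete second difference of
    position, and angular rate is the rotation-vector logarithm of
    ``R_{i-1}^T R_i`` divided by the sample interval.  Integrating the
    output open-loop from the exact initial state therefore reproduces
    the trajectory to machine precision.
    """
    dt_all = np.diff(traj.t)
    if len(dt_all) == 0:
        raise SpecError("trajectory must have at least 2 samples")
    dt = dt_all[0]
    if not np.allclose(dt_all, dt, rtol=0.0, atol=1e-9):
        raise SpecError("trajectory must be uniformly sampled")

    n = len(traj.t)
    p = traj.position
    v_d = np.zeros((n, 3))
    v_d[1:] = (p[1:] - p[:-1]) / dt
    a_d = np.zeros((n, 3))
    a_d[1:] = (v_d[1:] - v_d[:-1]) / dt

    f = np.einsum("nji,nj->ni", traj.attitude, a_d - G_VEC)

    omega = np.zeros((n, 3))
    rel = np.einsum("nji,njk->nik", traj.attitude[:-1], traj.attitude[1:])
    omega[1:] = Rotation.from_matrix(rel).as_rotvec() / dt

    return ImuRecording(
        t=traj.t.copy(),
        f=f,
        omega=omega,
        fs_configured=traj.fs,
        accel_range=16.0,
        gyro_range=2000.0,
        timestamp_mode="relative",
        device_label="synthetic",
    )


def inject_artifacts(rec: ImuRecording, art: ArtifactSpec) -> ImuRecording:
    """Apply sensor artifacts to an ideal recording.

    Order: scale/bias, additive Gaussian noise, full-scale clipping,
    i.i.d. packet loss, Gaussian timestamp jitter (then re-sort).  A
    zero/None artifact spec returns an identical recording.
    """
    art.validate()
    rng = np.random.default_rng(art.seed)

    t = rec.t.copy()
    f = rec.f * art.accel_scale + np.asarray(art.accel_bias, dtype=float)
    omega = rec.omega + np.asarray(art.gyro_bias, dtype=float)

    if art.accel_noise_sd > 0:
        f = f + rng.normal(0.0, art.accel_noise_sd, size=f.shape)
    if art.gyro_noise_sd > 0:
        omega = omega + rng.normal(0.0, art.gyro_noise_sd, size=omega.shape)

    accel_range = rec.accel_range
    if art.clip_accel_range is not None:
        limit = art.clip_accel_range * GRAVITY
        f = np.clip(f, -limit, limit)
        accel_range = art.clip_accel_range

    if art.packet_loss_fraction > 0:
        keep = rng.random(len(t)) >= art.packet_loss_fraction
        t, f, omega = t[keep], f[keep], omega[keep]

    if art.jitter_sd > 0 and len(t):
        t = t + rng.normal(0.0, art.jitter_sd, size=len(t))
        order = np.argsort(t, kind="stable")
        t, f, omega = t[order], f[order], omega[order]

    return ImuRecording(
        t=t,
        f=f,
        omega=omega,
        fs_configured=rec.fs_configured,
        accel_range=accel_range,
        gyro_range=rec.gyro_range,
        timestamp_mode=rec.timestamp_mode,
        time_offset=rec.time_offset,
        device_label=rec.device_label,
    )


def synth_stationary(duration: float, fs: float, art: ArtifactSpec = None) -> ImuRecording:
    """Ideal rest signal (f = (0, 0, g), omega = 0) with artifacts injected."""
    if duration <= 0:
        raise SpecError("duration must be positive")
    if fs <= 0:
        raise SpecError("fs must be positive")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    f = np.tile([0.0, 0.0, GRAVITY], (n, 1))
    omega = np.zeros((n, 3))
    rec = ImuRecording(
        t=t, f=f, omega=omega, fs_configured=fs,
        accel_range=16.0, gyro_range=2000.0,
        timestamp_mode="relative", device_label="synthetic-rest",
    )
    if art is None:
        return rec
    return inject_artifacts(rec, art)
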