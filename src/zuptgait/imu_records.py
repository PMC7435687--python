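"""Data model and I/O for unified IMU recordings and reference stride tables.

A recording holds time-stamped 6-axis samples (3-axis specific force in
m/s^2 and 3-axis angular rate in rad/s) plus sensor metadata.  The on-disk
format is a plain CSV with header ``t,ax,ay,az,gx,gy,gz`` (an optional
``unix_t`` column carries epoch timestamps).  All internal times are
seconds relative to recording start; epoch offsets are kept as metadata.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from zuptgait.errors import (
    ConfigurationError,
    FormatError,
    InsufficientDataError,
    ParseError,
)

logger = logging.getLogger(__name__)

#: Standard gravity, m/s^2.
GRAVITY = 9.80665

#: Degrees-to-radians factor.
DEG2RAD = math.pi / 180.0

_CHANNELS = ["ax", "ay", "az", "gx", "gy", "gz"]

_ACCEL_FACTORS = {"m/s^2": 1.0, "m/s²": 1.0, "g": GRAVITY}
_GYRO_FACTORS = {"rad/s": 1.0, "deg/s": DEG2RAD}


class ImuSample(NamedTuple):
    """One time-stamped 6-axis sample (SI units)."""

    t: float
    f: np.ndarray       # (3,) specific force, m/s^2
    omega: np.ndarray   # (3,) angular rate, rad/s


@dataclass
class ImuRecording:
    """A unified IMU recording.

    Attributes
    ----------
    t : (n,) float array, seconds since recording start, strictly increasing.
    f : (n, 3) float array, specific force in m/s^2 (sensor frame, x/y/z).
    omega : (n, 3) float array, angular rate in rad/s (sensor frame).
    fs_configured : configured sampling rate, Hz.
    accel_range : accelerometer full-scale range in g units.
    gyro_range : gyroscope full-scale range in deg/s.
    timestamp_mode : one of ``unix``, ``relative``, ``absent``.
    time_offset : epoch offset of t=0 when ``timestamp_mode == 'unix'``.
    device_label : free-text device identifier.
    """

    t: np.ndarray
    f: np.ndarray
    omega: np.ndarray
    fs_configured: float
    accel_range: float = 8.0
    gyro_range: float = 2000.0
    timestamp_mode: str = "relative"
    time_offset: float = 0.0
    device_label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float).reshape(-1, 3)
        self.omega = np.asarray(self.omega, dtype=float).reshape(-1, 3)
        if not (len(self.t) == len(self.f) == len(self.omega)):
            raise ValueError("t, f and omega must have equal length")
        if self.fs_configured <= 0:
            raise ConfigurationError("fs_configured must be positive")
        if self.accel_range <= 0 or self.gyro_range <= 0:
            raise ConfigurationError("sensor ranges must be positive")
        if self.timestamp_mode not in ("unix", "relative", "absent"):
            raise ConfigurationError(
                f"unknown timestamp_mode {self.timestamp_mode!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def nominal_dt(self) -> float:
        """Nominal sampling interval 1/fs_configured, seconds."""
        return 1.0 / self.fs_configured

    @property
    def duration(self) -> float:
        if self.n_samples < 2:
            return 0.0
        return float(self.t[-1] - self.t[0])

    def sample(self, i: int) -> ImuSample:
        return ImuSample(float(self.t[i]), self.f[i], self.omega[i])


@dataclass
class ReferenceStride:
    """One reference (gold-standard) stride."""

    foot: str
    ic_time: float
    stride_length: float
    stride_time: float

    def __post_init__(self) -> None:
        if self.foot not in ("left", "right"):
            raise ValueError(f"foot must be 'left' or 'right', got {self.foot!r}")
        if self.stride_length <= 0:
            raise ValueError("stride_length must be positive")
        if self.stride_time <= 0:
            raise ValueError("stride_time must be positive")


@dataclass
class GapReport:
    """Sampling gaps and overall retention of a recording."""

    gap_intervals: list[tuple[float, float]] = field(default_factory=list)
    retained_fraction: float = 1.0

    @property
    def n_gaps(self) -> int:
        return len(self.gap_intervals)


def read_unified_csv(
    path,
    fs_configured: float,
    accel_range: float = 8.0,
    gyro_range: float = 2000.0,
    accel_unit: str = "m/s^2",
    gyro_unit: str = "rad/s",
    device_label: str = "",
) -> ImuRecording:
    """Read a unified IMU CSV into an :class:`ImuRecording`.

    The file must have the six channel columns ``ax,ay,az,gx,gy,gz``; a
    ``t`` column (relative or epoch seconds) and/or ``unix_t`` column are
    optional.  Without any time column, timestamps are reconstructed as
    ``i / fs_configured``.  Values are normalized to m/s^2 and rad/s
    according to ``accel_unit`` / ``gyro_unit``.

    Samples are sorted by time; duplicate timestamps are collapsed to the
    first occurrence with a logged warning.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc

    missing = [c for c in _CHANNELS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")

    cols = list(_CHANNELS)
    has_t = "t" in df.columns
    has_unix = "unix_t" in df.columns
    if has_t:
        cols = ["t"] + cols
    if has_unix:
        cols = ["unix_t"] + cols

    for col in cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} at data row {row}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ParseError(f"{path}: missing value in column {col!r} at data row {row}")
        df[col] = numeric

    n = len(df)
    time_offset = 0.0
    if has_t:
        # prefer the relative column: rebasing epoch floats loses precision
        raw_t = df["t"].to_numpy(dtype=float)
        if has_unix:
            timestamp_mode = "unix"
            time_offset = float(df["unix_t"].iloc[0]) if n else 0.0
        elif n and raw_t[0] > 1e8:
            # epoch seconds are far beyond any plausible session length
            timestamp_mode = "unix"
        else:
            timestamp_mode = "relative"
    elif has_unix:
        raw_t = df["unix_t"].to_numpy(dtype=float)
        timestamp_mode = "unix"
    else:
        raw_t = np.arange(n, dtype=float) / fs_configured
        timestamp_mode = "absent"

    order = np.argsort(raw_t, kind="stable")
    raw_t = raw_t[order]
    data = df[_CHANNELS].to_numpy(dtype=float)[order]

    if n:
        keep = np.concatenate(([True], np.diff(raw_t) > 0))
        n_dup = int((~keep).sum())
        if n_dup:
            logger.warning(
                "%s: collapsed %d duplicate timestamps (kept first occurrence)",
                path, n_dup,
            )
            raw_t = raw_t[keep]
            data = data[keep]

    if timestamp_mode == "unix" and len(raw_t) and raw_t[0] > 1e8:
        time_offset = float(raw_t[0])
        raw_t = raw_t - time_offset

    rec = ImuRecording(
        t=raw_t,
        f=data[:, :3],
        omega=data[:, 3:],
        fs_configured=fs_configured,
        accel_range=accel_range,
        gyro_range=gyro_range,
        timestamp_mode=timestamp_mode,
        time_offset=time_offset,
        device_label=device_label,
    )
    return normalize_units(rec, accel_unit=accel_unit, gyro_unit=gyro_unit)


def normalize_units(
    rec: ImuRecording, accel_unit: str = "m/s^2", gyro_unit: str = "rad/s"
) -> ImuRecording:
    """Convert a recording to SI units (m/s^2, rad/s).

    ``accel_unit`` / ``gyro_unit`` state the units the recording currently
    carries.  Idempotent once units are SI.
    """
    if accel_unit not in _ACCEL_FACTORS:
        raise ConfigurationError(f"unknown acceleration unit {accel_unit!r}")
    if gyro_unit not in _GYRO_FACTORS:
        raise ConfigurationError(f"unknown angular-rate unit {gyro_unit!r}")
    fa = _ACCEL_FACTORS[accel_unit]
    fg = _GYRO_FACTORS[gyro_unit]
    if fa == 1.0 and fg == 1.0:
        return rec
    return replace(rec, f=rec.f * fa, omega=rec.omega * fg)


def detect_gaps(rec: ImuRecording, factor: float = 1.5) -> GapReport:
    """Detect sampling gaps and compute the retained-sample fraction.

    An interval ``(t[i-1], t[i])`` is a gap iff it exceeds
    ``factor * nominal_dt``.  ``retained_fraction`` is the number of
    samples divided by the number expected over the recorded duration at
    the configured rate, clamped to [0, 1].
    """
    if rec.n_samples < 2:
        raise InsufficientDataError("detect_gaps requires at least 2 samples")
    dt = np.diff(rec.t)
    threshold = factor * rec.nominal_dt
    idx = np.flatnonzero(dt > threshold)
    intervals = [(float(rec.t[i]), float(rec.t[i + 1])) for i in idx]
    expected = round(rec.duration * rec.fs_configured + 1)
    retained = rec.n_samples / expected if expected > 0 else 1.0
    return GapReport(
        gap_intervals=intervals,
        retained_fraction=float(min(1.0, max(0.0, retained))),
    )


def write_unified_csv(rec: ImuRecording, path) -> None:
    """Write a recording to unified CSV.

    Values are printed with 17 significant digits so that a read back
    through :func:`read_unified_csv` reproduces them bit-for-bit.  No
    resampling is performed: gaps survive a round trip.
    """
    header = ["t"] + _CHANNELS
    columns = [rec.t, *rec.f.T, *rec.omega.T]
    if rec.timestamp_mode == "unix":
        header = ["unix_t"] + header
        columns = [rec.t + rec.time_offset] + columns
    data = np.column_stack(columns) if rec.n_samples else np.empty((0, len(header)))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(header) + "\n")
        for row in data:
            fh.write(",".join(format(v, ".17g") for v in row) + "\n")


def read_reference_strides(path) -> list[ReferenceStride]:
    """Read a reference stride table (``foot,ic_time,stride_length,stride_time``)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    required = ["foot", "ic_time", "stride_length", "stride_time"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    strides = []
    for i, row in df.iterrows():
        try:
            strides.append(
                ReferenceStride(
                    foot=str(row["foot"]),
                    ic_time=float(row["ic_time"]),
                    stride_length=float(row["stride_length"]),
                    stride_time=float(row["stride_time"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: bad reference stride at data row {i}: {exc}") from exc
    return strides


def write_reference_strides(strides: Sequence[ReferenceStride], path) -> None:
    """Write a reference stride table CSV."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("foot,ic_time,stride_length,stride_time\n")
        for s in strides:
            fh.write(
                f"{s.foot},{s.ic_time:.17g},{s.stride_length:.17g},{s.stride_time:.17g}\n"
            )
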