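"""Raw-data quality checks: empirical sampling rates, stationary
baselines, and accelerometer saturation detection."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from zuptgait.errors import (
    ConfigurationError,
    InsufficientDataError,
    NotApplicableError,
)
from zuptgait.imu_records import GRAVITY, ImuRecording


@dataclass
class SamplingRateReport:
    """Per-interval empirical sampling rates and their histogram."""

    fs_values: np.ndarray              # Hz, one per positive adjacent interval
    fs_configured: float
    histogram: tuple                   # (bin_edges, counts)
    n_nonpositive_intervals: int = 0   # duplicated / out-of-order timestamps


@dataclass
class BaselineReport:
    """Stationary baseline statistics (SI units)."""

    n_used: int
    accel_mean: np.ndarray             # per axis, m/s^2
    accel_quartiles: np.ndarray        # (3, 3): q25/q50/q75 per axis
    gyro_mean: np.ndarray              # per axis, rad/s
    gyro_quartiles: np.ndarray
    accel_magnitude_mean: float
    gyro_magnitude_mean: float


@dataclass
class ClippingReport:
    """Fraction of samples at the accelerometer full-scale rail, per axis."""

    clipped_fraction_per_axis: np.ndarray
    limit_used: float                  # m/s^2
    tol: float = 0.999


def empirical_sampling_rates(rec: ImuRecording, bin_width: float = 1.0) -> SamplingRateReport:
    """Empirical rate 1/(t_i - t_{i-1}) for every adjacent timestamp pair.

    Non-positive intervals (duplicated or reordered timestamps, as seen in
    streamed data) are counted separately and excluded from the histogram.
    The histogram uses ``bin_width``-Hz bins centered on multiples of the
    width, spanning the observed values.
    """
    if rec.timestamp_mode == "absent":
        raise NotApplicableError(
            "recording has no native timestamps; sampling rates are not measurable"
        )
    if rec.n_samples < 2:
        raise InsufficientDataError("need at least 2 samples")
    dt = np.diff(rec.t)
    positive = dt > 0
    n_bad = int((~positive).sum())
    fs_values = 1.0 / dt[positive]
    if fs_values.size:
        lo = np.floor(fs_values.min() / bin_width) * bin_width - bin_width / 2.0
        hi = np.ceil(fs_values.max() / bin_width) * bin_width + bin_width / 2.0
        n_bins = max(1, int(round((hi - lo) / bin_width)))
        edges = lo + np.arange(n_bins + 1) * bin_width
        counts, edges = np.histogram(fs_values, bins=edges)
    else:
        edges, counts = np.array([0.0, bin_width]), np.array([0])
    return SamplingRateReport(
        fs_values=fs_values,
        fs_configured=rec.fs_configured,
        histogram=(edges, counts),
        n_nonpositive_intervals=n_bad,
    )


def baseline_summary(
    rec: ImuRecording, n: int = 5000, allow_fewer: bool = False
) -> BaselineReport:
    """Stationary baseline statistics over the first ``n`` samples.

    Magnitudes are Euclidean norms.  With fewer than ``n`` samples the
    call fails unless ``allow_fewer`` is set, in which case all samples
    are used.
    """
    if rec.n_samples < n:
        if not allow_fewer:
            raise InsufficientDataError(
                f"recording has {rec.n_samples} samples, need {n} "
                "(pass allow_fewer=True to use all)"
            )
        n = rec.n_samples
    f = rec.f[:n]
    w = rec.omega[:n]
    q = [25, 50, 75]
    return BaselineReport(
        n_used=n,
        accel_mean=f.mean(axis=0),
        accel_quartiles=np.percentile(f, q, axis=0),
        gyro_mean=w.mean(axis=0),
        gyro_quartiles=np.percentile(w, q, axis=0),
        accel_magnitude_mean=float(np.linalg.norm(f, axis=1).mean()),
        gyro_magnitude_mean=float(np.linalg.norm(w, axis=1).mean()),
    )


def detect_clipping(rec: ImuRecording, tol: float = 0.999) -> ClippingReport:
    """Flag samples whose acceleration sits at the full-scale rail.

    An axis of a sample is clipped iff its magnitude is at least
    ``tol`` times the configured range.  Lowering ``tol`` never
    decreases the reported fractions.
    """
    if rec.accel_range is None or rec.accel_range <= 0:
        raise ConfigurationError("accel_range metadata required for clipping detection")
    limit = rec.accel_range * GRAVITY
    if rec.n_samples == 0:
        return ClippingReport(np.zeros(3), limit, tol)
    clipped = np.abs(rec.f) >= tol * limit
    return ClippingReport(
        clipped_fraction_per_axis=clipped.mean(axis=0),
        limit_used=limit,
        tol=tol,
    )
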