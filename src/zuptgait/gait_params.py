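"""Gait event detection and spatio-temporal stride parameters.

Events are detected on the raw angular velocity: the sagittal channel is
taken as the gyro axis of maximal variance (mounting orientations differ
between devices), its sign is disambiguated so midswing peaks are
positive, midswing is found by peak detection, and initial contact /
foot off are the prominent local minima bracketing each midswing peak.
Spatial parameters come from the estimated trajectory between
consecutive initial contacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from zuptgait.errors import NoGaitError, ZuptGaitError
from zuptgait.imu_records import ImuRecording

#: Degrees per radian, for heading thresholds.
_RAD2DEG = 180.0 / np.pi


@dataclass
class GaitEvents:
    """Detected gait event times, seconds."""

    ic_times: np.ndarray
    fo_times: np.ndarray
    midswing_times: np.ndarray
    channel: int = 0          # gyro axis used
    sign: float = 1.0         # polarity applied to that axis


@dataclass
class Stride:
    """One gait cycle between consecutive initial contacts of a foot."""

    ic_time: float
    next_ic_time: float
    fo_time: float
    stride_length: float
    stride_time: float
    stance_time: float
    swing_time: float
    clearance: float
    speed: float
    is_turn: bool = False
    foot: str = "right"


def detect_gait_events(
    rec: ImuRecording,
    mask=None,
    prominence: float = 1.5,
    min_stride_time: float = 0.4,
    minima_prominence: float = 0.5,
) -> GaitEvents:
    """Peak-detection gait events from raw angular velocity.

    Midswing peaks are positive peaks above ``prominence`` (rad/s)
    separated by at least ``min_stride_time``.  Initial contact is the
    first prominent local minimum after each midswing peak, foot off the
    last prominent local minimum before it.  ``mask`` is accepted for
    interface symmetry with the filter but is not needed by the detector.
    """
    if rec.n_samples < 3:
        raise NoGaitError("recording too short for event detection")
    # dispersion by mean absolute deviation: robust against the rare,
    # violent yaw bursts of in-place turns, which can out-vote the
    # periodic sagittal swing signal in a plain variance comparison
    dispersion = np.mean(
        np.abs(rec.omega - np.median(rec.omega, axis=0)), axis=0
    )
    channel = int(np.argmax(dispersion))
    w = rec.omega[:, channel].astype(float)
    # polarity: midswing peaks must be positive
    sign = 1.0
    if np.abs(w.min()) > np.abs(w.max()):
        sign = -1.0
        w = -w

    distance = max(1, int(round(min_stride_time * rec.fs_configured)))
    # height filters reject the flat stance plateaus, whose prominence
    # relative to the adjacent negative lobes would otherwise qualify
    peaks, _ = find_peaks(w, height=prominence, prominence=prominence, distance=distance)
    if peaks.size == 0:
        raise NoGaitError("no midswing peaks found")
    minima, _ = find_peaks(-w, height=minima_prominence, prominence=minima_prominence)

    ic_idx, fo_idx, ms_idx = [], [], []
    for p in peaks:
        after = minima[minima > p]
        before = minima[minima < p]
        if after.size == 0 or before.size == 0:
            continue  # end effects: swing truncated by the recording edge
        ic_idx.append(int(after[0]))
        fo_idx.append(int(before[-1]))
        ms_idx.append(int(p))
    if not ic_idx:
        raise NoGaitError("no complete gait cycles found")

    t = rec.t
    return GaitEvents(
        ic_times=t[np.array(ic_idx)],
        fo_times=t[np.array(fo_idx)],
        midswing_times=t[np.array(ms_idx)],
        channel=channel,
        sign=sign,
    )


def segment_strides(
    events: GaitEvents, traj, t: np.ndarray | None = None, foot: str = "right"
) -> list[Stride]:
    """Build one stride per consecutive initial-contact pair.

    ``traj`` is the estimated state history (anything exposing ``s`` as
    an (n, 3) array, e.g. :class:`~zuptgait.zupt_eskf.NavTrajectory`);
    ``t`` defaults to ``traj.t``.  Stride length is the horizontal
    displacement between the two contacts; clearance is the maximum
    elevation above the stride's own stance ground level.
    """
    if t is None:
        t = traj.t
    s = np.asarray(traj.s, dtype=float)
    if len(s) != len(t):
        raise ZuptGaitError("trajectory and time arrays differ in length")
    ics = np.asarray(events.ic_times, dtype=float)
    if ics.size < 2:
        raise NoGaitError("need at least 2 initial contacts to form a stride")

    strides: list[Stride] = []
    for ic, next_ic in zip(ics[:-1], ics[1:]):
        j0 = int(np.searchsorted(t, ic))
        j1 = int(np.searchsorted(t, next_ic))
        j0 = min(j0, len(t) - 1)
        j1 = min(j1, len(t) - 1)
        # foot off inside this cycle
        fo_candidates = events.fo_times[
            (events.fo_times > ic) & (events.fo_times < next_ic)
        ]
        fo = float(fo_candidates[0]) if fo_candidates.size else float("nan")
        stride_time = float(next_ic - ic)
        stance_time = fo - ic if np.isfinite(fo) else float("nan")
        swing_time = next_ic - fo if np.isfinite(fo) else float("nan")
        disp = s[j1] - s[j0]
        length = float(np.hypot(disp[0], disp[1]))
        ground = s[j0, 2]
        clearance = float(np.max(s[j0:j1 + 1, 2]) - ground)
        strides.append(
            Stride(
                ic_time=float(ic),
                next_ic_time=float(next_ic),
                fo_time=fo,
                stride_length=length,
                stride_time=stride_time,
                stance_time=float(stance_time),
                swing_time=float(swing_time),
                clearance=clearance,
                speed=length / stride_time,
                foot=foot,
            )
        )
    return strides


def _yaw_of(R: np.ndarray) -> float:
    return float(np.arctan2(R[1, 0], R[0, 0]))


def exclude_turns(
    strides: list[Stride],
    traj,
    heading_threshold: float = 20.0,
    drop_adjacent: bool = False,
) -> list[Stride]:
    """Flag turning strides and return the non-turning ones.

    A stride is a turn iff the absolute heading (yaw) change of the
    estimated attitude between its two initial contacts is at least
    ``heading_threshold`` degrees.  ``drop_adjacent`` also removes the
    strides immediately before and after each turn (walkway end effects).
    The ``is_turn`` flag is set in place on every input stride.
    """
    t = traj.t
    R = traj.R
    for st in strides:
        j0 = min(int(np.searchsorted(t, st.ic_time)), len(t) - 1)
        j1 = min(int(np.searchsorted(t, st.next_ic_time)), len(t) - 1)
        dpsi = _yaw_of(R[j1]) - _yaw_of(R[j0])
        dpsi = (dpsi + np.pi) % (2.0 * np.pi) - np.pi  # wrap to (-pi, pi]
        st.is_turn = bool(abs(dpsi) * _RAD2DEG >= heading_threshold)

    turn_pos = {i for i, st in enumerate(strides) if st.is_turn}
    if drop_adjacent:
        adjacent = set()
        for i in turn_pos:
            adjacent.update({i - 1, i + 1})
        turn_pos |= {i for i in adjacent if 0 <= i < len(strides)}
    return [st for i, st in enumerate(strides) if i not in turn_pos]


def cadence(strides: list[Stride]) -> float:
    """Steps per minute: two steps per stride, from the mean stride time."""
    if not strides:
        raise ZuptGaitError("cadence of an empty stride list is undefined")
    mean_time = float(np.mean([s.stride_time for s in strides]))
    return 2.0 * 60.0 / mean_time


_STRIDE_COLUMNS = [
    "foot", "ic_time", "fo_time", "stride_length", "stride_time",
    "stance_time", "swing_time", "clearance", "speed", "is_turn",
]


def write_strides(strides: list[Stride], path) -> None:
    """Write a stride table CSV."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(_STRIDE_COLUMNS) + "\n")
        for s in strides:
            fh.write(
                f"{s.foot},{s.ic_time:.17g},{s.fo_time:.17g},"
                f"{s.stride_length:.17g},{s.stride_time:.17g},"
                f"{s.stance_time:.17g},{s.swing_time:.17g},"
                f"{s.clearance:.17g},{s.speed:.17g},{int(s.is_turn)}\n"
            )


def read_strides(path) -> list[Stride]:
    """Read a stride table CSV written by :func:`write_strides`."""
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    strides = []
    for _, row in df.iterrows():
        strides.append(
            Stride(
                ic_time=float(row["ic_time"]),
                next_ic_time=float(row["ic_time"]) + float(row["stride_time"]),
                fo_time=float(row["fo_time"]),
                stride_length=float(row["stride_length"]),
                stride_time=float(row["stride_time"]),
                stance_time=float(row["stance_time"]),
                swing_time=float(row["swing_time"]),
                clearance=float(row["clearance"]),
                speed=float(row["speed"]),
                is_turn=bool(int(row["is_turn"])),
                foot=str(row["foot"]),
            )
        )
    return strides
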