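"""End-to-end simulation experiments shared by tests and reporting.

Each helper generates a ground-truth walk, pushes it through the full
estimation pipeline, and pairs the measured strides with the generator's
truth table.  The walkway-entry stride (whose initial contact is the end
of the lead-in rest, not a detectable swing landing) is dropped from the
reference side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from zuptgait.agreement_eval import (
    MatchedStridePairs,
    match_strides,
    synchronize_by_first_stride,
)
from zuptgait.gait_params import detect_gait_events, exclude_turns, segment_strides
from zuptgait.synthetic_gait import (
    ArtifactSpec,
    GaitSpec,
    inject_artifacts,
    synth_walk_trajectory,
    trajectory_to_imu,
)
from zuptgait.zupt_eskf import EskfConfig, run_eskf


@dataclass
class WalkResult:
    """Everything produced by one simulated walk + analysis."""

    traj: object
    rec: object
    est: object
    mask: object
    diagnostics: dict
    strides: list
    kept: list                    # after turn exclusion
    length_pairs: MatchedStridePairs
    time_pairs: MatchedStridePairs


def analyze_walk(
    spec: GaitSpec,
    art: ArtifactSpec | None = None,
    config: EskfConfig | None = None,
    match_tol: float = 0.25,
) -> WalkResult:
    """Simulate a walk, run the full pipeline, pair strides with truth."""
    traj = synth_walk_trajectory(spec)
    rec = trajectory_to_imu(traj)
    if art is not None:
        rec = inject_artifacts(rec, art)
    est, mask, diagnostics = run_eskf(rec, config)
    events = detect_gait_events(rec, mask)
    strides = segment_strides(events, est, foot=spec.foot)
    kept = exclude_turns(strides, est)
    reference = traj.truth_strides[1:]
    offset = synchronize_by_first_stride(kept, reference)
    length_pairs = match_strides(
        kept, reference, offset=offset, tol=match_tol, metric="stride_length"
    )
    time_pairs = match_strides(
        kept, reference, offset=offset, tol=match_tol, metric="stride_time"
    )
    return WalkResult(
        traj=traj, rec=rec, est=est, mask=mask, diagnostics=diagnostics,
        strides=strides, kept=kept,
        length_pairs=length_pairs, time_pairs=time_pairs,
    )


def combine_pairs(*pair_sets: MatchedStridePairs) -> MatchedStridePairs:
    """Concatenate matched-pair sets (e.g. left and right feet)."""
    return MatchedStridePairs(
        measured=np.concatenate([p.measured for p in pair_sets]),
        reference=np.concatenate([p.reference for p in pair_sets]),
        ic_times=np.concatenate([p.ic_times for p in pair_sets]),
        feet=np.concatenate([p.feet for p in pair_sets]),
        metric=pair_sets[0].metric,
        n_unmatched_measured=sum(p.n_unmatched_measured for p in pair_sets),
        n_unmatched_reference=sum(p.n_unmatched_reference for p in pair_sets),
    )


def rmse(pairs: MatchedStridePairs) -> float:
    return float(np.sqrt(np.mean(pairs.differences ** 2)))
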