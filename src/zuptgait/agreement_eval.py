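"""Agreement evaluation against reference strides.

Synchronizes measured and reference stride series on the first initial
contact, matches strides one-to-one by initial-contact time, and computes
the comparison statistics: Pearson correlation with ordinary least
squares regression (measured on reference), RMSE about the identity
line, Bland-Altman bias and limits of agreement (1.96 sd of the
differences, n-1 denominator), and a two-cluster K-Means / silhouette
screen of the differences for left-right inconsistencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from zuptgait.errors import DegenerateClusterError, ZuptGaitError


@dataclass
class MatchedStridePairs:
    """One-to-one matched (measured, reference) stride values."""

    measured: np.ndarray          # metric values
    reference: np.ndarray
    ic_times: np.ndarray          # reference-side initial contact times
    feet: np.ndarray              # foot label per pair
    metric: str = "stride_length"
    n_unmatched_measured: int = 0
    n_unmatched_reference: int = 0

    @property
    def n(self) -> int:
        return len(self.measured)

    @property
    def differences(self) -> np.ndarray:
        return self.measured - self.reference


@dataclass
class AgreementReport:
    """Regression and Bland-Altman summary of matched pairs."""

    n: int
    r: float = float("nan")
    slope: float = float("nan")
    intercept: float = float("nan")
    rmse: float = float("nan")
    bias: float = float("nan")
    loa_half_width: float = float("nan")
    sd_diff: float = float("nan")
    means: np.ndarray | None = None       # (measured+reference)/2, plot-ready
    differences: np.ndarray | None = None


@dataclass
class ClusterReport:
    """K-Means screen of stride differences (left/right consistency)."""

    labels: np.ndarray
    mean_sc: float
    per_cluster_mean: dict
    centers: np.ndarray
    foot_crosstab: dict = field(default_factory=dict)


def synchronize_by_first_stride(measured, reference) -> float:
    """Time offset aligning measured onto reference series.

    Uses the initial contact of the very first reference stride and the
    first measured stride of the same foot.  Adding the returned offset
    to measured initial-contact times brings them onto the reference
    clock.
    """
    if not measured or not reference:
        raise ZuptGaitError("synchronization requires non-empty stride lists")
    ref0 = reference[0]
    for st in measured:
        if st.foot == ref0.foot:
            return float(ref0.ic_time - st.ic_time)
    raise ZuptGaitError(
        f"no measured stride with foot {ref0.foot!r} to synchronize on"
    )


def _metric_value(stride, metric: str) -> float:
    return float(getattr(stride, metric))


def match_strides(
    measured,
    reference,
    offset: float = 0.0,
    tol: float = 0.25,
    metric: str = "stride_length",
) -> MatchedStridePairs:
    """Greedy nearest-neighbour matching on initial-contact timestamps.

    Measured times are shifted by ``offset`` first.  Pairs are accepted
    closest-first, each stride used at most once, and only when the
    contact times differ by at most ``tol`` seconds.
    """
    m_ic = np.array([s.ic_time for s in measured], dtype=float) + offset
    r_ic = np.array([s.ic_time for s in reference], dtype=float)

    candidates = []
    for i, tm in enumerate(m_ic):
        for j, tr in enumerate(r_ic):
            d = abs(tm - tr)
            if d <= tol:
                candidates.append((d, i, j))
    candidates.sort()
    used_m, used_r = set(), set()
    pairs = []
    for d, i, j in candidates:
        if i in used_m or j in used_r:
            continue
        used_m.add(i)
        used_r.add(j)
        pairs.append((i, j))
    pairs.sort(key=lambda ij: r_ic[ij[1]])

    measured_vals = np.array([_metric_value(measured[i], metric) for i, _ in pairs])
    reference_vals = np.array([_metric_value(reference[j], metric) for _, j in pairs])
    ic_times = np.array([r_ic[j] for _, j in pairs])
    feet = np.array([reference[j].foot for _, j in pairs])
    return MatchedStridePairs(
        measured=measured_vals,
        reference=reference_vals,
        ic_times=ic_times,
        feet=feet,
        metric=metric,
        n_unmatched_measured=len(measured) - len(pairs),
        n_unmatched_reference=len(reference) - len(pairs),
    )


def correlation_analysis(pairs: MatchedStridePairs) -> AgreementReport:
    """Pearson correlation, OLS regression of measured on reference, RMSE.

    RMSE is computed about the identity line (measured vs gold), not the
    regression line.
    """
    m, r_vals = pairs.measured, pairs.reference
    if pairs.n < 3:
        raise ZuptGaitError("correlation analysis requires at least 3 pairs")
    if np.ptp(r_vals) == 0:
        raise ZuptGaitError("reference values have zero variance; r undefined")
    lr = stats.linregress(r_vals, m)
    rmse = float(np.sqrt(np.mean((m - r_vals) ** 2)))
    return AgreementReport(
        n=pairs.n,
        r=float(lr.rvalue),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        rmse=rmse,
    )


def bland_altman(pairs: MatchedStridePairs) -> AgreementReport:
    """Bland-Altman bias and limits of agreement (1.96 sd, n-1 denominator)."""
    if pairs.n < 2:
        raise ZuptGaitError("Bland-Altman requires at least 2 pairs")
    d = pairs.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementReport(
        n=pairs.n,
        bias=bias,
        sd_diff=sd,
        loa_half_width=1.96 * sd,
        means=(pairs.measured + pairs.reference) / 2.0,
        differences=d,
    )


def cluster_differences(
    pairs: MatchedStridePairs, k: int = 2, seed: int = 0
) -> ClusterReport:
    """K-Means (k clusters, fixed seed) on the 1-D stride differences.

    Reports the mean silhouette coefficient and cross-tabulates cluster
    labels against foot labels, screening for systematic left-right
    disagreement.  Degenerate input (all differences identical) raises.
    """
    d = pairs.differences
    if pairs.n < k:
        raise ZuptGaitError(f"need at least k={k} pairs to cluster")
    if np.ptp(d) == 0:
        raise DegenerateClusterError("all differences identical; clustering undefined")
    X = d.reshape(-1, 1)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    if pairs.n > k and len(np.unique(labels)) > 1:
        mean_sc = float(silhouette_score(X, labels, metric="euclidean"))
    else:
        mean_sc = 0.0  # singleton clusters: silhouette conventionally 0
    per_cluster = {
        int(c): float(d[labels == c].mean()) for c in np.unique(labels)
    }
    crosstab: dict = {}
    for lab, foot in zip(labels, pairs.feet):
        crosstab[(int(lab), str(foot))] = crosstab.get((int(lab), str(foot)), 0) + 1
    return ClusterReport(
        labels=labels,
        mean_sc=mean_sc,
        per_cluster_mean=per_cluster,
        centers=km.cluster_centers_.ravel(),
        foot_crosstab=crosstab,
    )
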