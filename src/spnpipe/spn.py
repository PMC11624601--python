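"""Post-cluster SPN analysis.

After TFCE has located a significant cluster, the analysis (i) keeps the
"most significant" sources — those whose p-value averaged over the
cluster's temporal extent lies strictly below the cluster-wide mean, never
leaving the STG+ auditory region; (ii) contrasts timecourses pointwise with
Benjamini-Hochberg control across time samples; (iii) averages the mean
onset and end of per-source significant runs into a group-difference
window; and (iv) computes SPNadj — the response magnitude to the test
stimulus with the control-stimulus magnitude and the square root of the
averaged-epoch count regressed out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .behavior import bh_fdr
from .cohort import SourceSpace
from .tfce import TfceResult

logger = logging.getLogger(__name__)

__all__ = [
    "select_most_significant_sources",
    "pointwise_contrast",
    "significant_runs",
    "group_difference_window",
    "compute_spn_adj",
    "SpnMeasures",
]


@dataclass
class SpnMeasures:
    """Per-subject SPN magnitudes over selected sources and window."""

    test_mag: np.ndarray      # mean current, test condition
    ctrl_mag: np.ndarray      # mean current, control condition
    spn_adj: np.ndarray
    window_ms: tuple[float, float]
    sources: np.ndarray


def select_most_significant_sources(
    result: TfceResult,
    space: SourceSpace,
    region_mask: np.ndarray | None = None,
    cluster_id: int | None = None,
) -> np.ndarray:
    """Sources of a cluster whose time-averaged p is below the cluster mean.

    The p-value of each source is averaged over the cluster's full temporal
    extent (all time samples at which the cluster exists); sources outside
    the STG+ region (or the supplied ``region_mask``) are never considered.
    With ``cluster_id=None`` the largest significant cluster is used.
    Strictly-below selection: a cluster with uniform p yields an empty
    selection.
    """
    if region_mask is None:
        region_mask = space.stg_mask
    labels = result.cluster_labels
    if not result.sig_mask.any():
        raise ValueError("result has no significant cluster")
    if cluster_id is None:
        ids, counts = np.unique(labels[labels >= 0], return_counts=True)
        cluster_id = int(ids[np.argmax(counts)])
    in_cluster = labels == cluster_id
    t_extent = in_cluster.any(axis=0)
    sources = np.flatnonzero(in_cluster.any(axis=1) & region_mask)
    if len(sources) == 0:
        logger.warning("cluster %d has no sources inside the region mask",
                       cluster_id)
        return sources
    mean_p = result.p_map[np.ix_(sources, np.flatnonzero(t_extent))].mean(axis=1)
    selected = sources[mean_p < mean_p.mean()]
    if len(selected) == 0:
        logger.warning("below-average selection is empty (uniform p in cluster)")
    return selected


def pointwise_contrast(
    tc_a: np.ndarray,
    tc_b: np.ndarray,
    alpha: float = 0.05,
    paired: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise t-test of two (n_subjects, n_times) timecourse sets with
    BH-FDR across time samples.

    Returns (t_values, adjusted_p, significant_mask).  ``paired=True`` is the
    test-vs-control contrast within subjects; ``paired=False`` the two-group
    contrast of differential responses.
    """
    tc_a = np.asarray(tc_a, float)
    tc_b = np.asarray(tc_b, float)
    if paired:
        if tc_a.shape != tc_b.shape:
            raise ValueError("paired contrast needs equally shaped inputs")
        if tc_a.shape[0] < 3:
            raise ValueError("need at least 3 subjects")
        t, p = stats.ttest_rel(tc_a, tc_b, axis=0)
    else:
        if min(tc_a.shape[0], tc_b.shape[0]) < 3:
            raise ValueError("need at least 3 subjects per group")
        t, p = stats.ttest_ind(tc_a, tc_b, axis=0)
    rej, p_adj = bh_fdr(p, q=alpha)
    return t, p_adj, rej


def significant_runs(sig: np.ndarray, min_len: int = 1) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive sample indices."""
    sig = np.asarray(sig, bool)
    if not sig.any():
        return []
    d = np.diff(np.r_[0, sig.astype(int), 0])
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s + 1 >= min_len]


def group_difference_window(
    runs_per_source: list[list[tuple[int, int]]],
    times_ms: np.ndarray,
    tvals_per_source: list[np.ndarray] | None = None,
    merge_gap_ms: float = 50.0,
    min_len: int = 1,
) -> tuple[float, float]:
    """Mean onset and mean end time over sources with a significant run.

    Per source, runs shorter than ``min_len`` samples are dropped, runs
    separated by gaps of at most ``merge_gap_ms`` are merged (short
    interruptions of an otherwise sustained difference do not split it), and
    the dominant merged run — largest summed |t| when ``tvals_per_source``
    is given, otherwise the longest — defines that source's onset (first
    significant sample) and end (last).  Isolated spurious FDR discoveries
    far from the sustained difference are thereby ignored.  Sources without
    any qualifying run are excluded; all-empty input raises.
    """
    onsets, ends = [], []
    for i, runs in enumerate(runs_per_source):
        runs = [r for r in runs if r[1] - r[0] + 1 >= min_len]
        if not runs:
            continue
        merged = [list(runs[0])]
        for s, e in runs[1:]:
            if times_ms[s] - times_ms[merged[-1][1]] <= merge_gap_ms:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        if tvals_per_source is not None:
            tv = np.abs(np.asarray(tvals_per_source[i]))
            best = max(merged, key=lambda r: tv[r[0] : r[1] + 1].sum())
        else:
            best = max(merged, key=lambda r: r[1] - r[0])
        onsets.append(times_ms[best[0]])
        ends.append(times_ms[best[1]])
    if not onsets:
        raise ValueError("no source has a significant run")
    return float(np.mean(onsets)), float(np.mean(ends))


def compute_spn_adj(
    test_mag: np.ndarray,
    ctrl_mag: np.ndarray,
    sqrt_n_epochs: np.ndarray,
) -> np.ndarray:
    """SPNadj: residuals of test magnitude after OLS on [1, control
    magnitude, sqrt(epoch count)].

    Residuals are exactly orthogonal to both regressors; adding any linear
    combination of the regressors to ``test_mag`` leaves them unchanged.
    """
    y = np.asarray(test_mag, float)
    x1 = np.asarray(ctrl_mag, float)
    x2 = np.asarray(sqrt_n_epochs, float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    X = np.column_stack([np.ones(n), x1, x2])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "collinear regressors: control magnitude and sqrt(n_epochs) "
            "(with intercept) do not span 3 dimensions"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def measure_spn(
    evoked_test: np.ndarray,
    evoked_ctrl: np.ndarray,
    times_ms: np.ndarray,
    sources: np.ndarray,
    window_ms: tuple[float, float],
    n_epochs_mean: np.ndarray,
) -> SpnMeasures:
    """Average current over selected sources and window, then adjust.

    ``evoked_*`` are (n_subjects, n_vertices, n_times); ``n_epochs_mean`` is
    the per-subject mean epoch count entering sqrt() in the adjustment.
    """
    tmask = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    test_mag = evoked_test[:, sources][:, :, tmask].mean(axis=(1, 2))
    ctrl_mag = evoked_ctrl[:, sources][:, :, tmask].mean(axis=(1, 2))
    adj = compute_spn_adj(test_mag, ctrl_mag, np.sqrt(n_epochs_mean))
    return SpnMeasures(
        test_mag=test_mag,
        ctrl_mag=ctrl_mag,
        spn_adj=adj,
        window_ms=tuple(window_ms),
        sources=np.asarray(sources),
    )
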