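"""Words-in-noise scoring and subject-level statistics.

Scoring: per subject, percent correct in each (SNR, noise type) cell;
WiNst and WiNam are the means over SNR 0, -3 and -6 dB in stationary and
amplitude-modulated noise (the -9 dB level is computed but excluded because
it floors).  Before scoring, words that are at ceiling or floor across the
cohort are excluded.

Statistics: normality-gated group comparison (Shapiro-Wilk p < 0.05 on
either sample selects Mann-Whitney, otherwise Student's t), a permutation
test for the Group x noise-Type interaction on AM-ST difference scores,
partial Pearson/Spearman correlations via precision-matrix inversion,
Fisher's Z for independent correlations and Steiger's Z for dependent
(overlapping) correlations, and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "WinScores",
    "StatResult",
    "exclude_words",
    "score_win",
    "group_compare",
    "interaction_group_by_type",
    "partial_correlation",
    "fisher_z_independent",
    "fisher_z_dependent",
    "bh_fdr",
]

RETAINED_SNRS = (0.0, -3.0, -6.0)


@dataclass
class StatResult:
    name: str
    value: float
    p: float
    n: int | None = None
    df: float | None = None
    effect_size: float | None = None
    detail: dict | None = None


@dataclass
class WinScores:
    """Per-subject percent-correct table and the WiNst/WiNam summaries."""

    per_cell: pd.DataFrame    # columns: subject, snr_db, noise_type, pct
    summary: pd.DataFrame     # columns: subject, WiNst, WiNam, masking_release

    def masking_release(self, snr_db: float) -> pd.Series:
        """AM - ST percent difference at one SNR, indexed by subject."""
        w = self.per_cell.pivot_table(
            index="subject", columns="noise_type", values="pct",
        )
        cell = self.per_cell[self.per_cell.snr_db == snr_db]
        w = cell.pivot(index="subject", columns="noise_type", values="pct")
        return w["AM"] - w["ST"]


def exclude_words(
    responses: pd.DataFrame,
    easy_thresh: float = 0.95,
    hard_thresh: float = 0.05,
) -> np.ndarray:
    """Retained word ids after dropping ceiling/floor words.

    ``responses`` is the long table (subject, word, snr_db, noise_type,
    correct) pooled over the cohort.  A word is excluded as "easiest" when
    its pooled accuracy over all its presentations reaches ``easy_thresh``
    and as "most difficult" when it falls at or below ``hard_thresh``.
    Pooling across conditions is used because each word is presented to any
    subject only once, so per-condition word accuracies are too sparse to
    threshold.
    """
    if not (0 < hard_thresh < easy_thresh <= 1.0) and not (
        easy_thresh == 1.0 and hard_thresh == 0.0
    ):
        raise ValueError("need 0 < hard_thresh < easy_thresh <= 1")
    acc = responses.groupby("word")["correct"].mean()
    easy = acc[acc >= easy_thresh].index if easy_thresh < 1.0 else acc.index[:0]
    hard = acc[acc <= hard_thresh].index if hard_thresh > 0.0 else acc.index[:0]
    retained = acc.index.difference(easy.union(hard)).to_numpy()
    if len(retained) == 0:
        raise ValueError("all words excluded; thresholds too aggressive")
    return retained


def score_win(
    responses: pd.DataFrame,
    retained_words: np.ndarray | None = None,
) -> WinScores:
    """Percent correct per (subject, SNR, noise type) and WiN summaries."""
    df = responses
    if retained_words is not None:
        df = df[df.word.isin(retained_words)]
    per_cell = (
        df.groupby(["subject", "snr_db", "noise_type"])["correct"]
        .mean()
        .mul(100.0)
        .rename("pct")
        .reset_index()
    )
    kept = per_cell[per_cell.snr_db.isin(RETAINED_SNRS)]
    summ = (
        kept.pivot_table(index="subject", columns="noise_type", values="pct")
        .rename(columns={"ST": "WiNst", "AM": "WiNam"})
        .reset_index()
    )
    for col in ("WiNst", "WiNam"):
        if col not in summ.columns:
            summ[col] = np.nan
    summ["masking_release"] = summ["WiNam"] - summ["WiNst"]
    return WinScores(per_cell=per_cell, summary=summ)


def group_compare(
    scores_a,
    scores_b,
    shapiro_alpha: float = 0.05,
) -> StatResult:
    """Two-group comparison with a Shapiro-Wilk normality gate.

    If either sample deviates from normality (p < ``shapiro_alpha``) the
    Mann-Whitney U test is used, otherwise Student's t; the branch taken is
    recorded in ``detail["test"]``.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if min(len(a), len(b)) < 3:
        raise ValueError("need at least 3 observations per group")
    if np.array_equal(np.sort(a), np.sort(b)):
        return StatResult("group_compare", 0.0, 1.0, n=len(a) + len(b),
                          detail={"test": "degenerate-equal"})
    normal = (
        stats.shapiro(a).pvalue >= shapiro_alpha
        and stats.shapiro(b).pvalue >= shapiro_alpha
    )
    n = len(a) + len(b)
    if normal:
        t, p = stats.ttest_ind(a, b)
        sp = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (n - 2)
        )
        d = (a.mean() - b.mean()) / sp if sp > 0 else 0.0
        return StatResult(
            "t", float(t), float(p), n=n, df=n - 2, effect_size=float(d),
            detail={"test": "student_t"},
        )
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    z = stats.norm.isf(res.pvalue / 2.0)
    return StatResult(
        "U", float(res.statistic), float(res.pvalue), n=n,
        effect_size=float(z**2 / n), detail={"test": "mann_whitney", "Z": float(z)},
    )


def interaction_group_by_type(
    win_long: pd.DataFrame,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
) -> StatResult:
    """Group x noise-Type interaction via label permutation.

    ``win_long`` needs columns (subject, group, snr_db, noise_type, pct).
    Each subject is reduced to the AM-ST difference averaged over the
    retained SNRs; the observed between-group difference of these difference
    scores is compared to its group-label permutation distribution.  With
    two within-subject levels this is the random-intercept interaction.
    Subjects missing a cell are dropped.
    """
    rng = rng or np.random.default_rng()
    df = win_long[win_long.snr_db.isin(RETAINED_SNRS)]
    wide = df.pivot_table(
        index=["subject", "group"], columns="noise_type", values="pct",
    )
    wide = wide.dropna(subset=["AM", "ST"])
    diff = (wide["AM"] - wide["ST"]).reset_index()
    groups = diff["group"].to_numpy()
    vals = diff[0].to_numpy()
    g_names = np.unique(groups)
    if len(g_names) != 2:
        raise ValueError("need exactly two groups")
    ga = groups == g_names[0]
    obs = vals[ga].mean() - vals[~ga].mean()
    n_a = ga.sum()
    count = 0
    for _ in range(n_perm):
        perm = np.zeros(len(vals), bool)
        perm[rng.permutation(len(vals))[:n_a]] = True
        stat = vals[perm].mean() - vals[~perm].mean()
        if abs(stat) >= abs(obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return StatResult(
        "interaction_perm", float(obs), float(p), n=len(vals),
        detail={"groups": list(g_names), "n_perm": n_perm},
    )


def partial_correlation(
    x,
    y,
    covariates: np.ndarray | None = None,
    method: str = "pearson",
) -> StatResult:
    """Partial correlation of x and y controlling for covariates.

    Spearman rank-transforms every variable first.  The partial coefficient
    comes from the inverse of the joint correlation matrix; the two-tailed p
    from the t distribution with n - 2 - k degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cols = [x, y]
    k = 0
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] == len(x) and cov.shape[1] != len(x):
            cov = cov.T
        k = cov.shape[0]
        cols += [cov[i] for i in range(k)]
    n = len(x)
    if n <= k + 2:
        raise ValueError(f"need n > k+2 observations (n={n}, k={k})")
    M = np.column_stack(cols)
    if method == "spearman":
        M = np.apply_along_axis(stats.rankdata, 0, M)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    C = np.corrcoef(M, rowvar=False)
    if not np.all(np.isfinite(C)):
        raise ValueError("constant variable: correlation undefined")
    try:
        P = np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular covariate correlation matrix") from err
    r = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * stats.t.sf(abs(t), df)
    return StatResult(f"R_part_{method}", r, float(p), n=n, df=df,
                      detail={"k": k})


def fisher_z_independent(r1: float, n1: int, r2: float, n2: int) -> StatResult:
    """Fisher's Z for correlations from two independent samples."""
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1")
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 in each sample")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return StatResult("fisher_z_independent", float(z), float(p), n=n1 + n2)


def fisher_z_dependent(
    r_xy1: float, r_xy2: float, r_y1y2: float, n: int
) -> StatResult:
    """Steiger's Z for two dependent correlations sharing one variable.

    Compares corr(x, y1) with corr(x, y2) given corr(y1, y2) in one sample
    of size n (Steiger 1980, with the Williams-style covariance term).
    """
    C = np.array(
        [[1.0, r_xy1, r_xy2], [r_xy1, 1.0, r_y1y2], [r_xy2, r_y1y2, 1.0]]
    )
    if np.linalg.eigvalsh(C).min() < -1e-10:
        raise ValueError("inconsistent correlation triple (not PSD)")
    for r in (r_xy1, r_xy2):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1")
    rbar = 0.5 * (r_xy1 + r_xy2)
    s = (
        r_y1y2 * (1.0 - 2.0 * rbar**2)
        - 0.5 * rbar**2 * (1.0 - 2.0 * rbar**2 - r_y1y2**2)
    ) / (1.0 - rbar**2) ** 2
    z = (np.arctanh(r_xy1) - np.arctanh(r_xy2)) * np.sqrt(
        (n - 3) / (2.0 * (1.0 - s))
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return StatResult("steiger_z_dependent", float(z), float(p), n=n)


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (reject mask, adjusted p)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    rej, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return rej, p_adj
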