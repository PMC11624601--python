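"""Words-in-noise scoring, exclusion, and subject-level statistics against
brute-force / closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spnpipe.behavior import (
    bh_fdr,
    exclude_words,
    fisher_z_dependent,
    fisher_z_independent,
    group_compare,
    interaction_group_by_type,
    partial_correlation,
    score_win,
)
from spnpipe.cohort import SubjectRecord, WinLinkConfig, simulate_win_behavior


def _responses(n_subj=40, rng=None, link=None):
    rng = rng or np.random.default_rng(0)
    link = link or WinLinkConfig()
    recs = [
        SubjectRecord(subject=i, group="TD", age=float(rng.uniform(7, 13)),
                      iq=100.0)
        for i in range(n_subj)
    ]
    inv = simulate_win_behavior(recs, link, rng)
    df = pd.concat(
        [r.win_responses.assign(subject=r.subject) for r in recs]
    )
    return df, inv


class TestExcludeWords:
    def test_trivial_thresholds_keep_everything(self):
        df, _ = _responses(10)
        retained = exclude_words(df, easy_thresh=1.0, hard_thresh=0.0)
        # only words that are literally perfect/never-correct could drop at
        # the degenerate thresholds; at (1.0, 0.0) nothing is dropped
        assert len(retained) == df.word.nunique()

    def test_extreme_words_flagged(self):
        # study-sized cohort: the 18 constructed ceiling/floor words violate
        # the default criteria, 142 of 160 are retained
        rng = np.random.default_rng(1)
        df, inv = _responses(74, rng=rng)
        retained = exclude_words(df)
        excluded = set(range(160)) - set(retained)
        flagged = set(inv.loc[inv.flag != "normal", "word"])
        assert excluded == flagged
        assert len(retained) == 142

    def test_all_excluded_raises(self):
        df = pd.DataFrame(
            {"subject": [0, 0], "word": [0, 1], "snr_db": [0.0, 0.0],
             "noise_type": ["ST", "ST"], "correct": [True, True]}
        )
        with pytest.raises(ValueError, match="all words"):
            exclude_words(df, easy_thresh=0.5, hard_thresh=0.05)


class TestScoreWin:
    def test_all_correct_subject(self):
        rows = [
            (0, w, snr, nt, True)
            for w, (snr, nt) in enumerate(
                [(s, n) for s in (0.0, -3.0, -6.0, -9.0) for n in ("ST", "AM")] * 2
            )
        ]
        df = pd.DataFrame(
            rows, columns=["subject", "word", "snr_db", "noise_type", "correct"]
        )
        sc = score_win(df)
        assert (sc.per_cell.pct == 100.0).all()
        assert sc.summary.loc[0, "WiNst"] == 100.0
        assert sc.summary.loc[0, "WiNam"] == 100.0

    def test_alternating_half_correct(self):
        rows = [(0, w, 0.0, "ST", w % 2 == 0) for w in range(20)]
        df = pd.DataFrame(
            rows, columns=["subject", "word", "snr_db", "noise_type", "correct"]
        )
        sc = score_win(df)
        assert sc.per_cell.pct.iloc[0] == 50.0

    def test_hand_table_means_and_minus9_exclusion(self):
        # 6 words x 2 SNR: WiNst averages only the retained SNRs
        rows = []
        for w, ok in enumerate([True, True, False]):
            rows.append((0, w, 0.0, "ST", ok))
        for w, ok in enumerate([False, False, False]):
            rows.append((0, 3 + w, -9.0, "ST", ok))
        df = pd.DataFrame(
            rows, columns=["subject", "word", "snr_db", "noise_type", "correct"]
        )
        sc = score_win(df)
        assert sc.summary.loc[0, "WiNst"] == pytest.approx(200.0 / 3)
        cell = sc.per_cell.set_index("snr_db")
        assert cell.loc[-9.0, "pct"] == 0.0  # computed but not in WiNst


class TestGroupCompare:
    def test_skewed_sample_goes_nonparametric(self):
        rng = np.random.default_rng(0)
        a = rng.exponential(1.0, 40) ** 2
        b = rng.exponential(1.0, 40) ** 2
        res = group_compare(a, b)
        assert res.detail["test"] == "mann_whitney"

    def test_normal_samples_go_parametric_mostly(self):
        # gate calibration: the Shapiro gate trips ~5% per sample, so normal
        # data takes the parametric branch in the large majority of draws
        parametric = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            res = group_compare(rng.normal(0, 1, 30), rng.normal(0.5, 1, 30))
            parametric += res.detail["test"] == "student_t"
            if res.detail["test"] == "student_t":
                assert res.df == 58
        assert parametric >= 15

    def test_equal_samples_p_one(self):
        x = np.arange(10.0)
        res = group_compare(x, x.copy())
        assert res.p == 1.0


class TestInteraction:
    def _long(self, release_a=0.0, n=15, rng=None):
        rng = rng or np.random.default_rng(0)
        rows = []
        for g, rel in (("TD", release_a), ("ASD", 0.0)):
            for s in range(n):
                sid = f"{g}{s}"
                for snr in (0.0, -3.0, -6.0):
                    base = rng.normal(50, 5)
                    rows.append((sid, g, snr, "ST", base))
                    rows.append((sid, g, snr, "AM", base + rel + rng.normal(0, 2)))
        return pd.DataFrame(
            rows, columns=["subject", "group", "snr_db", "noise_type", "pct"]
        )

    def test_constructed_interaction_detected(self):
        df = self._long(release_a=10.0)
        res = interaction_group_by_type(df, n_perm=2000,
                                        rng=np.random.default_rng(0))
        assert res.p < 0.001
        assert abs(res.value) == pytest.approx(10.0, abs=3.0)

    def test_null_not_rejected_mostly(self):
        rejections = 0
        for seed in range(20):
            df = self._long(release_a=0.0, rng=np.random.default_rng(seed))
            res = interaction_group_by_type(
                df, n_perm=400, rng=np.random.default_rng(seed)
            )
            rejections += res.p < 0.05
        assert rejections <= 3


class TestPartialCorrelation:
    def test_no_covariates_equals_plain_correlation(self, rng):
        x = rng.normal(0, 1, 50)
        y = 0.5 * x + rng.normal(0, 1, 50)
        res = partial_correlation(x, y, method="pearson")
        assert res.value == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-10)
        res_s = partial_correlation(x, y, method="spearman")
        assert res_s.value == pytest.approx(stats.spearmanr(x, y)[0], abs=1e-10)

    def test_y_nearly_equal_covariate_partials_out(self, rng):
        x = rng.normal(0, 1, 60)
        z = rng.normal(0, 1, 60)
        y = z + rng.normal(0, 1e-6, 60)
        res = partial_correlation(x, y, covariates=z[None, :])
        assert abs(res.value) < 0.2

    def test_eight_row_table_matches_residual_oracle(self):
        # two-stage OLS oracle: correlate the residuals of x and y on Z
        x = np.array([1.0, 2.0, 3.5, 2.2, 5.1, 4.4, 3.3, 6.0])
        y = np.array([2.0, 1.0, 4.0, 2.5, 5.5, 3.9, 3.0, 5.8])
        z = np.array([[1.0, 1.2, 2.0, 1.4, 3.0, 2.6, 2.1, 3.3],
                      [0.2, 0.9, 0.1, 0.8, 0.3, 0.7, 0.5, 0.6]])
        Z = np.column_stack([np.ones(8), z.T])
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        oracle = np.corrcoef(rx, ry)[0, 1]
        res = partial_correlation(x, y, covariates=z)
        assert res.value == pytest.approx(oracle, abs=1e-10)
        assert res.df == 8 - 2 - 2

    def test_singular_covariates_raise(self):
        x = np.arange(8.0)
        y = np.arange(8.0)[::-1]
        z = np.vstack([np.arange(8.0), 2 * np.arange(8.0)])
        with pytest.raises(ValueError):
            partial_correlation(x, y, covariates=z)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_partial_spearman_monotone_invariant(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0, 1, 25)
        z = rng.normal(0, 1, 25)
        base = partial_correlation(x, y, z[None, :], method="spearman")
        warped = partial_correlation(
            np.exp(x), y**3 + 10 * y, np.arctan(z)[None, :], method="spearman"
        )
        assert warped.value == pytest.approx(base.value, abs=1e-10)


class TestFisherZ:
    def test_equal_correlations_zero(self):
        res = fisher_z_independent(0.4, 30, 0.4, 40)
        assert res.value == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_closed_form_value(self):
        res = fisher_z_independent(0.5, 28, 0.0, 28)
        expected = np.arctanh(0.5) / np.sqrt(2.0 / 25.0)
        assert res.value == pytest.approx(expected, abs=1e-12)

    def test_antisymmetry(self):
        a = fisher_z_independent(0.6, 30, 0.2, 25)
        b = fisher_z_independent(0.2, 25, 0.6, 30)
        assert a.value == pytest.approx(-b.value, abs=1e-12)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_independent(1.0, 30, 0.2, 30)

    def test_dependent_equal_correlations_zero(self):
        res = fisher_z_dependent(0.5, 0.5, 0.3, 26)
        assert res.value == pytest.approx(0.0, abs=1e-12)

    def test_dependent_formula_oracle(self):
        # direct evaluation of the Steiger (1980) formula
        r1, r2, r12, n = 0.55, 0.30, 0.40, 26
        rbar = (r1 + r2) / 2
        s = (r12 * (1 - 2 * rbar**2)
             - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r12**2)) / (1 - rbar**2) ** 2
        expected = (np.arctanh(r1) - np.arctanh(r2)) * np.sqrt(
            (n - 3) / (2 * (1 - s))
        )
        res = fisher_z_dependent(r1, r2, r12, n)
        assert res.value == pytest.approx(expected, abs=1e-12)

    def test_dependent_monotone_in_overlap(self):
        # larger correlation between the two overlapping variables makes the
        # same difference more surprising: |Z| increases with r_y1y2
        zs = [abs(fisher_z_dependent(0.6, 0.4, r12, 40).value)
              for r12 in (0.0, 0.3, 0.6, 0.8)]
        assert all(b > a for a, b in zip(zs, zs[1:]))

    def test_inconsistent_triple_rejected(self):
        with pytest.raises(ValueError, match="PSD"):
            fisher_z_dependent(0.9, -0.9, 0.9, 30)


class TestBhFdr:
    def test_single_small_p(self):
        rej, adj = bh_fdr([0.01])
        assert rej[0] and adj[0] == pytest.approx(0.01)

    def test_all_ones(self):
        rej, _ = bh_fdr([1.0, 1.0, 1.0])
        assert not rej.any()

    def test_step_up_oracle(self):
        # exhaustive step-up: largest k with p_(k) <= k q / m
        p = np.array([0.001, 0.011, 0.02, 0.04, 0.9])
        q, m = 0.05, 5
        order = np.sort(p)
        k_star = max(
            (k + 1 for k in range(m) if order[k] <= (k + 1) * q / m), default=0
        )
        expected = p <= order[k_star - 1] if k_star else np.zeros(m, bool)
        rej, _ = bh_fdr(p, q=q)
        assert np.array_equal(rej, expected)
        assert rej.sum() == 4

    def test_worked_example_first_three_pass(self):
        rej, _ = bh_fdr([0.001, 0.01, 0.02, 0.8], q=0.05)
        assert rej.tolist() == [True, True, True, False]

    def test_fdr_controlled_on_nulls(self):
        # 300 replicates of 20 uniform nulls + 5 strong signals
        rng = np.random.default_rng(0)
        fdps = []
        for _ in range(300):
            p = np.concatenate([rng.uniform(0, 1, 20), rng.uniform(0, 1e-5, 5)])
            rej, _ = bh_fdr(p, q=0.05)
            false = rej[:20].sum()
            fdps.append(false / max(rej.sum(), 1))
        assert np.mean(fdps) <= 0.05 + 0.02

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 500))
    def test_adjusted_p_monotone_in_raw_p(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 12)
        _, adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
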