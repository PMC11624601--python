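"""End-to-end orchestration: generate (or ingest) -> preprocess -> TFCE ->
source selection -> SPNadj -> P3a -> behavioral linkage, with one global
seed and a JSON manifest of parameters.

The three analysis steps mirror the study design: (1) within each group,
test-versus-control one-sample TFCE establishes the SPN; (2) two-sample
TFCE on differential responses locates group differences; (3) the SPNadj of
the most significant sources is linked to words-in-noise scores by partial
correlation controlling age and IQ.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (
    exclude_words,
    fisher_z_dependent,
    group_compare,
    interaction_group_by_type,
    partial_correlation,
    score_win,
)
from .cohort import (
    CohortConfig,
    WinLinkConfig,
    make_source_space,
    records_to_frame,
    simulate_evoked,
    simulate_win_behavior,
)
from .io import ingest_real
from .p3a import detect_p3a
from .preprocess import align_polarity, baseline_crop_resample
from .spn import (
    group_difference_window,
    measure_spn,
    pointwise_contrast,
    select_most_significant_sources,
    significant_runs,
)
from .tfce import TfceParams, one_sample_tfce_test, two_sample_tfce_test

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full", "ingest_real"]

TEST_CONDITIONS = ("periodic_vowel", "nonperiodic_vowel", "periodic_nonvowel")


@dataclass
class PipelineConfig:
    """One structured configuration governing every stage."""

    seed: int = 0
    profile: str = "test"              # "test" (500 perms) or "full" (5000)
    out_dir: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    link: WinLinkConfig = field(default_factory=WinLinkConfig)
    tfce: TfceParams = field(default_factory=TfceParams)
    contrasts: tuple[str, ...] = TEST_CONDITIONS
    fs_out: float = 500.0
    alpha: float = 0.05
    easy_thresh: float = 0.95
    hard_thresh: float = 0.05

    def __post_init__(self):
        n_perm = {"test": 500, "full": 5000}.get(self.profile)
        if n_perm is None:
            raise ValueError("profile must be 'test' or 'full'")
        self.tfce = replace(self.tfce, n_perm=n_perm)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, sub in (
            ("cohort", CohortConfig),
            ("link", WinLinkConfig),
            ("tfce", TfceParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "contrasts" in raw:
            raw["contrasts"] = tuple(raw["contrasts"])
        return cls(**raw)


def _cluster_summary_row(contrast, who, hemi, result, space, times):
    hm = space.hemi_mask(hemi)
    sig = result.sig_mask[hm]
    if not sig.any():
        return {
            "contrast": contrast, "test": who, "hemi": hemi, "n_sig": 0,
            "min_p": float(result.p_map[hm].min()), "peak_stat": np.nan,
            "t_start_ms": np.nan, "t_end_ms": np.nan,
        }
    tmask = sig.any(axis=0)
    stat = result.stat_map[hm]
    peak = stat[sig][np.argmax(np.abs(stat[sig]))]
    return {
        "contrast": contrast, "test": who, "hemi": hemi,
        "n_sig": int(sig.sum()),
        "min_p": float(result.p_map[hm].min()),
        "peak_stat": float(peak),
        "t_start_ms": float(times[tmask][0]),
        "t_end_ms": float(times[tmask][-1]),
    }


def _largest_cluster_in_hemi(result, space, hemi):
    hm = space.hemi_mask(hemi)
    labs = result.cluster_labels[hm]
    labs = labs[labs >= 0]
    if labs.size == 0:
        return None
    ids, counts = np.unique(labs, return_counts=True)
    return int(ids[np.argmax(counts)])


def run_full(config: PipelineConfig) -> dict:
    """Execute the full synthetic-mode analysis; returns the report bundle
    (DataFrames and the manifest dict) and writes CSVs when ``out_dir`` is
    set."""
    t_start = time.time()
    rng = np.random.default_rng(config.seed)
    stage = "generate"
    try:
        space = make_source_space(config.cohort.n_vertices_per_hemi)
        ev, records = simulate_evoked(space, config.cohort, rng)
        inventory = simulate_win_behavior(records, config.link, rng)
        logger.info("generated %d subjects on %d vertices",
                    len(records), space.n_vertices)

        stage = "preprocess"
        aligned, align_report = align_polarity(ev, space)
        pp = baseline_crop_resample(aligned, fs_out=config.fs_out)
        wide = baseline_crop_resample(
            aligned, window_ms=(-200.0, 800.0), fs_out=config.fs_out
        )
        times = pp.times_ms
        groups = np.array([r.group for r in records])
        is_asd = groups == "ASD"

        stage = "tfce"
        ctrl = pp.get("control")
        cluster_rows, windows, spn_rows = [], {}, []
        for cond in config.contrasts:
            diffs = pp.get(cond) - ctrl
            for gname, gmask in (("TD", ~is_asd), ("ASD", is_asd)):
                res1 = one_sample_tfce_test(
                    diffs[gmask], space, config.tfce, rng
                )
                for hemi in ("L", "R"):
                    cluster_rows.append(_cluster_summary_row(
                        cond, f"one_sample_{gname}", hemi, res1, space, times
                    ))
            res2 = two_sample_tfce_test(
                diffs[is_asd], diffs[~is_asd], space, config.tfce, rng
            )
            for hemi in ("L", "R"):
                cluster_rows.append(_cluster_summary_row(
                    cond, "two_sample", hemi, res2, space, times
                ))

            stage = "source_selection"
            for hemi in ("L", "R"):
                cid = _largest_cluster_in_hemi(res2, space, hemi)
                if cid is None:
                    continue
                region = space.stg_mask & space.hemi_mask(hemi)
                sources = select_most_significant_sources(
                    res2, space, region_mask=region, cluster_id=cid
                )
                if len(sources) == 0:
                    continue
                runs_per_source, tvals = [], []
                for s in sources:
                    t, _, sig = pointwise_contrast(
                        diffs[is_asd][:, s], diffs[~is_asd][:, s],
                        alpha=config.alpha, paired=False,
                    )
                    runs_per_source.append(significant_runs(sig))
                    tvals.append(t)
                try:
                    win = group_difference_window(runs_per_source, times, tvals)
                except ValueError:
                    continue
                windows[(cond, hemi)] = (win, sources)
                n_ep = ev.n_epochs.mean(axis=1)
                meas = measure_spn(
                    pp.get(cond)[is_asd], ctrl[is_asd], times, sources, win,
                    n_ep[is_asd],
                )
                for i, subj in enumerate(np.flatnonzero(is_asd)):
                    spn_rows.append({
                        "subject": int(subj), "hemi": hemi, "condition": cond,
                        "window_on_ms": win[0], "window_end_ms": win[1],
                        "test_mag": meas.test_mag[i], "ctrl_mag": meas.ctrl_mag[i],
                        "spn_adj": meas.spn_adj[i],
                    })

        stage = "p3a"
        p3a_rows = []
        for hemi in ("L", "R"):
            hm = np.flatnonzero(space.stg_mask & space.hemi_mask(hemi))
            for cond in ("periodic_vowel", "nonperiodic_vowel", "control"):
                tcs = (wide.get(cond) - wide.get("control"))[:, hm].mean(axis=1) \
                    if cond != "control" else wide.get("control")[:, hm].mean(axis=1)
                for s, rec in enumerate(records):
                    m = detect_p3a(tcs[s], wide.times_ms, wide.fs)
                    p3a_rows.append({
                        "subject": s, "group": rec.group, "hemi": hemi,
                        "condition": cond, "present": m.present,
                        "amplitude": m.amplitude, "latency_ms": m.peak_latency_ms,
                    })

        stage = "behavior"
        responses = pd.concat(
            [r.win_responses.assign(subject=r.subject, group=r.group)
             for r in records]
        )
        retained = exclude_words(responses, config.easy_thresh, config.hard_thresh)
        scores = score_win(responses, retained)
        summ = scores.summary.merge(records_to_frame(records), on="subject")
        stat_rows = []
        for col in ("WiNst", "WiNam"):
            res = group_compare(
                summ.loc[summ.group == "TD", col],
                summ.loc[summ.group == "ASD", col],
            )
            stat_rows.append({"name": f"group_{col}", "value": res.value,
                              "p": res.p, "test": res.detail["test"]})
        long = scores.per_cell.merge(
            records_to_frame(records)[["subject", "group"]], on="subject"
        )
        inter = interaction_group_by_type(long, rng=rng)
        stat_rows.append({"name": "interaction_group_by_type",
                          "value": inter.value, "p": inter.p, "test": "perm"})

        stage = "linkage"
        spn_df = pd.DataFrame(spn_rows)
        link_rows = []
        if len(spn_df):
            asd = summ[summ.group == "ASD"].set_index("subject")
            for (cond, hemi), grp in spn_df.groupby(["condition", "hemi"]):
                g = grp.set_index("subject").join(asd, how="inner")
                if len(g) <= 4:
                    continue
                for score in ("WiNam", "WiNst"):
                    res = partial_correlation(
                        g["spn_adj"], g[score],
                        covariates=np.c_[g["age"], g["iq"]].T,
                        method="spearman",
                    )
                    link_rows.append({
                        "condition": cond, "hemi": hemi, "score": score,
                        "R_part": res.value, "p": res.p, "n": res.n,
                    })
            for cond in set(c for c, _ in windows):
                sub = pd.DataFrame(link_rows)
                sel = sub[(sub.condition == cond) & (sub.hemi == "L")]
                if len(sel) == 2:
                    r_am = float(sel[sel.score == "WiNam"].R_part.iloc[0])
                    r_st = float(sel[sel.score == "WiNst"].R_part.iloc[0])
                    gsub = spn_df[(spn_df.condition == cond)
                                  & (spn_df.hemi == "L")].set_index("subject")
                    j = gsub.join(asd, how="inner")
                    r_scores = float(np.corrcoef(j["WiNam"], j["WiNst"])[0, 1])
                    cmpres = fisher_z_dependent(r_am, r_st, r_scores, len(j))
                    stat_rows.append({
                        "name": f"steiger_WiNam_vs_WiNst_{cond}_L",
                        "value": cmpres.value, "p": cmpres.p, "test": "steiger_z",
                    })

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "profile": config.profile,
            "n_perm": config.tfce.n_perm,
            "n_subjects": len(records),
            "n_vertices": space.n_vertices,
            "flagged_alignment": align_report.flagged,
            "n_words_retained": int(len(retained)),
            "contrasts": list(config.contrasts),
            "elapsed_s": round(time.time() - t_start, 2),
        }
        bundle = {
            "clusters": pd.DataFrame(cluster_rows),
            "spn": spn_df,
            "p3a": pd.DataFrame(p3a_rows),
            "win_scores": summ,
            "stats": pd.DataFrame(stat_rows),
            "linkage": pd.DataFrame(link_rows),
            "manifest": manifest,
            "inventory": inventory,
            "windows": windows,
        }
        if config.out_dir:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            for key in ("clusters", "spn", "p3a", "win_scores", "stats",
                        "linkage"):
                bundle[key].to_csv(out / f"{key}.csv", index=False)
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=2, default=str)
            )
        return bundle
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        raise
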