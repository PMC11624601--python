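# spnpipe

Analysis pipeline for the **sustained processing negativity (SPN)** — the
long-lasting negative shift of auditory-cortex source current evoked by
vowel-like sounds — and its linkage to **words-in-noise (WiN)** perception
in children.  The scientific question it serves: is the cortical grouping
of vowel formants into phonetic objects weakened in autism, and does that
weakening predict difficulty recovering words from fluctuating background
noise?

The package is aimed at auditory-MEG researchers who start from
source-space evoked current timecourses (subject x condition x vertex x
time) and want a tested, reusable implementation of the full analysis
chain.  A synthetic cohort generator with stored ground truth makes every
stage testable end-to-end with no data download.

## What it implements

* **Stimulus synthesis** (`spnpipe.stimuli`): the four stimulus classes —
  {periodic, non-periodic} x {vowel, non-vowel} — built from damped
  sinusoids repeated every 12 ms (f0 = 83.3 Hz), with +/-6 ms onset jitter
  breaking periodicity and per-pulse carrier randomization breaking formant
  constancy; pink-noise and 10 Hz amplitude-modulated maskers; trial
  sequences (270 per class, ISI 500-800 ms); WAV export.
* **Synthetic cohort** (`spnpipe.cohort`): two groups (default 39 TD /
  35 ASD) of evoked responses on a grid-graph cortical surrogate with
  A1 / A4 / pINS / STG+ labels, containing a P100m transient, a
  condition-dependent SPN, a group deficit confined to A4+pINS and
  150-450 ms, an optional left-hemisphere P3a-like bump, epoch-scaled
  noise, and WiN behavior linked to the injected deficit.
* **Preprocessing** (`spnpipe.preprocess`): per-vertex polarity alignment
  (P100m-positive convention), baseline correction, crop to 0-800 ms,
  downsampling to 500 Hz.
* **TFCE permutation statistics** (`spnpipe.tfce`): spatiotemporal
  threshold-free cluster enhancement,

      TFCE(p) = ∫_{h0}^{h_p} e(h)^E h^H dh,    E = 0.5, H = 2, dh = 0.4,

  with sign-flip one-sample and label-shuffle two-sample permutation tests,
  disjoint hemispheres, and max-statistic family-wise correction.
* **SPN measures** (`spnpipe.spn`): most-significant-source selection
  inside STG+, pointwise FDR contrasts, group-difference windows, and
  SPNadj (test-condition magnitude with control magnitude and
  sqrt(n_epochs) regressed out).
* **P3a-like detection** (`spnpipe.p3a`): 10 Hz low-pass, largest positive
  peak in 200-400 ms vs. flanking minima, presence gated by baseline RMS;
  chi-square occurrence and Mann-Whitney amplitude comparisons.
* **Behavioral statistics** (`spnpipe.behavior`): word exclusion, WiNst /
  WiNam scoring, normality-gated group tests, a permutation
  Group x noise-Type interaction, partial Pearson/Spearman correlations,
  Fisher / Steiger Z correlation comparisons, Benjamini-Hochberg FDR.
* **Orchestration** (`spnpipe.pipeline`, CLI `spnpipe`): one seeded config
  drives generate → preprocess → TFCE → selection → SPNadj → P3a →
  behavioral linkage, writing CSV tables and a JSON manifest.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

```python
import numpy as np
from spnpipe.stimuli import StimulusSpec, synth_stimulus, envelope_f0
from spnpipe.cohort import CohortConfig
from spnpipe.pipeline import PipelineConfig, run_full

w = synth_stimulus(StimulusSpec.for_class("periodic_vowel"),
                   np.random.default_rng(0))
print("f0 =", round(envelope_f0(w), 1), "Hz")          # f0 = 83.3 Hz

cfg = PipelineConfig(
    seed=7, profile="test",
    cohort=CohortConfig(n_td=12, n_asd=12, n_vertices_per_hemi=50,
                        fs=250.0, p3a_amp=0.0),
    contrasts=("periodic_vowel",), fs_out=250.0,
)
bundle = run_full(cfg)
print(bundle["clusters"].query("test == 'two_sample'")
      [["hemi", "n_sig", "min_p", "t_start_ms", "t_end_ms"]])
```

prints (seed 7):

```
hemi  n_sig     min_p  t_start_ms  t_end_ms
   L    551  0.001996       160.0     440.0
   R    394  0.001996       160.0     436.0
```

i.e. the two-sample TFCE test finds, in both hemispheres, a cluster of
group differences in the vowel-minus-control differential response whose
temporal extent brackets the injected 150-450 ms deficit; `min_p` is the
permutation floor at 500 permutations.  The derived group-difference
windows for this run are 184.7-428.7 ms (left, 6 selected sources) and
153.3-374.7 ms (right, 3 sources); `bundle["linkage"]` then holds the
partial Spearman correlations of SPNadj with WiNam/WiNst in the ASD
subsample (at this toy size, n = 12, they are estimated but noisy — the
n = 26 operating characteristics are exercised in the test suite).

The same run from a shell:

```bash
spnpipe run --seed 7 --profile test --out-dir results/run7
spnpipe stimgen --klass periodic_vowel --seed 0 --out-dir stimuli_out
```

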