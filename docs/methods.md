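# Methods

`spnpipe` implements a source-space analysis of the **sustained processing
negativity (SPN)** — the prolonged negative shift of auditory-cortex current
evoked by patterned sounds such as vowels — and of its behavioral linkage to
words-in-noise (WiN) perception in a two-group (TD / ASD) child cohort.
This note documents the models, the synthetic data the pipeline is
validated on, and the numerical choices.

## Stimulus model

MEG stimuli are 812 ms trains of damped sinusoids,
`sin(2*pi*f*t) * 2^(-t/tau)`, with four formant trains summed and a 10 ms
raised-cosine rise/fall:

* **periodic** classes place pulse onsets on an exact 12 ms grid
  (f0 = 83.3 Hz); **non-periodic** classes jitter each onset i.i.d.
  uniformly within +/-6 ms, independently per pulse and per formant
  (jittered onsets outside the window are clipped to it; overrunning pulses
  are truncated at the stimulus end);
* **vowel** classes keep each formant's carrier fixed at the formant center;
  **non-vowel** classes draw every pulse's carrier uniformly from a set of
  8 log-spaced frequencies spanning the formant band (F1 270-1300,
  F2 850-2260, F3 1750-3000, F4 3300-5500 Hz).

Choices left open by the construction rules: the damping half-life defaults
to 3 ms (a quarter period — formant peaks stay audible while each pulse
decays to ~6% before the next onset); vowel formant tables are standard
adult-male values (/a/ /e/ /i/ /o/ /u/) nudged inside the bands above; the
pulse phase at onset is 0; sample rate 44.1 kHz.  All are configurable on
`StimulusSpec`.

WiN maskers are 1 s of spectrally shaped pink noise (PSD proportional to
1/f, i.e. -3 dB/octave), optionally multiplied by the 100%-depth envelope
`(1 + sin(2*pi*10*t))/2` (sine starting at 0 degrees, interrupting the
noise 10 times per second), with 1 ms edge smoothing.  The masker leads the
word by 75 ms and is scaled to realize the requested SNR (0, -3, -6, -9 dB)
against the word's RMS.

## Synthetic cohort

The generator (`spnpipe.cohort`) produces everything downstream stages
consume, with stored ground truth, so the full pipeline is testable without
recordings.  Defaults mirror the study conditions: 39 TD / 35 ASD boys aged
~7-13, per-condition epoch counts uniform on 140-340 (mean ~231 averaged
epochs), raw sampling at 1 kHz over -200 to 1000 ms.

* **Source space**: one planar grid graph per hemisphere (no
  cross-hemisphere edges), with an "STG+" band of middle rows containing
  contiguous pINS, A1 and A4 column patches — a topological surrogate for
  the auditory ROI, not cortical geometry.
* **Evoked model** per subject/condition, in arbitrary current units:
  positive P100m Gaussian (peak 100 ms, sigma 25 ms, gain 1 in STG+ and
  0.25 outside); SPN plateau of amplitude 0.6 / 0.5 / 0.4 / 0 (periodic
  vowel / non-periodic vowel / periodic non-vowel / control) over STG+,
  onset 80 ms, 40 ms rise, lasting to 600 ms; an ASD-only **deficit** term
  (+0.5 x subject latent, latent ~ N(1, 0.4) truncated at 0) confined to
  A4 + pINS and 150-450 ms for the two vowel conditions — at this amplitude
  a typical latent erases the vowel negativity in the affected regions,
  matching the reported near-abolition there; an optional left-hemisphere
  P3a-like Gaussian (300 ms, sigma 40 ms, amplitude 0.35, scaled 1.6x for
  ASD periodic vowels) with group/condition prevalence echoing the reported
  percentages; temporally smoothed Gaussian noise (20 ms autocorrelation,
  per-trace SD 4/sqrt(n_epochs) ~ 0.26).  Only relative amplitudes are
  meaningful; no physical units are claimed.
* **Behavior**: each subject hears each of 160 words once, 20 per
  (SNR x noise-type) cell.  P(correct) is logistic in effective SNR with
  slope 0.35/dB; word thresholds ~ N(0, 1.5) dB, with 10 ceiling and 8
  floor words built in so the standard exclusion criteria flag exactly 18;
  amplitude-modulated noise adds +3 dB masking release and a -2.5 dB/latent
  SPN penalty (the WiNam-only link); age adds +0.5 dB/yr.  These constants
  were fixed once from a closed-form power sketch so that the ASD-subsample
  partial correlation magnitude sits near the reported ~ -0.55; the -9 dB
  stationary cell floors for roughly half the cohort, motivating its
  exclusion from the WiNst/WiNam summaries.

What the generator does **not** emulate: realistic cortical geometry and
field spread, 1/f sensor noise, spatially correlated noise, non-stationary
artifacts, lapses/guessing in the psychometric function.  Passing tests
therefore demonstrate correctness and calibration of the *statistics*, not
performance on real MEG data.

## Preprocessing

Per-vertex current polarity is aligned per subject on condition-average
data: the sign of the correlation with the hemisphere ROI mean (one
refinement iteration), with the global hemisphere sign fixed by the
convention that the P100m (50-150 ms) is positive and the sustained
response (300-800 ms) negative; subjects violating the convention after
alignment are flagged, never silently passed.  This correlation rule is
equivalent up to global sign to eigenvector-based sign flipping; the sign
of noise-only vertices is indeterminate by nature and harmless.  Traces are
then baseline-corrected (-200-0 ms), polyphase-resampled (zero-phase
anti-alias FIR) to 500 Hz, and cropped to the half-open [0, 800) ms window
(400 samples).

## TFCE and permutation inference

For each point p of a vertex x time statistic map, threshold-free cluster
enhancement integrates `e(h)^E * h^H` over thresholds h, where e(h) is the
size of the supra-threshold spatiotemporal component containing p
(connectivity: spatial neighbors at the same sample, same vertex at
adjacent samples).  Defaults E = 0.5, H = 2, h0 = 0, dh = 0.4.  The
integral is a left-Riemann sum at h0 + k*dh with a final partial step up to
the map maximum; a single isolated point with t = 2.0 therefore enhances to
0.4*(0.4^2 + 0.8^2 + 1.2^2 + 1.6^2 + 2.0^2) = 3.52, which is frozen as a
unit test.  The implementation adds points in descending order into a
union-find forest (numba-compiled), which matches a brute-force
threshold-loop + flood-fill oracle to 1e-10 on small maps.

Inference: the one-sample test (test-minus-control differences) permutes by
sign-flipping whole-subject maps (exhaustive enumeration when 2^n does not
exceed the permutation budget); the two-sample test (group comparison of
differential responses) permutes group labels (exhaustive over label
assignments when feasible).  Hemispheres are enhanced disjointly, but each
permutation contributes a single max |TFCE| over both hemispheres, so the
family-wise error of the whole map is controlled at alpha = 0.05
(max-statistic correction; a pointwise null is available behind
`correction="pointwise"`).  Random-permutation p-values use
(1 + #{null >= obs}) / (n_perm + 1); ties count against rejection.  The
default budget is 5000 permutations ("full" profile) or 500 ("test"
profile).  Null calibration and deficit recovery are verified in
`tests/test_acceptance.py` at desk scale: 50 vertices per hemisphere,
125-250 Hz time grids, 500 permutations — sizes chosen so the full
calibration (200 null cohorts) and recovery (50 cohorts) complete on a
single CPU in minutes.

## Post-cluster SPN analysis

Within the largest significant cluster per hemisphere (never leaving
STG+), the "most significant" sources are those whose p-value averaged over
the cluster's full temporal extent is strictly below the cluster mean (ties
excluded, so a uniform-p cluster selects nothing).  Group-difference
timecourses at these sources are compared pointwise (two-sample t,
Benjamini-Hochberg across the 400 time samples).  Each source's onset/end
come from its *dominant* significant run: runs separated by <= 50 ms are
merged and the run with the largest summed |t| is kept.  Averaging first
and last significant samples across all runs — the naive reading — lets
single FDR false discoveries 100+ ms from the effect set the window
boundary; with smooth noise these are common enough to destroy the window
estimate, while the dominant-run rule recovers the injected 150-450 ms
window to within +/-30 ms.  The group-difference window is the mean onset
and mean end over sources.

**SPNadj** is the per-subject mean current over selected sources and window
for the test condition, with the control-condition magnitude and
sqrt(mean averaged-epoch count) regressed out by OLS; residuals are exactly
orthogonal to both regressors and invariant to adding any linear
combination of them.  The regression is fitted within the sample entering
the subsequent correlation (the ASD subsample), as in the study's n = 26
analysis.

## P3a-like detection

Traces (covering -200-800 ms) are zero-phase low-passed at 10 Hz
(4th-order Butterworth, forward-backward).  The candidate peak is the
largest local maximum in 200-400 ms; its amplitude is the peak minus the
mean of the nearest local minima before and after it (searched over
0-800 ms, falling back to the side minimum if no local minimum exists).
The peak is *present* only when both margins reach the pre-stimulus
baseline RMS; otherwise the amplitude is 0.  The baseline RMS is computed
about the baseline's own mean and **before** filtering: filtered-noise
excursions are ~2x the filtered RMS by construction, so a filtered-baseline
criterion would fire on pure noise most of the time, whereas the raw-noise
floor gives sensitivity 1.0 / false detection < 0.01 on constructed traces
while remaining permissive on smooth averaged timecourses (consistent with
the substantial control-condition detection rates the procedure yields on
real data).  Occurrence is compared by Pearson chi-square without
continuity correction; amplitudes by Mann-Whitney U (tie-corrected normal
Z, eta^2 = Z^2/N).

## Behavioral statistics

Word exclusion pools each word's accuracy over **all** its presentations and
drops words at or above 0.95 (ceiling) or at or below 0.05 (floor).  With
each word presented once per subject in a single cell, per-condition word
accuracies rest on ~n/8 observations and cannot be thresholded reliably;
pooled accuracy separates the built-in ceiling/floor words from the rest
with margin at cohort size.  WiNst/WiNam are percent correct averaged over
SNR 0/-3/-6 dB (the -9 dB level is scored but excluded).  Group
comparisons pass a Shapiro-Wilk gate (p < 0.05 on either sample selects
Mann-Whitney, else Student's t; the branch is recorded).  The
Group x noise-Type interaction uses a label-permutation test on AM-ST
difference scores (10 000 draws) — with two within-subject levels this is
the random-intercept interaction, replacing a mixed-model fit.  Partial
Pearson/Spearman correlations invert the joint correlation matrix (Spearman
rank-transforms first); p-values use t with n-2-k df.  Correlations are
compared by Fisher's Z for independent samples and Steiger's (1980) Z for
dependent overlapping correlations.  Multiple testing uses
Benjamini-Hochberg.

## Known limitations

* The source space is a topological surrogate; no forward/inverse modelling
  or anatomical claims.
* Noise is temporally smoothed Gaussian, independent across vertices; TFCE
  spillover into spatially correlated noise is therefore not exercised.
* The psychometric model has no lapse/guess rates.
* The exact membership of the 8-frequency non-vowel carrier sets and the
  supplementary word-exclusion criteria are not published; both are
  configurable defaults here.
* Presence/absence of the P3a-like peak on smooth averaged traces is
  intrinsically permissive (see above); only the constructed-trace
  operating characteristics are guaranteed.
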