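"""Synthetic two-group cohort of source-space auditory evoked responses.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without any recorded data:

* a cortical-mesh surrogate — one planar grid graph per hemisphere with
  contiguous auditory region patches (A1, A4, pINS) inside an "STG+" band;
* per-subject evoked source currents containing a positive P100m transient
  (~100 ms), a condition-dependent sustained negative shift (SPN, onset
  before 100 ms, several hundred ms long) confined to STG+, a group deficit
  term that erodes the SPN only in designated regions (A4, pINS) and a
  designated latency window for the formant-structure conditions in the ASD
  group, an optional left-hemisphere P3a-like positive bump near 300 ms,
  and temporally smoothed Gaussian noise whose SD scales as
  1/sqrt(n_epochs);
* words-in-noise behavior: Bernoulli word outcomes from a logistic
  psychometric function of SNR with an age benefit in both noise types and
  a latent-SPN penalty in amplitude-modulated noise only.

Each subject's latent deficit scalar is stored on the record so recovery
tests have ground truth; analysis operations never read it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "CONDITIONS",
    "SourceSpace",
    "EvokedSet",
    "SubjectRecord",
    "CohortConfig",
    "WinLinkConfig",
    "make_source_space",
    "simulate_evoked",
    "simulate_win_behavior",
    "records_to_frame",
]

#: Condition order used throughout; "control" is the non-periodic non-vowel.
CONDITIONS = ("periodic_vowel", "nonperiodic_vowel", "periodic_nonvowel", "control")


# ---------------------------------------------------------------------------
# source space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceSpace:
    """Cortical mesh surrogate: vertices, adjacency, hemisphere and region labels.

    Vertices 0..n_lh-1 are left-hemisphere, the rest right-hemisphere.
    ``region`` is one of {"A1", "A4", "pINS", "STG", "non"}; the STG+ mask is
    everything except "non".
    """

    hemi: np.ndarray          # (n,) "L"/"R"
    region: np.ndarray        # (n,) region labels
    edges: np.ndarray         # (E, 2) undirected vertex pairs, within hemisphere

    @property
    def n_vertices(self) -> int:
        return len(self.hemi)

    @property
    def stg_mask(self) -> np.ndarray:
        return self.region != "non"

    def hemi_mask(self, hemi: str) -> np.ndarray:
        return self.hemi == hemi

    def region_mask(self, *names: str) -> np.ndarray:
        return np.isin(self.region, names)

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric vertex adjacency (no cross-hemisphere edges)."""
        n = self.n_vertices
        if len(self.edges) == 0:
            return sparse.csr_matrix((n, n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * len(i))
        a = sparse.coo_matrix(
            (data, (np.r_[i, j], np.r_[j, i])), shape=(n, n)
        )
        a = a.tocsr()
        a.data[:] = 1.0
        return a


def _grid_dims(n: int) -> tuple[int, int]:
    rows = max(1, int(np.sqrt(n)))
    while n % rows:
        rows -= 1
    return rows, n // rows


def _hemi_labels(rows: int, cols: int) -> np.ndarray:
    """Region labels on one hemisphere grid: an STG+ band of middle rows with
    contiguous pINS / A1 / A4 column patches."""
    region = np.full((rows, cols), "non", dtype=object)
    r0, r1 = rows // 4, max(rows // 4 + 1, (3 * rows) // 4 + 1)
    band = slice(r0, r1)
    region[band, :] = "STG"

    def colrange(lo_frac, hi_frac):
        lo = int(np.floor(lo_frac * cols))
        hi = max(lo + 1, int(np.ceil(hi_frac * cols)))
        return slice(lo, min(hi, cols))

    region[band, colrange(0.00, 0.20)] = "pINS"
    region[band, colrange(0.35, 0.55)] = "A1"
    region[band, colrange(0.65, 0.90)] = "A4"
    return region.ravel()


def make_source_space(
    n_vertices_per_hemi: int,
    rng: np.random.Generator | None = None,
) -> SourceSpace:
    """Planar-grid source space: ``n_vertices_per_hemi`` per hemisphere.

    The grid is the largest rows x cols factorization near square.  Region
    patches are deterministic; ``rng`` is accepted for interface symmetry.
    """
    if n_vertices_per_hemi < 50:
        raise ValueError("need at least 50 vertices per hemisphere")
    rows, cols = _grid_dims(n_vertices_per_hemi)
    n = rows * cols
    labels = _hemi_labels(rows, cols)
    for name in ("A1", "A4", "pINS"):
        if not np.any(labels == name):
            raise ValueError(f"region {name} is empty on a {rows}x{cols} grid")

    # 4-connected grid edges within one hemisphere
    idx = np.arange(n).reshape(rows, cols)
    horiz = np.c_[idx[:, :-1].ravel(), idx[:, 1:].ravel()]
    vert = np.c_[idx[:-1, :].ravel(), idx[1:, :].ravel()]
    e = np.vstack([horiz, vert])

    hemi = np.array(["L"] * n + ["R"] * n)
    region = np.concatenate([labels, labels])
    edges = np.vstack([e, e + n])
    return SourceSpace(hemi=hemi, region=region, edges=edges)


# ---------------------------------------------------------------------------
# evoked data containers
# ---------------------------------------------------------------------------

@dataclass
class EvokedSet:
    """Per-subject, per-condition source current timecourses.

    ``data`` has shape (n_subjects, n_conditions, n_vertices, n_times) in
    arbitrary current units; ``times_ms`` is the common time axis.
    """

    data: np.ndarray
    conditions: tuple[str, ...]
    times_ms: np.ndarray
    n_epochs: np.ndarray      # (n_subjects, n_conditions) ints
    fs: float

    def condition_index(self, name: str) -> int:
        try:
            return self.conditions.index(name) if isinstance(
                self.conditions, list
            ) else tuple(self.conditions).index(name)
        except ValueError as err:
            raise KeyError(f"condition {name!r} not in {self.conditions}") from err

    def get(self, condition: str) -> np.ndarray:
        """(n_subjects, n_vertices, n_times) for one condition."""
        return self.data[:, self.condition_index(condition)]

    def copy(self) -> "EvokedSet":
        return EvokedSet(
            self.data.copy(), tuple(self.conditions), self.times_ms.copy(),
            self.n_epochs.copy(), self.fs,
        )


@dataclass
class SubjectRecord:
    """One subject: group membership, covariates, behavior, and the hidden
    generator truth (latent deficit scalar, injected P3a flags)."""

    subject: int
    group: str                # "TD" or "ASD"
    age: float
    iq: float
    n_epochs: dict[str, int] = field(default_factory=dict)
    latent_spn: float = 0.0   # hidden generator truth; analysis must not read
    p3a_truth: dict[str, bool] = field(default_factory=dict)
    win_responses: pd.DataFrame | None = None


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": [r.subject for r in records],
            "group": [r.group for r in records],
            "age": [r.age for r in records],
            "iq": [r.iq for r in records],
            "latent_spn": [r.latent_spn for r in records],
        }
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions of the simulated cohort.

    Amplitudes are in arbitrary source-current units; times in ms.  The SPN
    amplitude is the expected test-minus-control negativity at STG+ sources;
    the deficit coefficient is the expected erosion of that negativity (per
    unit of the subject's latent scalar) in the deficit regions/window for
    the formant-structure conditions in the ASD group.
    """

    n_td: int = 39
    n_asd: int = 35
    n_vertices_per_hemi: int = 100
    fs: float = 1000.0
    tmin_ms: float = -200.0
    tmax_ms: float = 1000.0
    age_range: tuple[float, float] = (6.9, 13.0)
    iq_td: tuple[float, float] = (116.2, 13.3)
    iq_asd: tuple[float, float] = (83.1, 15.8)
    n_epochs_range: tuple[int, int] = (140, 340)   # mean ~= 231 as in the study

    # P100m transient
    p100_amp: float = 1.0
    p100_latency_ms: float = 100.0
    p100_sigma_ms: float = 25.0
    p100_off_stg_gain: float = 0.25

    # sustained processing negativity (test-minus-control plateau)
    spn_amp: dict[str, float] = field(
        default_factory=lambda: {
            "periodic_vowel": 0.6,
            "nonperiodic_vowel": 0.5,
            "periodic_nonvowel": 0.4,
            "control": 0.0,
        }
    )
    spn_onset_ms: float = 80.0
    spn_rise_ms: float = 40.0
    spn_end_ms: float = 600.0
    spn_fall_ms: float = 100.0

    # ASD group deficit (erodes SPN; default comparable to the SPN amplitude,
    # i.e. the negativity is essentially abolished in the affected regions)
    deficit_amp: float = 0.5
    deficit_window_ms: tuple[float, float] = (150.0, 450.0)
    deficit_edge_ms: float = 20.0
    deficit_regions: tuple[str, ...] = ("A4", "pINS")
    deficit_conditions: tuple[str, ...] = ("periodic_vowel", "nonperiodic_vowel")
    latent_mean: float = 1.0
    latent_sd: float = 0.4

    # P3a-like bump (left hemisphere, ~300 ms)
    p3a_amp: float = 0.35
    p3a_latency_ms: float = 300.0
    p3a_sigma_ms: float = 40.0
    p3a_hemi: str = "L"
    p3a_conditions: tuple[str, ...] = ("periodic_vowel", "nonperiodic_vowel")
    #: presence probability per (group, condition); study-like prevalence
    p3a_presence: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("TD", "periodic_vowel"): 0.72,
            ("ASD", "periodic_vowel"): 0.94,
            ("TD", "nonperiodic_vowel"): 0.64,
            ("ASD", "nonperiodic_vowel"): 0.74,
        }
    )
    p3a_asd_scale: float = 1.6     # amplitude scaling, ASD periodic vowels

    # noise
    noise_sd: float = 4.0          # per-trace SD = noise_sd / sqrt(n_epochs)
    noise_smooth_ms: float = 20.0  # Gaussian temporal autocorrelation length
    scramble_polarity: bool = False

    def null(self) -> "CohortConfig":
        """Copy with every group/behavior link zeroed and equal SPN in all
        conditions: downstream statistics should be calibrated on this."""
        flat = {c: 0.0 for c in CONDITIONS}
        return replace(
            self,
            spn_amp=flat,
            deficit_amp=0.0,
            latent_mean=0.0,
            latent_sd=0.0,
            p3a_amp=0.0,
        )


@dataclass
class WinLinkConfig:
    """Psychometric model linking words-in-noise outcomes to SNR, age and the
    latent SPN deficit (amplitude-modulated noise only).

    The per-word probability of a correct repetition is
    sigmoid(slope * (snr_eff - word_threshold)) with
    snr_eff = snr + masking_release*[AM] + age_coef*(age-10)
              + spn_coef*latent*[AM].
    """

    n_words: int = 160
    n_easy: int = 10
    n_hard: int = 8
    slope_per_db: float = 0.35
    word_thr_mean_db: float = 0.0
    word_thr_sd_db: float = 1.5
    easy_thr_db: float = -25.0
    hard_thr_db: float = 25.0
    masking_release_db: float = 3.0
    age_coef_db_per_yr: float = 0.5
    age_center_yr: float = 10.0
    spn_coef_db: float = -2.5       # AM-only penalty per latent unit
    snr_levels_db: tuple[float, ...] = (0.0, -3.0, -6.0, -9.0)
    noise_types: tuple[str, ...] = ("ST", "AM")


# ---------------------------------------------------------------------------
# evoked simulation
# ---------------------------------------------------------------------------

def _plateau_profile(t: np.ndarray, onset: float, rise: float,
                     end: float, fall: float) -> np.ndarray:
    """0 before onset, raised-cosine rise, 1 plateau, raised-cosine fall."""
    p = np.zeros_like(t)
    up = (t >= onset) & (t < onset + rise)
    p[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - onset) / rise)) if rise > 0 else 1.0
    p[(t >= onset + rise) & (t <= end)] = 1.0
    down = (t > end) & (t < end + fall)
    if fall > 0:
        p[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - end) / fall))
    return p


def _gauss_profile(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def simulate_evoked(
    space: SourceSpace,
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> tuple[EvokedSet, list[SubjectRecord]]:
    """Simulate the cohort's evoked source currents and subject covariates."""
    if cfg.deficit_amp < 0 or cfg.p100_amp < 0 or cfg.p3a_amp < 0:
        raise ValueError("component amplitudes must be non-negative")
    n_subj = cfg.n_td + cfg.n_asd
    groups = ["TD"] * cfg.n_td + ["ASD"] * cfg.n_asd
    t = np.arange(cfg.tmin_ms, cfg.tmax_ms - 1e-9, 1000.0 / cfg.fs)
    n_time = len(t)
    n_vert = space.n_vertices
    n_cond = len(CONDITIONS)

    stg = space.stg_mask.astype(float)
    p100_gain = np.where(space.stg_mask, 1.0, cfg.p100_off_stg_gain)
    deficit_mask = space.region_mask(*cfg.deficit_regions).astype(float)
    p3a_mask = (space.hemi_mask(cfg.p3a_hemi) & space.stg_mask).astype(float)

    p100_t = _gauss_profile(t, cfg.p100_latency_ms, cfg.p100_sigma_ms)
    p100_t[t < 0] = 0.0
    spn_t = _plateau_profile(
        t, cfg.spn_onset_ms, cfg.spn_rise_ms, cfg.spn_end_ms, cfg.spn_fall_ms
    )
    w0, w1 = cfg.deficit_window_ms
    deficit_t = _plateau_profile(
        t, w0, cfg.deficit_edge_ms, w1 - cfg.deficit_edge_ms, cfg.deficit_edge_ms
    )
    p3a_t = _gauss_profile(t, cfg.p3a_latency_ms, cfg.p3a_sigma_ms)

    # covariates
    ages = rng.uniform(*cfg.age_range, n_subj)
    iqs = np.where(
        np.array(groups) == "TD",
        rng.normal(*cfg.iq_td, n_subj),
        rng.normal(*cfg.iq_asd, n_subj),
    )
    latents = np.array(
        [
            max(0.0, rng.normal(cfg.latent_mean, cfg.latent_sd))
            if g == "ASD" and (cfg.latent_sd > 0 or cfg.latent_mean > 0)
            else 0.0
            for g in groups
        ]
    )
    n_epochs = rng.integers(
        cfg.n_epochs_range[0], cfg.n_epochs_range[1] + 1, size=(n_subj, n_cond)
    )

    data = np.empty((n_subj, n_cond, n_vert, n_time))
    records: list[SubjectRecord] = []
    for s in range(n_subj):
        grp = groups[s]
        p3a_truth: dict[str, bool] = {}
        for ci, cond in enumerate(CONDITIONS):
            sig = np.outer(p100_gain * cfg.p100_amp, p100_t)
            sig -= cfg.spn_amp.get(cond, 0.0) * np.outer(stg, spn_t)
            if (
                grp == "ASD"
                and cond in cfg.deficit_conditions
                and cfg.deficit_amp > 0
            ):
                sig += cfg.deficit_amp * latents[s] * np.outer(deficit_mask, deficit_t)
            if cond in cfg.p3a_conditions and cfg.p3a_amp > 0:
                prob = cfg.p3a_presence.get((grp, cond), 0.0)
                present = bool(rng.random() < prob)
                p3a_truth[cond] = present
                if present:
                    amp = cfg.p3a_amp
                    if grp == "ASD" and cond == "periodic_vowel":
                        amp *= cfg.p3a_asd_scale
                    sig += amp * np.outer(p3a_mask, p3a_t)
            data[s, ci] = sig
        records.append(
            SubjectRecord(
                subject=s,
                group=grp,
                age=float(ages[s]),
                iq=float(iqs[s]),
                n_epochs={c: int(n_epochs[s, i]) for i, c in enumerate(CONDITIONS)},
                latent_spn=float(latents[s]),
                p3a_truth=p3a_truth,
            )
        )

    # temporally smoothed Gaussian noise, per-trace SD = noise_sd/sqrt(n_epochs)
    noise = rng.standard_normal(data.shape)
    sigma_samp = cfg.noise_smooth_ms / 1000.0 * cfg.fs
    if sigma_samp > 0:
        noise = gaussian_filter1d(noise, sigma_samp, axis=-1, mode="reflect")
        noise /= noise.std(axis=(-2, -1), keepdims=True)
    data += noise * (cfg.noise_sd / np.sqrt(n_epochs))[:, :, None, None]

    if cfg.scramble_polarity:
        flips = rng.choice([-1.0, 1.0], size=n_vert)
        data *= flips[None, None, :, None]

    ev = EvokedSet(
        data=data,
        conditions=CONDITIONS,
        times_ms=t,
        n_epochs=n_epochs,
        fs=cfg.fs,
    )
    return ev, records


# ---------------------------------------------------------------------------
# words-in-noise behavior
# ---------------------------------------------------------------------------

def make_word_inventory(link: WinLinkConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Word inventory with thresholds; a few words are made extreme so the
    standard exclusion criteria flag n_easy + n_hard of them."""
    thr = rng.normal(link.word_thr_mean_db, link.word_thr_sd_db, link.n_words)
    flag = np.array(["normal"] * link.n_words, dtype=object)
    extreme = rng.choice(link.n_words, link.n_easy + link.n_hard, replace=False)
    thr[extreme[: link.n_easy]] = link.easy_thr_db
    flag[extreme[: link.n_easy]] = "easy"
    thr[extreme[link.n_easy :]] = link.hard_thr_db
    flag[extreme[link.n_easy :]] = "hard"
    return pd.DataFrame({"word": np.arange(link.n_words), "thr_db": thr, "flag": flag})


def simulate_win_behavior(
    records: list[SubjectRecord],
    link: WinLinkConfig,
    rng: np.random.Generator,
    inventory: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw Bernoulli word outcomes for every subject; attaches a
    ``win_responses`` frame (word, snr_db, noise_type, correct) to each record
    and returns the word inventory used.

    Every subject hears each word exactly once, in one (SNR, noise type)
    cell; cells are balanced at n_words / (n_snr * n_types) words each.
    """
    if inventory is None:
        inventory = make_word_inventory(link, rng)
    conds = [(s, nt) for s in link.snr_levels_db for nt in link.noise_types]
    n_cells = len(conds)
    if link.n_words % n_cells:
        raise ValueError("n_words must be divisible by the number of cells")
    per_cell = link.n_words // n_cells

    thr = inventory["thr_db"].to_numpy()
    for rec in records:
        order = rng.permutation(link.n_words)
        rows = []
        for ci, (snr, nt) in enumerate(conds):
            words = order[ci * per_cell : (ci + 1) * per_cell]
            snr_eff = (
                snr
                + (link.masking_release_db if nt == "AM" else 0.0)
                + link.age_coef_db_per_yr * (rec.age - link.age_center_yr)
                + (link.spn_coef_db * rec.latent_spn if nt == "AM" else 0.0)
            )
            p = 1.0 / (1.0 + np.exp(-link.slope_per_db * (snr_eff - thr[words])))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            correct = rng.random(per_cell) < p
            for w, c in zip(words, correct):
                rows.append((int(w), snr, nt, bool(c)))
        rec.win_responses = pd.DataFrame(
            rows, columns=["word", "snr_db", "noise_type", "correct"]
        )
    return inventory
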