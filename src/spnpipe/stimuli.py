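"""Synthesis of the four vowel-like MEG stimulus classes and the
words-in-noise maskers.

The MEG stimuli are trains of damped sinusoids.  Four formant trains (one
per formant) are summed; in the *periodic* classes every pulse starts on an
exact 12 ms grid (f0 = 83.3 Hz), in the *non-periodic* classes each pulse
onset is jittered independently within +/-6 ms.  In the *vowel* classes the
carrier of every pulse within a formant train is fixed at that formant's
center frequency; in the *non-vowel* classes each pulse's carrier is drawn
uniformly from a per-formant set of eight frequencies spanning the formant
band, which destroys formant constancy while keeping the long-term spectrum
in the same bands.

The speech-in-noise maskers are stationary pink noise (power spectral
density falling 3 dB per octave) and the same noise amplitude-modulated at
10 Hz (sine modulator starting at 0 deg phase), 1 s long, leading the word
onset by 75 ms.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.signal import hilbert, welch

logger = logging.getLogger(__name__)

__all__ = [
    "StimClass",
    "StimulusSpec",
    "Waveform",
    "StimulusRender",
    "TrialSequence",
    "MaskerSpec",
    "VOWEL_FORMANTS",
    "FORMANT_BANDS",
    "default_nonvowel_carriers",
    "synth_damped_pulse",
    "synth_stimulus",
    "render_stimulus",
    "make_trial_sequence",
    "synth_masker",
    "mix_word_with_masker",
    "write_wav",
    "read_wav",
    "envelope_autocorrelation",
    "envelope_f0",
]


class StimClass(str, enum.Enum):
    """The four stimulus classes: periodicity x formant structure."""

    PERIODIC_VOWEL = "periodic_vowel"
    NONPERIODIC_VOWEL = "nonperiodic_vowel"
    PERIODIC_NONVOWEL = "periodic_nonvowel"
    NONPERIODIC_NONVOWEL = "nonperiodic_nonvowel"

    @property
    def is_periodic(self) -> bool:
        return self in (StimClass.PERIODIC_VOWEL, StimClass.PERIODIC_NONVOWEL)

    @property
    def is_vowel(self) -> bool:
        return self in (StimClass.PERIODIC_VOWEL, StimClass.NONPERIODIC_VOWEL)


#: First four formant center frequencies (Hz) for the five strong vowels,
#: adult-male values, each inside the randomization bands below.
VOWEL_FORMANTS: dict[str, tuple[float, float, float, float]] = {
    "a": (730.0, 1090.0, 2440.0, 3500.0),
    "e": (530.0, 1840.0, 2480.0, 3600.0),
    "i": (270.0, 2250.0, 2900.0, 3700.0),
    "o": (570.0, 850.0, 2410.0, 3400.0),
    "u": (300.0, 870.0, 2240.0, 3300.0),
}

#: Frequency band (Hz) per formant within which non-vowel carriers are drawn.
FORMANT_BANDS: tuple[tuple[float, float], ...] = (
    (270.0, 1300.0),
    (850.0, 2260.0),
    (1750.0, 3000.0),
    (3300.0, 5500.0),
)

#: Vowel used for each of the three variants of the vowel classes.
VARIANT_VOWELS: dict[str, tuple[str, str, str]] = {
    "periodic_vowel": ("a", "i", "o"),
    "nonperiodic_vowel": ("a", "u", "e"),
}


def default_nonvowel_carriers(n: int = 8) -> tuple[np.ndarray, ...]:
    """Per-formant candidate carrier sets for the non-vowel classes.

    ``n`` log-spaced frequencies spanning each formant band.
    """
    return tuple(np.geomspace(lo, hi, n) for lo, hi in FORMANT_BANDS)


@dataclass(frozen=True)
class Waveform:
    """A peak-normalized mono audio buffer."""

    samples: np.ndarray
    sample_rate: float

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.sample_rate

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate * 1000.0

    def normalized(self) -> "Waveform":
        peak = np.max(np.abs(self.samples))
        if peak == 0:
            return self
        return Waveform(self.samples / peak, self.sample_rate)


@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of one stimulus.

    ``f0`` fixes the 12 ms pulse period (1000/f0).  ``formant_centers`` are
    the per-formant carriers used for the vowel classes; non-vowel classes
    draw per-pulse carriers from ``nonvowel_carriers`` instead.
    """

    klass: StimClass
    vowel_id: str = "a"
    f0: float = 1000.0 / 12.0  # 83.33 Hz -> 12 ms period
    formant_centers: tuple[float, ...] = VOWEL_FORMANTS["a"]
    nonvowel_carriers: tuple[np.ndarray, ...] = field(
        default_factory=default_nonvowel_carriers
    )
    jitter_bound_ms: float = 6.0
    duration_ms: float = 812.0
    ramp_ms: float = 10.0
    pulse_len_ms: float = 12.0
    decay_half_life_ms: float = 3.0
    sample_rate: float = 44100.0

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.f0

    @classmethod
    def for_class(
        cls, klass: StimClass | str, variant: int = 0, **kwargs
    ) -> "StimulusSpec":
        """Spec for one of the three variants of a class (variant 0..2)."""
        klass = StimClass(klass)
        if klass.is_vowel:
            vowel = VARIANT_VOWELS[klass.value][variant % 3]
            return cls(
                klass=klass,
                vowel_id=vowel,
                formant_centers=VOWEL_FORMANTS[vowel],
                **kwargs,
            )
        return cls(klass=klass, vowel_id=f"v{variant % 3 + 1}", **kwargs)


@dataclass(frozen=True)
class StimulusRender:
    """A rendered stimulus plus its construction bookkeeping.

    ``onsets_ms[k]`` holds the realized pulse onsets of formant train k and
    ``grid_ms[k]`` the corresponding un-jittered 12 ms grid positions, so
    jitter bounds can be audited after the fact.  ``carriers_hz[k]`` holds
    the per-pulse carrier frequencies.
    """

    waveform: Waveform
    spec: StimulusSpec
    onsets_ms: tuple[np.ndarray, ...]
    grid_ms: tuple[np.ndarray, ...]
    carriers_hz: tuple[np.ndarray, ...]

    @property
    def onset_deviations_ms(self) -> np.ndarray:
        """All pulse-onset deviations from the periodic grid, flattened."""
        return np.concatenate(
            [on - g for on, g in zip(self.onsets_ms, self.grid_ms)]
        )


@dataclass(frozen=True)
class TrialSequence:
    """Randomized presentation order for the MEG session."""

    klass: list[str]
    variant: list[int]
    onset_ms: np.ndarray
    isi_ms: np.ndarray
    isi_range_ms: tuple[float, float]

    def __len__(self) -> int:
        return len(self.klass)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "trial": np.arange(len(self.klass)),
                "class": self.klass,
                "variant": self.variant,
                "onset_ms": self.onset_ms,
                "isi_ms": self.isi_ms,
            }
        )


@dataclass(frozen=True)
class MaskerSpec:
    """Masking-noise parameters for the words-in-noise test."""

    noise_type: str = "ST"  # "ST" stationary or "AM" amplitude-modulated
    am_rate: float = 10.0
    snr_db: float = 0.0
    duration_ms: float = 1000.0
    lead_ms: float = 75.0
    ramp_ms: float = 1.0
    sample_rate: float = 44100.0

    def __post_init__(self):
        if self.noise_type not in ("ST", "AM"):
            raise ValueError(f"noise_type must be 'ST' or 'AM', got {self.noise_type!r}")


# ---------------------------------------------------------------------------
# synthesis primitives
# ---------------------------------------------------------------------------

def synth_damped_pulse(
    carrier_hz: float,
    decay_half_life_ms: float,
    pulse_len_ms: float,
    sample_rate: float,
) -> Waveform:
    """One damped sinusoid: sin(2*pi*f*t) * 2**(-t/half_life).

    Phase is 0 at onset; the envelope halves every ``decay_half_life_ms``.
    """
    if carrier_hz >= sample_rate / 2:
        raise ValueError(
            f"carrier {carrier_hz:g} Hz is at or above Nyquist "
            f"({sample_rate / 2:g} Hz)"
        )
    if decay_half_life_ms <= 0:
        raise ValueError("decay_half_life_ms must be positive")
    n = int(round(pulse_len_ms / 1000.0 * sample_rate))
    t = np.arange(n) / sample_rate  # seconds, t=0 at onset
    samples = np.sin(2 * np.pi * carrier_hz * t) * 2.0 ** (
        -t * 1000.0 / decay_half_life_ms
    )
    return Waveform(samples, sample_rate)


def _raised_cosine_ramp(n_total: int, n_ramp: int) -> np.ndarray:
    env = np.ones(n_total)
    if n_ramp > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = r
        env[-n_ramp:] = r[::-1]
    return env


def render_stimulus(spec: StimulusSpec, rng: np.random.Generator) -> StimulusRender:
    """Render one stimulus and keep onset/carrier bookkeeping.

    Pulse onsets of non-periodic classes are i.i.d. uniform within
    +/-jitter_bound around the 12 ms grid, drawn separately per pulse and
    per formant; onsets falling outside the stimulus window are clipped to
    it (and logged).  Non-vowel classes draw each pulse's carrier uniformly
    from the per-formant candidate set.
    """
    fs = spec.sample_rate
    n_total = int(round(spec.duration_ms / 1000.0 * fs))
    period = spec.period_ms
    grid = np.arange(0.0, spec.duration_ms - 1e-9, period)

    out = np.zeros(n_total)
    all_onsets, all_grids, all_carriers = [], [], []
    n_clipped = 0
    for k in range(4):
        if spec.klass.is_periodic:
            onsets = grid.copy()
        else:
            jit = rng.uniform(-spec.jitter_bound_ms, spec.jitter_bound_ms, len(grid))
            onsets = grid + jit
            # onsets outside the stimulus window are clipped to it; pulses
            # running past the end are simply truncated below
            clipped = np.clip(onsets, 0.0, spec.duration_ms)
            n_clipped += int(np.sum(clipped != onsets))
            onsets = clipped
        if spec.klass.is_vowel:
            carriers = np.full(len(grid), spec.formant_centers[k])
        else:
            carriers = rng.choice(spec.nonvowel_carriers[k], size=len(grid))
        pulse_n = int(round(spec.pulse_len_ms / 1000.0 * fs))
        t = np.arange(pulse_n) / fs
        decay = 2.0 ** (-t * 1000.0 / spec.decay_half_life_ms)
        for onset, f in zip(onsets, carriers):
            i0 = int(round(onset / 1000.0 * fs))
            i1 = min(i0 + pulse_n, n_total)
            if i0 >= n_total:
                continue
            seg = np.sin(2 * np.pi * f * t[: i1 - i0]) * decay[: i1 - i0]
            out[i0:i1] += seg
        all_onsets.append(onsets)
        all_grids.append(grid.copy())
        all_carriers.append(carriers)
    if n_clipped:
        logger.debug("clipped %d jittered pulse onsets to stimulus window", n_clipped)

    n_ramp = int(round(spec.ramp_ms / 1000.0 * fs))
    out *= _raised_cosine_ramp(n_total, n_ramp)
    wf = Waveform(out, fs).normalized()
    return StimulusRender(
        waveform=wf,
        spec=spec,
        onsets_ms=tuple(all_onsets),
        grid_ms=tuple(all_grids),
        carriers_hz=tuple(all_carriers),
    )


def synth_stimulus(spec: StimulusSpec, rng: np.random.Generator) -> Waveform:
    """Render one stimulus (four summed formant pulse trains, 812 ms)."""
    return render_stimulus(spec, rng).waveform


def make_trial_sequence(
    rng: np.random.Generator,
    n_per_class: int = 270,
    n_variants: int = 3,
    isi_ms: tuple[float, float] = (500.0, 800.0),
    stim_duration_ms: float = 812.0,
) -> TrialSequence:
    """Shuffled trial list: n_per_class stimuli per class, variants balanced,
    ISIs i.i.d. uniform on ``isi_ms``."""
    if n_per_class % n_variants:
        raise ValueError(
            f"n_per_class={n_per_class} not divisible by n_variants={n_variants}"
        )
    per_variant = n_per_class // n_variants
    klasses, variants = [], []
    for kl in StimClass:
        for v in range(n_variants):
            klasses += [kl.value] * per_variant
            variants += [v] * per_variant
    order = rng.permutation(len(klasses))
    klasses = [klasses[i] for i in order]
    variants = [variants[i] for i in order]
    isis = rng.uniform(isi_ms[0], isi_ms[1], len(klasses))
    onsets = np.concatenate(([0.0], np.cumsum(stim_duration_ms + isis)[:-1]))
    return TrialSequence(klasses, variants, onsets, isis, isi_ms)


# ---------------------------------------------------------------------------
# maskers
# ---------------------------------------------------------------------------

def _pink_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian pink noise via spectral shaping: PSD ~ 1/f (-3 dB/octave)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    out = np.fft.irfft(spec * shape, n=n)
    return out / np.std(out)


def synth_masker(spec: MaskerSpec, rng: np.random.Generator) -> Waveform:
    """Unit-RMS pink-noise masker, optionally 10 Hz amplitude-modulated.

    The AM envelope is (1 + sin(2*pi*am_rate*t)) / 2, sine starting at 0 deg
    phase, interrupting the noise am_rate times per second.  Onset/offset are
    smoothed with ``ramp_ms`` raised-cosine flanks.  The returned samples
    have RMS 1; SNR scaling against a target word is applied when mixing.
    """
    fs = spec.sample_rate
    n = int(round(spec.duration_ms / 1000.0 * fs))
    noise = _pink_noise(n, fs, rng)
    if spec.noise_type == "AM":
        t = np.arange(n) / fs
        noise = noise * 0.5 * (1.0 + np.sin(2 * np.pi * spec.am_rate * t))
    noise *= _raised_cosine_ramp(n, int(round(spec.ramp_ms / 1000.0 * fs)))
    noise = noise / np.sqrt(np.mean(noise**2))
    return Waveform(noise, fs)


def mix_word_with_masker(
    word: Waveform, masker: MaskerSpec, rng: np.random.Generator
) -> Waveform:
    """Mix a word into its masker; the masker leads the word by 75 ms.

    The word level is fixed; the masker RMS is set to realize
    ``masker.snr_db`` against the word's RMS (SNR = word - masker, dB).
    """
    fs = masker.sample_rate
    if abs(word.sample_rate - fs) > 1e-9:
        raise ValueError("word and masker sample rates differ")
    if word.duration_ms > masker.duration_ms - masker.lead_ms:
        raise ValueError(
            f"word of {word.duration_ms:.0f} ms does not fit in the "
            f"{masker.duration_ms:.0f} ms masker with a {masker.lead_ms:.0f} ms lead"
        )
    noise = synth_masker(masker, rng)
    word_rms = np.sqrt(np.mean(word.samples**2))
    noise_rms = word_rms * 10.0 ** (-masker.snr_db / 20.0)
    mix = noise.samples * noise_rms
    i0 = int(round(masker.lead_ms / 1000.0 * fs))
    mix[i0 : i0 + len(word.samples)] += word.samples
    return Waveform(mix, fs)


# ---------------------------------------------------------------------------
# analysis helpers and WAV I/O
# ---------------------------------------------------------------------------

def envelope_autocorrelation(w: Waveform, max_lag_ms: float = 50.0):
    """Normalized autocorrelation of the (mean-removed) Hilbert envelope.

    Returns (lags_ms, r) with r[0] = 1.
    """
    env = np.abs(hilbert(w.samples))
    env = env - env.mean()
    n_lag = int(round(max_lag_ms / 1000.0 * w.sample_rate))
    denom = float(np.dot(env, env))
    r = np.array(
        [np.dot(env[: len(env) - k], env[k:]) / denom for k in range(n_lag + 1)]
    )
    lags = np.arange(n_lag + 1) / w.sample_rate * 1000.0
    return lags, r


def envelope_f0(w: Waveform, min_lag_ms: float = 4.0, max_lag_ms: float = 50.0) -> float:
    """f0 (Hz) from the first major envelope-autocorrelation peak.

    The peak lag is refined by parabolic interpolation of the
    autocorrelation around the sample maximum.
    """
    lags, r = envelope_autocorrelation(w, max_lag_ms)
    k0 = int(np.searchsorted(lags, min_lag_ms))
    k = k0 + int(np.argmax(r[k0:]))
    if 0 < k < len(r) - 1:
        a, b, c = r[k - 1], r[k], r[k + 1]
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
    else:
        delta = 0.0
    lag_s = (k + delta) / w.sample_rate
    return 1.0 / lag_s


def psd_slope(w: Waveform, f_lo: float = 100.0, f_hi: float = 5000.0) -> float:
    """Log-log slope of the Welch PSD between f_lo and f_hi (pink noise: -1)."""
    f, p = welch(w.samples, fs=w.sample_rate, nperseg=4096)
    m = (f >= f_lo) & (f <= f_hi) & (p > 0)
    return float(np.polyfit(np.log10(f[m]), np.log10(p[m]), 1)[0])


def write_wav(w: Waveform, path) -> None:
    """Write 16-bit PCM RIFF/WAVE (no dithering; bit-exact round trip)."""
    x = np.clip(w.samples, -1.0, 1.0)
    pcm = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(path, int(round(w.sample_rate)), pcm)


def read_wav(path) -> Waveform:
    """Read a 16-bit PCM WAV back into a float Waveform in [-1, 1]."""
    rate, pcm = wavfile.read(path)
    return Waveform(pcm.astype(float) / 32767.0, float(rate))
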