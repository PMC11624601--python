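"""Stimulus synthesis: damped pulses, the four stimulus classes, trial
sequences, maskers, mixing, and WAV round trips."""

import numpy as np
import pytest
from scipy.signal import hilbert, periodogram

from spnpipe.stimuli import (
    FORMANT_BANDS,
    MaskerSpec,
    StimClass,
    StimulusSpec,
    envelope_autocorrelation,
    envelope_f0,
    make_trial_sequence,
    mix_word_with_masker,
    read_wav,
    render_stimulus,
    synth_damped_pulse,
    synth_masker,
    synth_stimulus,
    write_wav,
    _raised_cosine_ramp,
)


class TestDampedPulse:
    def test_matches_closed_form(self):
        w = synth_damped_pulse(250.0, 3.0, 12.0, 44100.0)
        t = np.arange(len(w.samples)) / 44100.0
        expected = np.sin(2 * np.pi * 250.0 * t) * 2.0 ** (-t * 1000.0 / 3.0)
        np.testing.assert_allclose(w.samples, expected)
        assert w.samples[0] == 0.0  # sine at phase 0

    def test_envelope_half_life(self):
        w = synth_damped_pulse(5000.0, 3.0, 12.0, 44100.0)
        env = np.abs(hilbert(w.samples))
        i3 = int(round(0.003 * 44100))
        # analytic peak amplitude is 1.0 (Hilbert edge ripple excluded)
        assert env[i3] == pytest.approx(0.5, rel=0.07)

    def test_spectral_peak_at_carrier(self):
        # independent oracle: FFT argmax
        w = synth_damped_pulse(500.0, 6.0, 50.0, 44100.0)
        spec = np.abs(np.fft.rfft(w.samples, n=1 << 16))
        f = np.fft.rfftfreq(1 << 16, 1 / 44100.0)
        assert abs(f[np.argmax(spec)] - 500.0) < 44100.0 / (1 << 16) + 30.0

    def test_rejects_carrier_above_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            synth_damped_pulse(30000.0, 3.0, 12.0, 44100.0)


class TestStimulusClasses:
    def test_periodic_envelope_peak_at_12_ms(self, rng):
        w = synth_stimulus(StimulusSpec.for_class("periodic_vowel"), rng)
        lags, r = envelope_autocorrelation(w)
        k = np.argmin(np.abs(lags - 12.0))
        assert r[k - 2 : k + 3].max() >= 0.8
        assert envelope_f0(w) == pytest.approx(1000.0 / 12.0, abs=0.5)

    @pytest.mark.parametrize("variant", [0, 1, 2])
    def test_periodicity_beats_jitter_over_seeds(self, variant):
        # invariant holds across >= 20 seeds
        drops = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            wp = synth_stimulus(
                StimulusSpec.for_class("periodic_vowel", variant), rng
            )
            wn = synth_stimulus(
                StimulusSpec.for_class("nonperiodic_vowel", variant), rng
            )
            def peak(w):
                lags, r = envelope_autocorrelation(w)
                k = np.argmin(np.abs(lags - 12.0))
                return r[k - 4 : k + 5].max()
            drops.append(peak(wp) - peak(wn))
        assert np.all(np.asarray(drops) > 0)

    def test_jitter_bounded_by_6_ms(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            rend = render_stimulus(
                StimulusSpec.for_class("nonperiodic_nonvowel"), rng
            )
            assert np.abs(rend.onset_deviations_ms).max() <= 6.0

    def test_zero_jitter_degenerates_to_periodic(self, rng):
        spec_p = StimulusSpec.for_class("periodic_vowel", 0)
        spec_n = StimulusSpec.for_class("nonperiodic_vowel", 0)
        spec_n = StimulusSpec(
            klass=StimClass.NONPERIODIC_VOWEL,
            vowel_id=spec_p.vowel_id,
            formant_centers=spec_p.formant_centers,
            jitter_bound_ms=0.0,
        )
        wp = synth_stimulus(spec_p, np.random.default_rng(0))
        wn = synth_stimulus(spec_n, np.random.default_rng(0))
        np.testing.assert_allclose(wp.samples, wn.samples)

    def test_duration_and_normalization(self, rng):
        for klass in StimClass:
            w = synth_stimulus(StimulusSpec.for_class(klass), rng)
            assert w.duration_ms == pytest.approx(812.0, abs=0.1)
            assert np.abs(w.samples).max() <= 1.0 + 1e-12

    def test_vowel_formant_peaks_in_band(self, rng):
        spec = StimulusSpec.for_class("periodic_vowel", 0)
        w = synth_stimulus(spec, rng)
        spect = np.abs(np.fft.rfft(w.samples)) ** 2
        f = np.fft.rfftfreq(len(w.samples), 1 / w.sample_rate)
        for (lo, hi), center in zip(FORMANT_BANDS, spec.formant_centers):
            m = (f >= lo) & (f <= hi)
            peak = f[m][np.argmax(spect[m])]
            assert abs(peak - center) <= (hi - lo) / 2

    def test_nonvowel_carriers_stay_in_band(self, rng):
        rend = render_stimulus(StimulusSpec.for_class("periodic_nonvowel"), rng)
        for (lo, hi), carriers in zip(FORMANT_BANDS, rend.carriers_hz):
            assert carriers.min() >= lo and carriers.max() <= hi
            assert len(np.unique(carriers)) > 1  # carriers vary per pulse

    def test_determinism(self):
        spec = StimulusSpec.for_class("nonperiodic_nonvowel", 1)
        w1 = synth_stimulus(spec, np.random.default_rng(7))
        w2 = synth_stimulus(spec, np.random.default_rng(7))
        assert np.array_equal(w1.samples, w2.samples)

    def test_ramp_gain_monotone(self):
        env = _raised_cosine_ramp(1000, 100)
        assert np.all(np.diff(env[:100]) >= 0)
        assert np.all(np.diff(env[-100:]) <= 0)
        assert env[0] == 0.0


class TestTrialSequence:
    def test_default_counts(self, rng):
        seq = make_trial_sequence(rng)
        assert len(seq) == 1080
        import collections

        counts = collections.Counter(zip(seq.klass, seq.variant))
        assert all(v == 90 for v in counts.values())
        assert len(counts) == 12

    def test_minimal_counts(self, rng):
        seq = make_trial_sequence(rng, n_per_class=3, n_variants=3)
        counts = {}
        for k, v in zip(seq.klass, seq.variant):
            counts[(k, v)] = counts.get((k, v), 0) + 1
        assert all(v == 1 for v in counts.values())

    def test_indivisible_raises(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            make_trial_sequence(rng, n_per_class=10, n_variants=3)

    def test_isi_uniform_law(self):
        # oracle: uniform law on [500, 800] -> min/max bounds, mean 650
        rng = np.random.default_rng(0)
        isis = np.concatenate(
            [make_trial_sequence(rng).isi_ms for _ in range(10)]
        )
        assert isis.min() >= 500.0 and isis.max() <= 800.0
        mc_err = 3 * (300 / np.sqrt(12)) / np.sqrt(len(isis))
        assert abs(isis.mean() - 650.0) < mc_err


class TestMasker:
    def _slope(self, w):
        # independent oracle: periodogram + least squares in log-log
        f, p = periodogram(w.samples, fs=w.sample_rate)
        m = (f >= 100) & (f <= 5000)
        # average log-power in octave bins to stabilize the fit
        bins = np.geomspace(100, 5000, 18)
        fb, pb = [], []
        for lo, hi in zip(bins[:-1], bins[1:]):
            sel = (f >= lo) & (f < hi)
            if sel.any():
                fb.append(np.sqrt(lo * hi))
                pb.append(p[sel].mean())
        return np.polyfit(np.log10(fb), np.log10(pb), 1)[0]

    def test_pink_slope(self):
        slopes = [
            self._slope(synth_masker(MaskerSpec("ST"), np.random.default_rng(s)))
            for s in range(5)
        ]
        assert np.all(np.abs(np.array(slopes) + 1.0) < 0.15)

    def test_two_seeds_differ_same_slope(self):
        w1 = synth_masker(MaskerSpec("ST"), np.random.default_rng(1))
        w2 = synth_masker(MaskerSpec("ST"), np.random.default_rng(2))
        assert not np.array_equal(w1.samples, w2.samples)
        assert abs(self._slope(w1) - self._slope(w2)) < 0.3

    def test_am_envelope_peak_at_10_hz(self, rng):
        w = synth_masker(MaskerSpec("AM"), rng)
        env = np.abs(hilbert(w.samples))
        spec = np.abs(np.fft.rfft(env - env.mean()))
        f = np.fft.rfftfreq(len(env), 1 / w.sample_rate)
        assert f[np.argmax(spec)] == pytest.approx(10.0, abs=0.5)

    def test_unit_rms(self, rng):
        w = synth_masker(MaskerSpec("AM"), rng)
        assert np.sqrt(np.mean(w.samples**2)) == pytest.approx(1.0, abs=1e-9)


class TestMixing:
    def _word(self, dur_ms=600.0, fs=44100.0):
        t = np.arange(int(dur_ms / 1000 * fs)) / fs
        x = np.sin(2 * np.pi * 440 * t)
        from spnpipe.stimuli import Waveform

        return Waveform(x / np.sqrt(np.mean(x**2)), fs)

    def test_lead_is_masker_only(self):
        word = self._word()
        mix = mix_word_with_masker(word, MaskerSpec("ST", snr_db=0.0),
                                   np.random.default_rng(3))
        ref = synth_masker(MaskerSpec("ST", snr_db=0.0),
                           np.random.default_rng(3))
        n_lead = int(round(0.075 * 44100))
        np.testing.assert_allclose(mix.samples[:n_lead], ref.samples[:n_lead])

    def test_high_snr_is_word(self):
        word = self._word()
        mix = mix_word_with_masker(word, MaskerSpec("ST", snr_db=60.0),
                                   np.random.default_rng(3))
        i0 = int(round(0.075 * 44100))
        seg = mix.samples[i0 : i0 + len(word.samples)]
        assert np.corrcoef(seg, word.samples)[0, 1] > 0.99

    @pytest.mark.parametrize("snr", [0.0, -3.0, -6.0, -9.0])
    def test_realized_snr(self, snr):
        # RMS oracle: masker = mixture minus embedded word
        word = self._word()
        mix = mix_word_with_masker(word, MaskerSpec("AM", snr_db=snr),
                                   np.random.default_rng(5))
        padded = np.zeros(len(mix.samples))
        i0 = int(round(0.075 * 44100))
        padded[i0 : i0 + len(word.samples)] = word.samples
        masker = mix.samples - padded
        ratio = 20 * np.log10(
            np.sqrt(np.mean(word.samples**2)) / np.sqrt(np.mean(masker**2))
        )
        assert abs(ratio - snr) < 0.5

    def test_word_too_long_raises(self):
        with pytest.raises(ValueError, match="fit"):
            mix_word_with_masker(self._word(950.0), MaskerSpec("ST"),
                                 np.random.default_rng(0))


class TestWav:
    def test_round_trip(self, tmp_path, rng):
        w = synth_stimulus(StimulusSpec.for_class("periodic_vowel"), rng)
        p = tmp_path / "s.wav"
        write_wav(w, p)
        back = read_wav(p)
        assert back.sample_rate == w.sample_rate
        assert len(back.samples) == len(w.samples)
        assert np.abs(back.samples - w.samples).max() <= 1.0 / 32767.0
        # second pass is bit-exact: samples are already on the 16-bit grid
        p2 = tmp_path / "s2.wav"
        write_wav(back, p2)
        again = read_wav(p2)
        assert np.array_equal(again.samples, back.samples)
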