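"""Filtering, resampling, re-referencing and analytic-signal extraction."""

import numpy as np
import pytest
from oracles import dpli_loop, fft_hilbert

from dirconn.connectivity import dpli
from dirconn.preprocess import (
    AnalyticSeries,
    analytic,
    bandpass,
    bandpass_gain,
    concatenate_clean,
    preprocess_trials,
    rereference_common_average,
    resample,
    split_clean,
    wrap_phase,
)

FS = 500.0
THETA = (7.0, 10.0)


def _sine(freq, fs, dur, phase=0.0):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t + phase)


class TestBandpass:
    def test_passband_zero_phase_and_gain(self):
        """An in-band sine passes with near-unit gain and no phase shift."""
        x = _sine(8.5, FS, 10.0)
        y = bandpass(x[:, None], FS, THETA)[:, 0]
        interior = slice(500, -500)
        # zero-phase: cross-correlation peaks at zero lag
        lags = np.arange(-20, 21)
        xc = [np.dot(x[interior], np.roll(y, k)[interior]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0
        gain = y[interior].std() / x[interior].std()
        assert 0.9 <= gain <= 1.0 + 1e-3

    def test_stopband_attenuation_matches_squared_magnitude_response(self):
        """Out-of-band attenuation follows the squared Butterworth
        magnitude (forward-backward application).  Measured deep in the
        interior, where the narrowband turn-on transient has decayed."""
        x = _sine(40.0, FS, 20.0)
        y = bandpass(x[:, None], FS, THETA)[:, 0]
        predicted = bandpass_gain(40.0, FS, THETA)
        interior = slice(4000, 6000)  # 8 s from either edge
        measured = y[interior].std() / x[interior].std()
        assert measured <= predicted * 1.1 + 1e-12

    def test_dc_rejected(self):
        y = bandpass(np.ones((2000, 1)), FS, THETA)
        assert np.max(np.abs(y[200:-200])) < 1e-6

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros((100, 1)), FS, (30.0, 300.0))


class TestResample:
    def test_length_scaling_5000_to_500(self):
        x = np.zeros(50_000)  # 10 s at 5000 Hz
        y = resample(x, 5000.0, 500.0)
        assert y.shape[0] == 5000

    def test_spectral_peak_preserved(self):
        x = _sine(8.0, 5000.0, 10.0)
        y = resample(x, 5000.0, 500.0)
        freqs = np.fft.rfftfreq(len(y), 1 / 500.0)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(y)))]
        assert peak == pytest.approx(8.0, abs=0.1)

    def test_high_frequencies_do_not_alias(self):
        """A 300 Hz tone must not fold to 200 Hz after 5000->500 Hz."""
        x = _sine(300.0, 5000.0, 10.0)
        y = resample(x, 5000.0, 500.0)
        spec = np.abs(np.fft.rfft(y)) / len(y)
        freqs = np.fft.rfftfreq(len(y), 1 / 500.0)
        alias_band = (freqs > 195) & (freqs < 205)
        assert spec[alias_band].max() < 0.01 * 0.5  # < 1% of tone amplitude

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample(np.zeros(100), 500.0, 1000.0)


class TestCommonAverage:
    def test_two_channel_example(self):
        out = rereference_common_average(np.array([[1.0, 3.0]]))
        assert np.allclose(out, [[-1.0, 1.0]])

    def test_idempotent_on_zero_mean_data(self, rng):
        x = rng.standard_normal((100, 4))
        x -= x.mean(axis=1, keepdims=True)
        assert np.allclose(rereference_common_average(x), x)

    def test_channel_mean_zero_after(self, rng):
        x = rng.standard_normal((100, 4))
        out = rereference_common_average(x)
        assert np.allclose(out.mean(axis=1), 0.0, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            rereference_common_average(np.zeros((100, 1)))


class TestAnalytic:
    def test_cosine_amplitude_and_phase_rate(self):
        t = np.arange(5000) / FS
        x = np.cos(2 * np.pi * 8.0 * t)
        series = analytic(x, FS, THETA)
        assert np.allclose(series.amplitude, 1.0, atol=0.02)
        dphi = wrap_phase(np.diff(series.phase, axis=0))
        assert np.allclose(dphi, 2 * np.pi * 8.0 / FS, atol=1e-3)

    def test_envelope_recovery_of_am_carrier(self):
        t = np.arange(5000) / FS
        env = 1.0 + 0.5 * np.sin(2 * np.pi * 1.0 * t)
        x = env * np.cos(2 * np.pi * 40.0 * t)
        series = analytic(x, FS, (30.0, 80.0), trim_samples=100)
        expected = env[100:-100]
        assert np.allclose(series.amplitude.ravel(), expected, atol=0.05)

    def test_phase_matches_fft_hilbert_oracle(self, rng):
        x = bandpass(rng.standard_normal((4000, 1)), FS, THETA)[:, 0]
        series = analytic(x, FS, THETA, trim_samples=0)
        z = fft_hilbert(x)
        oracle_phase = np.arctan2(z.imag, z.real)
        assert np.allclose(series.phase.ravel(), oracle_phase, atol=1e-10)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            analytic(np.zeros(50), FS, THETA)  # < 3 cycles of 7 Hz

    def test_amplitude_scaling_phase_invariance(self, rng):
        x = bandpass(rng.standard_normal((3000, 1)), FS, THETA)[:, 0]
        s1 = analytic(x, FS, THETA)
        s2 = analytic(3.5 * x, FS, THETA)
        assert np.allclose(s2.amplitude, 3.5 * s1.amplitude)
        assert np.allclose(s2.phase, s1.phase)


class TestArtifactHandling:
    def test_concatenated_length_is_additive(self):
        a = AnalyticSeries(np.zeros(100), np.ones(100), FS, THETA)
        b = AnalyticSeries(np.zeros(200), np.ones(200), FS, THETA)
        assert concatenate_clean([a, b]).n_samples == 300

    def test_fully_artifactual_trial_contributes_nothing(self):
        segs = split_clean(np.zeros((1000, 2)), FS, [(0.0, 2.0)])
        assert segs == []

    def test_zero_retained_samples_rejected(self):
        with pytest.raises(ValueError):
            concatenate_clean([])

    def test_split_excises_marked_interval(self):
        segs = split_clean(np.arange(1000.0), FS, [(0.5, 1.0)])
        assert len(segs) == 2
        assert len(segs[0]) == 250 and len(segs[1]) == 500

    def test_dpli_on_concatenation_equals_pooled_oracle(self, rng):
        """dPLI of concatenated clean segments equals the Heaviside-sum
        oracle run on the pooled phase arrays."""
        segments = []
        for _ in range(3):
            x = bandpass(rng.standard_normal((2000, 2)), FS, THETA)
            segments.append(analytic(x, FS, THETA))
        pooled = concatenate_clean(segments)
        val = dpli(pooled.phase[:, 0], pooled.phase[:, 1])
        expected = dpli_loop(pooled.phase[:, 0], pooled.phase[:, 1])
        assert val == pytest.approx(expected, abs=1e-12)

    def test_preprocess_trials_skips_bad_spans(self, rng):
        trials = [rng.standard_normal((2000, 2)) for _ in range(2)]
        arts = [[(0.0, 4.0)], []]  # first trial fully artifactual
        series = preprocess_trials(trials, FS, THETA, arts)
        clean = preprocess_trials(trials[1:], FS, THETA)
        assert series.n_samples == clean.n_samples


def test_wrap_phase_range(rng):
    x = rng.uniform(-20, 20, size=1000)
    w = wrap_phase(x)
    assert np.all(w > -np.pi) and np.all(w <= np.pi)
    assert np.allclose(np.cos(w), np.cos(x)) and np.allclose(np.sin(w), np.sin(x))


class TestBrainVisionReader:
    @staticmethod
    def _write_triplet(d, data, fs):
        ch, n = data.shape
        (d / "rec.eeg").write_bytes(data.T.reshape(-1).astype("<f4").tobytes())
        chans = "\n".join(f"Ch{i+1}=E{i+1},,1,uV" for i in range(ch))
        (d / "rec.vhdr").write_text(
            "Brain Vision Data Exchange Header File Version 1.0\n\n"
            "[Common Infos]\nDataFile=rec.eeg\nMarkerFile=rec.vmrk\n"
            "DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n"
            f"NumberOfChannels={ch}\nSamplingInterval={1e6 / fs:.0f}\n\n"
            "[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n\n"
            f"[Channel Infos]\n{chans}\n"
        )
        (d / "rec.vmrk").write_text(
            "Brain Vision Data Exchange Marker File, Version 1.0\n\n"
            "[Common Infos]\nDataFile=rec.eeg\n\n"
            "[Marker Infos]\nMk1=New Segment,,1,1,0\n"
        )

    def test_reads_generated_triplet(self, tmp_path, rng):
        pytest.importorskip("mne")
        from dirconn.preprocess import read_brainvision

        data = rng.standard_normal((3, 500)).astype("<f4")
        self._write_triplet(tmp_path, data, 500.0)
        arr, fs, labels = read_brainvision(str(tmp_path / "rec.vhdr"))
        assert fs == 500.0
        assert labels == ["E1", "E2", "E3"]
        # MNE returns volts; the header declares microvolt units
        assert np.allclose(arr * 1e6, data.T, atol=1e-5)
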