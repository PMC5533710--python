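import numpy as np
import pytest
from scipy import signal as sg

from gyrocg import (FilterSpec, PreprocessConfig, Recording,
                    butterworth_bandpass, fft_bandpass, preprocess_recording)

FS = 800.0


def _steady_amplitude(y, fs):
    mid = y[int(2 * fs):-int(2 * fs)]
    return np.max(np.abs(mid))


def _lockin_amplitude(y, fs, freq, lo_s, hi_s):
    """Amplitude of the ``freq`` component over [lo_s, hi_s] seconds,
    by complex demodulation — immune to residual broadband transients."""
    seg = y[int(lo_s * fs):int(hi_s * fs)]
    t = np.arange(int(lo_s * fs), int(hi_s * fs)) / fs
    return 2 * np.abs(np.mean(seg * np.exp(-2j * np.pi * freq * t)))


class TestButterworth:
    spec = FilterSpec("butterworth_bandpass", 1.0, 20.0, 4, True)

    def test_passband_center_gain(self):
        t = np.arange(int(6 * FS)) / FS
        y = butterworth_bandpass(np.sin(2 * np.pi * 10 * t), FS, self.spec)
        assert _steady_amplitude(y, FS) == pytest.approx(1.0, abs=0.02)

    def test_dc_rejection(self):
        y = butterworth_bandpass(np.full(int(6 * FS), 5.0), FS, self.spec)
        assert abs(np.mean(y)) < 1e-3 * 5.0

    @pytest.mark.parametrize("zero_phase", [False, True])
    def test_stopband_attenuation_matches_analytic_magnitude(self, zero_phase):
        # Analytic oracle: the designed transfer function evaluated at
        # 100 Hz; the forward-backward pass squares the magnitude.
        spec = FilterSpec("butterworth_bandpass", 1.0, 20.0, 4, zero_phase)
        t = np.arange(int(8 * FS)) / FS
        y = butterworth_bandpass(np.sin(2 * np.pi * 100 * t), FS, spec)
        sos = sg.butter(4, [1.0, 20.0], btype="bandpass", output="sos", fs=FS)
        _, h = sg.sosfreqz(sos, worN=[100.0], fs=FS)
        expected = np.abs(h[0]) ** (2 if zero_phase else 1)
        measured = _lockin_amplitude(y, FS, 100.0, 4.0, 7.0)
        assert measured == pytest.approx(expected, rel=0.05)

    def test_zero_phase_preserves_gaussian_extremum(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.exp(-0.5 * ((t - 2.0) / 0.015) ** 2)
        y = butterworth_bandpass(x, FS, self.spec)
        assert np.argmax(y) == np.argmax(x)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=4000)
        x2 = rng.normal(size=4000)
        f = lambda v: butterworth_bandpass(v, FS, self.spec)
        np.testing.assert_allclose(f(2.5 * x1 - 0.7 * x2),
                                   2.5 * f(x1) - 0.7 * f(x2), atol=1e-9)

    def test_band_edge_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            butterworth_bandpass(np.zeros(1000), FS,
                                 FilterSpec("butterworth_bandpass", 1, 500, 4))


class TestFftBandpass:
    def test_stopband_60hz(self):
        t = np.arange(int(6 * FS)) / FS
        x = np.sin(2 * np.pi * 60 * t)
        y = fft_bandpass(x, FS, 0.5, 45.0)
        assert np.sqrt(np.mean(y ** 2)) < 0.01 * np.sqrt(np.mean(x ** 2))

    def test_passband_10hz(self):
        t = np.arange(int(6 * FS)) / FS
        x = np.sin(2 * np.pi * 10 * t)
        y = fft_bandpass(x, FS, 0.5, 45.0)
        assert np.sqrt(np.mean(y ** 2)) == pytest.approx(
            np.sqrt(np.mean(x ** 2)), rel=0.02)

    def test_tone_gains_match_mask_oracle(self):
        # Direct-DFT oracle: an integer-cycle tone occupies one DFT bin,
        # so its gain equals the raised-cosine mask at its frequency.
        low, high, w = 0.5, 45.0, 0.1

        def mask(f):
            if f < low * (1 - w) or f > high * (1 + w):
                return 0.0
            if f < low * (1 + w):
                u = (f - low * (1 - w)) / (2 * w * low)
                return 0.5 * (1 - np.cos(np.pi * u))
            if f > high * (1 - w):
                u = (f - high * (1 - w)) / (2 * w * high)
                return 1 - 0.5 * (1 - np.cos(np.pi * u))
            return 1.0

        t = np.arange(int(5 * FS)) / FS  # 5 s -> f*5 cycles, all integer
        for f in (0.4, 2.0, 20.0, 43.0, 46.0, 60.0):
            x = np.sin(2 * np.pi * f * t)
            y = fft_bandpass(x, FS, low, high)
            gain = np.sqrt(np.mean(y ** 2) / np.mean(x ** 2))
            assert gain == pytest.approx(mask(f), abs=0.01)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            fft_bandpass(np.zeros(100), FS, 45.0, 0.5)


class TestPreprocessRecording:
    def test_all_zero_in_all_zero_out(self):
        n = 4000
        rec = Recording(fs=FS, ecg=np.zeros(n), gyro_x=np.zeros(n),
                        gyro_y=np.zeros(n), gyro_z=np.zeros(n))
        out = preprocess_recording(rec)
        for ch in out.channels().values():
            np.testing.assert_allclose(ch, 0.0, atol=1e-12)

    def test_gyro_only_recording_accepted(self, clean_sim):
        rec, _ = clean_sim
        slim = Recording(fs=rec.fs, ecg=rec.ecg, gyro_x=rec.gyro_x,
                         gyro_y=rec.gyro_y, gyro_z=rec.gyro_z)
        out = preprocess_recording(slim)
        assert out.acc_x is None

    def test_g_j_peak_shift_under_filtering(self, clean_sim):
        # Zero-phase chain: the dominant y peak moves <= 2 samples.
        rec, gt = clean_sim
        out = preprocess_recording(rec)
        i = int(round(gt.t_ao[5] * rec.fs))
        w = slice(i - 40, i + 40)
        shift = np.argmax(out.gyro_y[w]) - np.argmax(rec.gyro_y[w])
        assert abs(shift) <= 2

    def test_config_overrides(self, clean_sim):
        rec, _ = clean_sim
        cfg = PreprocessConfig(
            gyro=FilterSpec("butterworth_bandpass", 2.0, 30.0, 2, True))
        out = preprocess_recording(rec, cfg)
        assert out.n == rec.n
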