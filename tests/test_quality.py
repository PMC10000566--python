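import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ppgrr.quality import (
    resample_4hz,
    rqi_autocorrelation,
    rqi_autoregression,
    rqi_fft,
    skewness,
    sqi_mean,
)


def _wave4(freq, duration=32.0, amplitude=1.0):
    t = np.arange(int(duration * 4)) / 4.0
    return amplitude * np.sin(2 * np.pi * freq * t)


class TestSkewness:
    def test_symmetric_input_is_zero(self):
        assert skewness(np.array([1.0, 2.0, 3.0])) == pytest.approx(0.0)

    def test_constant_input_convention(self):
        assert skewness(np.full(10, 7.0)) == 0.0

    def test_hand_computed_value(self):
        # [0,0,0,1]: mean 1/4, population sd sqrt(3)/4 -> 2/sqrt(3)
        assert skewness(np.array([0.0, 0.0, 0.0, 1.0])) == pytest.approx(
            2.0 / np.sqrt(3.0), abs=1e-12
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            skewness(np.array([1.0, 2.0]))

    @given(
        x=arrays(np.float64, st.integers(5, 40),
                 elements=st.floats(-50, 50)),
        a=st.floats(0.1, 10.0),
        b=st.floats(-5.0, 5.0),
    )
    def test_affine_invariance_and_antisymmetry(self, x, a, b):
        assume(np.std(x) > 1e-3)  # avoid near-constant float cancellation
        s = skewness(x)
        assert skewness(a * x + b) == pytest.approx(s, abs=1e-6)
        assert skewness(-x) == pytest.approx(-s, abs=1e-6)


class TestSqiMean:
    def test_sixteen_subwindows_for_32s(self):
        # binary subwindow with 62 of 250 samples high: closed-form
        # skewness (1-2p)/sqrt(p(1-p)); every 2-s subwindow identical,
        # so the mean over the 16 subwindows equals that value
        fs = 125.0
        sub = np.zeros(250)
        sub[:62] = 1.0
        x = np.tile(sub, 16)
        assert x.size == int(32 * fs)
        p = 62 / 250
        expected = (1 - 2 * p) / np.sqrt(p * (1 - p))
        assert sqi_mean(x, fs) == pytest.approx(expected, abs=1e-9)

    def test_alternating_subwindow_skewness_cancels(self):
        fs = 2.0  # 2-s subwindow = 4 samples
        pos = np.array([0.0, 0.0, 0.0, 1.0])  # skewness +2/sqrt(3)
        neg = 1.0 - pos  # mirrored: -2/sqrt(3)
        x = np.concatenate([pos, neg] * 8)
        assert sqi_mean(x, fs) == pytest.approx(0.0, abs=1e-12)

    def test_window_shorter_than_subwindow_rejected(self):
        with pytest.raises(ValueError):
            sqi_mean(np.ones(100), fs=125.0)


class TestResample4hz:
    def test_output_length(self):
        out = resample_4hz(np.random.default_rng(0).normal(size=4000), 125.0)
        assert out.size == 128

    def test_identity_at_4hz(self):
        x = np.arange(64.0)
        np.testing.assert_array_equal(resample_4hz(x, 4.0), x)

    def test_respiratory_tone_survives(self):
        fs = 125.0
        t = np.arange(int(32 * fs)) / fs
        x = np.sin(2 * np.pi * 0.25 * t)
        out = resample_4hz(x, fs)
        ratio = (np.max(out) - np.min(out)) / (np.max(x) - np.min(x))
        assert ratio >= 0.99

    def test_rate_below_4hz_rejected(self):
        with pytest.raises(ValueError):
            resample_4hz(np.ones(100), 2.0)


class TestRqis:
    def test_periodic_wave_scores_high_qr1(self):
        assert rqi_autocorrelation(_wave4(0.25)) >= 0.97

    def test_white_noise_scores_low_qr1(self):
        x = np.random.default_rng(3).normal(size=128)
        assert rqi_autocorrelation(x) < 0.5

    def test_zero_signal_guards(self):
        z = np.zeros(128)
        assert rqi_autocorrelation(z) == 0.0
        assert rqi_fft(z) == 0.0
        assert rqi_autoregression(z) == 0.0

    def test_pure_tone_concentrates_spectrum(self):
        assert rqi_fft(_wave4(0.25)) >= 0.95

    def test_split_spectrum_halves_qr2(self):
        x = _wave4(0.15) + _wave4(0.45)
        assert rqi_fft(x) == pytest.approx(0.5, abs=0.1)

    def test_pure_tone_pole_near_unit_circle(self):
        assert rqi_autoregression(_wave4(0.25)) >= 0.97

    def test_white_noise_pole_weaker(self):
        x = np.random.default_rng(4).normal(size=128)
        assert rqi_autoregression(x) < 0.9

    @pytest.mark.parametrize("scale", [0.1, 1.0, 25.0])
    def test_amplitude_invariance(self, scale):
        base = _wave4(0.2) + 0.2 * np.random.default_rng(5).normal(size=128)
        for fn in (rqi_autocorrelation, rqi_fft, rqi_autoregression):
            assert fn(scale * base) == pytest.approx(fn(base), abs=1e-8)

    def test_added_noise_degrades_every_rqi(self):
        clean = _wave4(0.25)
        noisy = clean + np.random.default_rng(6).normal(
            0, np.std(clean), clean.size
        )
        for fn in (rqi_autocorrelation, rqi_fft, rqi_autoregression):
            assert fn(noisy) < fn(clean)

    def test_rqis_bounded(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.normal(size=140)
            for fn in (rqi_autocorrelation, rqi_fft, rqi_autoregression):
                assert 0.0 <= fn(x) <= 1.0
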