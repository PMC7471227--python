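"""Spectral estimation (Welch, Morlet CWT) and band-power accumulation."""

import numpy as np
import pytest
import pywt
from hypothesis import given
from hypothesis import strategies as st

from mitopo.features import (BETA_LOW, MU, Band, ContributionTensor, CWTConfig,
                             SCENARIO_BANDS, SpectralVector, WelchConfig,
                             band_power, contribution_tensor, cwt_power,
                             morlet_cwt, welch_psd)
from mitopo.preprocess import TrialEpoch

FS = 250.0


def _tone(freq, seconds=2.0, fs=FS, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestWelch:
    def test_white_noise_spectrum_is_flat_in_band(self):
        rng = np.random.default_rng(7)
        spec = welch_psd(rng.standard_normal(2560), WelchConfig(fs=FS))
        in_band = (spec.freqs >= 8) & (spec.freqs <= 30)
        assert spec.values[in_band].max() / spec.values[in_band].min() < 3.0

    def test_tone_peak_within_one_bin(self):
        spec = welch_psd(_tone(10.0, seconds=4.0), WelchConfig(fs=FS))
        df = spec.freqs[1] - spec.freqs[0]
        assert abs(spec.freqs[np.argmax(spec.values)] - 10.0) <= df

    def test_zero_signal_zero_spectrum(self):
        spec = welch_psd(np.zeros(500), WelchConfig(fs=FS))
        assert np.all(spec.values == 0.0)

    def test_signal_shorter_than_segment_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), WelchConfig(fs=FS))

    def test_total_power_approximates_variance(self):
        # Parseval-style sanity on band-limited noise
        rng = np.random.default_rng(3)
        x = rng.standard_normal(5000)
        spec = welch_psd(x, WelchConfig(fs=FS))
        total = np.trapezoid(spec.values, spec.freqs)
        assert abs(total - x.var()) / x.var() < 0.10


class TestMorletCWT:
    def test_tone_peak_frequency_within_one_grid_step(self):
        cfg = CWTConfig(fs=FS)
        power = cwt_power(morlet_cwt(_tone(10.0), cfg), cfg)
        peak = cfg.freqs[np.argmax(power.values)]
        step = np.max(np.diff(cfg.freqs))
        assert abs(peak - 10.0) <= step

    def test_linearity(self):
        cfg = CWTConfig(fs=FS)
        x = _tone(12.0) + 0.3 * _tone(22.0)
        np.testing.assert_allclose(morlet_cwt(3.0 * x, cfg),
                                   3.0 * morlet_cwt(x, cfg), atol=1e-10)

    def test_time_shift_shifts_coefficients(self):
        cfg = CWTConfig(fs=FS)
        rng = np.random.default_rng(5)
        x = rng.standard_normal(800)
        shift = 50
        a = morlet_cwt(x, cfg)[:, 300:500]
        b = morlet_cwt(np.roll(x, shift), cfg)[:, 300 + shift:500 + shift]
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            morlet_cwt(np.array([]), CWTConfig(fs=FS))

    def test_agrees_with_pywt_reference(self):
        # independent oracle: pywt's own cwt on the same scales
        cfg = CWTConfig(fs=FS)
        x = _tone(10.0)
        mine = np.abs(morlet_cwt(x, cfg))
        scales = pywt.frequency2scale(cfg.wavelet, cfg.freqs / FS)
        ref, _ = pywt.cwt(x, scales, cfg.wavelet, sampling_period=1 / FS)
        for i in range(cfg.n_freqs):
            r = np.corrcoef(np.abs(ref[i]), mine[i])[0, 1]
            assert r > 0.99

    def test_cwt_power_of_zero_and_constant_coeffs(self):
        cfg = CWTConfig(fs=FS)
        zeros = np.zeros((cfg.n_freqs, 100), dtype=complex)
        assert np.all(cwt_power(zeros, cfg).values == 0.0)
        const = np.full((cfg.n_freqs, 100), 2.0 + 0j)
        np.testing.assert_allclose(cwt_power(const, cfg).values, 4.0)


class TestBandPower:
    def test_single_bin_in_band(self):
        spec = SpectralVector([6.0, 10.0, 14.0], [0.0, 5.0, 0.0])
        assert band_power(spec, MU) == 5.0

    def test_hand_computed_sum(self):
        spec = SpectralVector([8.0, 10.0, 12.0], [1.0, 2.0, 3.0])
        assert band_power(spec, MU) == 6.0

    def test_disjoint_bands_are_additive(self):
        freqs = np.linspace(8, 20, 13)
        vals = np.arange(13.0)
        spec = SpectralVector(freqs, vals)
        union = Band("u", 8.0, 20.0)
        low = Band("a", 8.0, 11.9)
        high = Band("b", 12.0, 20.0)
        assert band_power(spec, low) + band_power(spec, high) \
            == pytest.approx(band_power(spec, union))

    def test_empty_band_rejected(self):
        spec = SpectralVector([8.0, 10.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            band_power(spec, Band("hi", 40.0, 50.0))

    @given(st.floats(0.1, 100.0))
    def test_scaling_spectrum_scales_band_power(self, c):
        spec = SpectralVector([8.0, 10.0, 12.0], [1.0, 2.0, 3.0])
        scaled = SpectralVector(spec.freqs, c * spec.values)
        assert band_power(scaled, MU) == pytest.approx(c * band_power(spec, MU))


class TestContributionTensor:
    def _trials(self, n=2, rng=None):
        rng = rng or np.random.default_rng(0)
        return [TrialEpoch(rng.standard_normal((22, 1750)), "left", FS)
                for _ in range(n)]

    @pytest.mark.parametrize("extractor", ["psd", "cwt"])
    def test_shapes_and_counts(self, extractor):
        tensor = contribution_tensor(self._trials(), extractor=extractor,
                                     bands=SCENARIO_BANDS["D"])
        assert tensor.values.shape == (2, 5, 4, 22)
        assert np.all(tensor.values >= 0.0)

    def test_psd_and_cwt_shapes_match(self):
        trials = self._trials()
        a = contribution_tensor(trials, "psd", SCENARIO_BANDS["C"])
        b = contribution_tensor(trials, "cwt", SCENARIO_BANDS["C"])
        assert a.values.shape == b.values.shape

    def test_identical_trials_identical_tensors(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((22, 1750))
        trials = [TrialEpoch(data.copy(), "left", FS) for _ in range(2)]
        t = contribution_tensor(trials, "cwt", (MU,))
        np.testing.assert_array_equal(t.values[0], t.values[1])

    def test_planted_channel_dominates_mu_band(self):
        rng = np.random.default_rng(2)
        data = 0.05 * rng.standard_normal((22, 1750))
        t = np.arange(1750) / FS
        data[7] += 5.0 * np.sin(2 * np.pi * 10.0 * t)  # channel C3
        tensor = contribution_tensor([TrialEpoch(data, "left", FS)],
                                     "cwt", (MU,))
        assert np.all(tensor.values[..., 7] == tensor.values.max(axis=-1))

    def test_window_start_selection(self):
        tensor = contribution_tensor(self._trials(1), "psd", (MU,),
                                     window_starts=[3.0])
        assert tensor.values.shape[1] == 1
        np.testing.assert_allclose(tensor.window_starts, [3.0])

    def test_unknown_extractor_rejected(self):
        with pytest.raises(ValueError):
            contribution_tensor(self._trials(1), "fft", (MU,))
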