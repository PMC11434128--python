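"""LFP forward models and spectral analysis."""

import numpy as np
import pytest

from somnotc.lfp import (GeometryError, band_power, biophysical_lfp,
                         dominant_frequency, silent_fraction, spectrogram,
                         summed_voltage_lfp, transfer_resistance,
                         transfer_resistance_array)

FS = 1000.0


class TestTransferResistance:
    def test_inverse_distance_law(self):
        r1 = transfer_resistance(100.0, 0.3)
        r2 = transfer_resistance(200.0, 0.3)
        assert r1 == pytest.approx(2 * r2, rel=1e-12)

    def test_closed_form_value(self):
        # 1/(4π·0.3 S/m·100 µm) ≈ 2652.58 Ω
        assert transfer_resistance(100.0, 0.3) == pytest.approx(2652.582, rel=1e-6)

    def test_equidistant_compartments_equal(self):
        elec = np.zeros(3)
        pts = np.array([[100.0, 0, 0], [0, 100.0, 0], [0, -100.0, 0]])
        r = transfer_resistance_array(elec, pts, 0.3)
        assert np.allclose(r, r[0])

    def test_minimum_distance_enforced(self):
        with pytest.raises(GeometryError):
            transfer_resistance(5.0, 0.3)
        with pytest.raises(GeometryError):
            transfer_resistance_array(np.zeros(3), np.array([[1.0, 0, 0]]), 0.3)


class TestBiophysicalLfp:
    def test_single_compartment_closed_form(self):
        # 1 nA at r = 100 µm, σ = 0.3 → φ = R·I ≈ 2.65 µV, to 1e-10 relative
        r = np.array([transfer_resistance(100.0, 0.3)])
        phi = biophysical_lfp(np.array([[1.0]]), r)
        expected = 1e-9 / (4 * np.pi * 0.3 * 100e-6) * 1e6  # 1 nA → volts → µV
        assert abs(phi[0] - expected) / expected < 1e-10

    def test_zero_currents_zero_potential(self):
        r = np.array([1000.0, 2000.0])
        phi = biophysical_lfp(np.zeros((5, 2)), r)
        assert np.all(phi == 0.0)

    def test_superposition_exact(self):
        rng = np.random.default_rng(0)
        i_a = rng.normal(size=(50, 4))
        i_b = rng.normal(size=(50, 4))
        r = rng.uniform(500, 5000, size=4)
        lhs = biophysical_lfp(i_a + i_b, r)
        rhs = biophysical_lfp(i_a, r) + biophysical_lfp(i_b, r)
        assert np.allclose(lhs, rhs, rtol=1e-12, atol=0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            biophysical_lfp(np.zeros((5, 3)), np.ones(4))


class TestSummedVoltageLfp:
    def test_single_trace_identity(self):
        v = np.sin(np.linspace(0, 10, 100))[:, None]
        assert np.array_equal(summed_voltage_lfp(v), v[:, 0])

    def test_constant_traces_give_constant_mean(self):
        v = np.full((50, 7), -65.0)
        assert np.allclose(summed_voltage_lfp(v), -65.0)

    def test_two_traces_pointwise_mean(self):
        a = np.linspace(0, 1, 20)
        b = np.linspace(1, 0, 20)
        out = summed_voltage_lfp(np.column_stack([a, b]))
        assert np.allclose(out, (a + b) / 2)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            summed_voltage_lfp(np.zeros((10, 0)))


class TestSpectrogram:
    def test_pure_tone_peaks_at_its_frequency_in_every_window(self):
        t = np.arange(0, 20, 1 / FS)
        x = np.sin(2 * np.pi * 10.0 * t)
        f, tw, sxx = spectrogram(x, FS, window_s=2.0, overlap=0.75)
        peak_bin = np.argmax(sxx, axis=0)
        assert np.allclose(f[peak_bin], 10.0, atol=f[1] - f[0])

    def test_zero_signal_zero_matrix(self):
        f, tw, sxx = spectrogram(np.zeros(5000), FS)
        assert np.all(sxx == 0.0)

    def test_two_tone_input_gives_two_ridges(self):
        t = np.arange(0, 30, 1 / FS)
        x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 12.0 * t)
        f, tw, sxx = spectrogram(x, FS, window_s=4.0, overlap=0.5)
        mean_psd = sxx.mean(axis=1)
        lo = mean_psd[(f >= 0.5) & (f <= 1.5)].max()
        hi = mean_psd[(f >= 11.5) & (f <= 12.5)].max()
        mid = mean_psd[(f >= 4.0) & (f <= 8.0)].max()
        assert lo > 50 * mid and hi > 50 * mid

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            spectrogram(np.zeros(100), FS, window_s=2.0)

    def test_energy_identity_within_tolerance(self):
        # Parseval-style check: integrated PSD ≈ signal variance
        rng = np.random.default_rng(1)
        x = rng.normal(size=20_000)
        f, tw, sxx = spectrogram(x, FS, window_s=2.0, overlap=0.5)
        total = np.trapezoid(sxx.mean(axis=1), f)
        assert total == pytest.approx(np.var(x), rel=0.05)


class TestBandPower:
    def test_tone_power_captured_by_containing_band(self):
        t = np.arange(0, 20, 1 / FS)
        x = np.sin(2 * np.pi * 10.0 * t)
        f, tw, sxx = spectrogram(x, FS, window_s=2.0, overlap=0.5)
        inband = band_power(f, sxx, (7.0, 14.0)).mean()
        assert inband == pytest.approx(0.5, rel=0.05)  # sine power = A²/2

    def test_disjoint_band_leakage_bounded(self):
        t = np.arange(0, 20, 1 / FS)
        x = np.sin(2 * np.pi * 10.0 * t)
        f, tw, sxx = spectrogram(x, FS, window_s=2.0, overlap=0.5)
        out = band_power(f, sxx, (30.0, 60.0)).mean()
        assert out < 1e-6

    def test_white_noise_power_proportional_to_bandwidth(self):
        # Monte-Carlo over 100 realisations: E[P(band)] ∝ bandwidth
        rng = np.random.default_rng(7)
        ratios = []
        for _ in range(100):
            x = rng.normal(size=4000)
            f, tw, sxx = spectrogram(x, FS, window_s=1.0, overlap=0.0)
            p1 = band_power(f, sxx, (10.0, 30.0)).mean()
            p2 = band_power(f, sxx, (100.0, 180.0)).mean()
            ratios.append(p2 / p1)
        assert np.mean(ratios) == pytest.approx(4.0, rel=0.1)  # 80 Hz / 20 Hz

    def test_empty_band_rejected(self):
        f = np.linspace(0, 100, 101)
        with pytest.raises(ValueError):
            band_power(f, np.ones((101, 3)), (20.0, 20.0))


class TestSummaries:
    def test_silent_fraction_counts_empty_bins(self):
        spikes = np.array([5.0, 7.0, 95.0])
        # bins [0,10), [10,20), ... [90,100): two occupied of ten
        assert silent_fraction(spikes, 0.0, 100.0, bin_ms=10.0) == pytest.approx(0.8)

    def test_silent_fraction_of_tonic_train_is_zero(self):
        spikes = np.arange(0.0, 1000.0, 5.0)
        assert silent_fraction(spikes, 0.0, 1000.0, bin_ms=10.0) == 0.0

    def test_dominant_frequency_of_tone(self):
        t = np.arange(0, 30, 1 / FS)
        x = np.sin(2 * np.pi * 9.0 * t) + 0.01 * np.sin(2 * np.pi * 3.0 * t)
        assert dominant_frequency(x, FS, fmin=0.5, fmax=30.0) == pytest.approx(
            9.0, abs=0.3)
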