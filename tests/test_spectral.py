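"""Boxcar spectra, ITC, brain-to-tagging coherence, and the dB SNR statistic."""

import numpy as np
import pandas as pd
import pytest

from riftkit.spectral import SpectralSet, fft_boxcar, itc, power_spectrum, snr_db, tag_coherence
from riftkit.synthmeg import Epochs


def _epochs_from_timecourses(tcs: np.ndarray, fs: float = 600.0) -> Epochs:
    """Wrap (trials, channels, time) arrays covering -0.4..1.2 s."""
    return Epochs(data=tcs, sample_rate=fs, epoch_window=(-0.4, 1.2))


def _spec(coeffs, tag=None, freqs=None):
    coeffs = np.asarray(coeffs)
    if freqs is None:
        freqs = np.arange(coeffs.shape[-1], dtype=float)
    return SpectralSet(coefficients=coeffs, frequencies=freqs, tag_coefficients=tag)


class TestFftBoxcar:
    def test_integer_cycle_sinusoid_is_a_single_bin(self):
        t = -0.4 + np.arange(960) / 600.0
        x = np.sin(2 * np.pi * 60.0 * t)[None, None, :]
        spec = fft_boxcar(_epochs_from_timecourses(x))
        mags = np.abs(spec.coefficients[0, 0])
        assert mags[60] == pytest.approx(0.5, abs=1e-9)
        mags[60] = 0.0
        assert mags.max() < 1e-12

    def test_dc_trial_has_no_nonzero_frequency_content(self):
        spec = fft_boxcar(_epochs_from_timecourses(np.full((1, 1, 960), 3.0)))
        assert np.abs(spec.coefficients[0, 0, 1:]).max() < 1e-12
        assert spec.coefficients[0, 0, 0] == pytest.approx(3.0)

    def test_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 3, 960))
        spec = fft_boxcar(_epochs_from_timecourses(x))
        seg = x[..., 360:960]
        L = 600
        c = spec.coefficients
        freq_sum = L * (
            np.abs(c[..., 0]) ** 2
            + 2 * np.sum(np.abs(c[..., 1:-1]) ** 2, axis=-1)
            + np.abs(c[..., -1]) ** 2
        )
        time_sum = np.sum(seg**2, axis=-1)
        np.testing.assert_allclose(freq_sum, time_sum, rtol=1e-10)

    def test_window_validation(self):
        ep = _epochs_from_timecourses(np.zeros((1, 1, 960)))
        with pytest.raises(ValueError, match="outside"):
            fft_boxcar(ep, window=(0.5, 1.5))


class TestPowerSpectrum:
    def test_single_coefficient_magnitude(self):
        spec = _spec(np.array([[[3 + 4j]]]))
        assert power_spectrum(spec)[0, 0] == pytest.approx(25.0)

    def test_invariant_to_per_trial_phase(self):
        rng = np.random.default_rng(1)
        amps = rng.uniform(0.5, 2.0, size=(5, 2, 4))
        phases = rng.uniform(0, 2 * np.pi, size=(5, 2, 4))
        p0 = power_spectrum(_spec(amps + 0j))
        p1 = power_spectrum(_spec(amps * np.exp(1j * phases)))
        np.testing.assert_allclose(p0, p1, rtol=1e-12)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(2)
        c = rng.standard_normal((5, 3, 7)) + 1j * rng.standard_normal((5, 3, 7))
        expected = sum(np.abs(c[t]) ** 2 for t in range(5)) / 5
        np.testing.assert_allclose(power_spectrum(_spec(c)), expected, rtol=1e-12)


class TestItc:
    def test_shared_phase_is_one(self):
        c = np.exp(1j * 0.7) * np.ones((6, 2, 3)) * np.arange(1, 7)[:, None, None]
        np.testing.assert_allclose(itc(_spec(c)), 1.0, atol=1e-12)

    def test_quadrature_phases_cancel(self):
        c = np.exp(1j * np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2]))[:, None, None]
        assert itc(_spec(c))[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_two_trials_quarter_turn(self):
        c = np.exp(1j * np.array([0.0, np.pi / 2]))[:, None, None]
        assert itc(_spec(c))[0, 0] == pytest.approx(np.sqrt(2) / 2, abs=1e-12)

    def test_zero_bins_excluded_and_flagged(self):
        c = np.zeros((3, 1, 2), dtype=complex)
        c[:, 0, 1] = np.exp(1j * 0.3)
        with pytest.warns(UserWarning, match="all-zero"):
            out = itc(_spec(c))
        assert out[0, 0] == 0.0 and out[0, 1] == pytest.approx(1.0)

    def test_bounded(self):
        rng = np.random.default_rng(3)
        c = rng.standard_normal((20, 4, 8)) + 1j * rng.standard_normal((20, 4, 8))
        out = itc(_spec(c))
        assert np.all(out >= 0.0) and np.all(out <= 1.0 + 1e-12)


class TestTagCoherence:
    def test_perfect_phase_relation_is_one(self):
        rng = np.random.default_rng(4)
        G = np.exp(1j * rng.uniform(0, 2 * np.pi, size=(8, 5)))
        F = 2.3 * G[:, None, :] * np.exp(1j * 0.9)
        np.testing.assert_allclose(tag_coherence(_spec(F, tag=G)), 1.0, atol=1e-12)

    def test_independent_noise_is_near_zero(self):
        rng = np.random.default_rng(5)
        n = 400
        G = np.exp(1j * rng.uniform(0, 2 * np.pi, size=(n, 6)))
        F = rng.standard_normal((n, 3, 6)) + 1j * rng.standard_normal((n, 3, 6))
        assert tag_coherence(_spec(F, tag=G)).max() < 0.15

    def test_invariant_to_common_phase_randomization(self):
        """A per-trial phase entering both brain and tag cancels exactly."""
        rng = np.random.default_rng(6)
        G = np.exp(1j * rng.uniform(0, 2 * np.pi, size=(10, 4)))
        F = rng.standard_normal((10, 2, 4)) + 1j * rng.standard_normal((10, 2, 4))
        common = np.exp(1j * rng.uniform(0, 2 * np.pi, size=10))
        base = tag_coherence(_spec(F, tag=G))
        spun = tag_coherence(
            _spec(F * common[:, None, None], tag=G * common[:, None])
        )
        np.testing.assert_allclose(base, spun, rtol=1e-12)

    def test_invariant_to_constant_apparatus_delay(self):
        """A fixed unknown delay rotates all brain coefficients equally."""
        rng = np.random.default_rng(7)
        G = np.exp(1j * rng.uniform(0, 2 * np.pi, size=(10, 4)))
        F = rng.standard_normal((10, 2, 4)) + 1j * rng.standard_normal((10, 2, 4))
        base = tag_coherence(_spec(F, tag=G))
        delayed = tag_coherence(_spec(F * np.exp(1j * 1.234), tag=G))
        np.testing.assert_allclose(base, delayed, rtol=1e-12)

    def test_agrees_with_itc_for_constant_tag_noise_free(self):
        phases = np.full(5, 0.4)
        G = np.exp(1j * phases)[:, None]
        F = 1.7 * np.exp(1j * (phases + 0.2))[:, None, None]
        spec = _spec(F, tag=G)
        assert tag_coherence(spec)[0, 0] == pytest.approx(itc(spec)[0, 0], abs=1e-6)

    def test_missing_tag_coefficients(self):
        with pytest.raises(ValueError, match="tag"):
            tag_coherence(_spec(np.ones((2, 1, 1), dtype=complex)))


class TestSnrDb:
    FREQS = np.arange(50.0, 71.0)

    def test_flat_spectrum_is_zero(self):
        assert snr_db(np.ones(21), self.FREQS, 60.0) == pytest.approx(0.0, abs=1e-12)

    def test_tenfold_peak_is_ten(self):
        x = np.ones(21)
        x[10] = 10.0
        assert snr_db(x, self.FREQS, 60.0) == pytest.approx(10.0, abs=1e-12)

    def test_hand_computed_mixed_neighbours(self):
        x = np.ones(21)
        x[10] = 4.0
        # neighbours 55..58 and 62..65
        x[[5, 6, 7, 8]] = [1, 2, 1, 2]
        x[[12, 13, 14, 15]] = [1, 2, 1, 2]
        assert snr_db(x, self.FREQS, 60.0) == pytest.approx(10 * np.log10(4 / 1.5), abs=1e-12)

    def test_adjacent_bins_excluded(self):
        x = np.ones(21)
        x[[9, 11]] = 1e6  # within the +-1 Hz exclusion zone
        assert snr_db(x, self.FREQS, 60.0) == pytest.approx(0.0, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ZeroDivisionError):
            x = np.zeros(21)
            x[10] = 1.0
            snr_db(x, self.FREQS, 60.0)
        with pytest.raises(ValueError, match="grid"):
            snr_db(np.ones(21), self.FREQS, 59.5)
        with pytest.raises(ValueError, match="neighbour"):
            snr_db(np.ones(6), np.arange(58.0, 64.0), 60.0)
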