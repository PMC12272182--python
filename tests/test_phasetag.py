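"""Phase correction, phase projection, lag profiles, and disentangling."""

import numpy as np
import pytest

from conftest import circdist_mod_pi
from riftkit.phasetag import (
    PHASE_GRID,
    disentangle_two_stim,
    lag_profile,
    phase_correct,
    project_phase,
)
from riftkit.spectral import SpectralSet, fft_boxcar
from riftkit.synthmeg import NoiseConfig, occipital_source, simulate_epochs


def _spec(coeffs, tag=None):
    coeffs = np.asarray(coeffs)
    return SpectralSet(
        coefficients=coeffs,
        frequencies=np.arange(coeffs.shape[-1], dtype=float),
        tag_coefficients=tag,
    )


class TestPhaseCorrect:
    def test_brain_equals_tag_gives_zero_phase(self):
        rng = np.random.default_rng(0)
        G = 0.5 * np.exp(1j * rng.uniform(0, 2 * np.pi, size=(6, 3)))
        F = G[:, None, :] * np.array([1.0, 2.0])[None, :, None]
        corr = phase_correct(_spec(F, tag=G), foi=1.0)
        np.testing.assert_allclose(np.angle(corr), 0.0, atol=1e-12)

    def test_magnitudes_preserved(self):
        rng = np.random.default_rng(1)
        G = np.exp(1j * rng.uniform(0, 2 * np.pi, size=(6, 2)))
        F = rng.standard_normal((6, 4, 2)) + 1j * rng.standard_normal((6, 4, 2))
        corr = phase_correct(_spec(F, tag=G), foi=1.0)
        np.testing.assert_allclose(np.abs(corr), np.abs(F[:, :, 1]), rtol=1e-12)

    def test_injected_lag_appears_in_corrected_phase(self, array32):
        """Noise-free random-phase trials: corrected phases all equal the lag
        (mod pi; the leadfield's sign splits channels into lag / lag + pi)."""
        lag = 0.7
        run = simulate_epochs(
            [occipital_source(extra_phase=lag)], array32, 10,
            noise=NoiseConfig().silent(), phase_mode="random", seed=2,
        )
        corr = phase_correct(fft_boxcar(run.epochs, run.tag), foi=60.0)
        dist = (np.angle(corr) - lag) % np.pi
        dist = np.minimum(dist, np.pi - dist)
        assert dist.max() < 1e-6

    def test_weak_tag_trials_dropped_with_warning(self):
        G = np.ones((4, 2), dtype=complex)
        G[1, 1] = 0.0
        F = np.ones((4, 3, 2), dtype=complex)
        with pytest.warns(UserWarning, match="excluded"):
            corr = phase_correct(_spec(F, tag=G), foi=1.0)
        assert corr.shape[0] == 3


class TestProjectPhase:
    def test_unit_phasor_projections(self):
        phi0 = 0.9
        F = np.array([np.exp(1j * phi0)])
        assert project_phase(F, phi0)[0] == pytest.approx(1.0, abs=1e-12)
        assert project_phase(F, phi0 + np.pi / 2)[0] == pytest.approx(0.0, abs=1e-12)

    def test_antiperiodic(self):
        rng = np.random.default_rng(3)
        F = rng.standard_normal(5) + 1j * rng.standard_normal(5)
        phi = 1.1
        np.testing.assert_allclose(
            project_phase(F, phi + np.pi), -project_phase(F, phi), rtol=1e-12
        )


class TestLagProfile:
    def test_shared_phase_peaks_on_nearest_grid_point(self):
        rng = np.random.default_rng(4)
        phi0 = 5 * np.pi / 16  # on grid
        coeffs = rng.uniform(0.5, 2.0, size=8) * np.exp(1j * phi0)
        prof = lag_profile(coeffs)
        assert prof.peak_phase == pytest.approx(phi0 % np.pi, abs=1e-12)

    def test_profile_is_pi_periodic(self):
        rng = np.random.default_rng(5)
        coeffs = rng.standard_normal(6) + 1j * rng.standard_normal(6)
        prof = lag_profile(coeffs)
        np.testing.assert_allclose(prof.gfp[:16], prof.gfp[16:], rtol=1e-9)

    def test_total_gfp_invariant_under_global_rotation(self):
        rng = np.random.default_rng(6)
        coeffs = rng.standard_normal(6) + 1j * rng.standard_normal(6)
        s0 = lag_profile(coeffs).gfp.sum()
        s1 = lag_profile(coeffs * np.exp(1j * 0.813)).gfp.sum()
        assert s1 == pytest.approx(s0, rel=1e-9)

    def test_noise_free_lag_recovery_within_grid_step(self, array32):
        lag = 0.7
        run = simulate_epochs(
            [occipital_source(extra_phase=lag)], array32, 12,
            noise=NoiseConfig().silent(), phase_mode="random", seed=7,
        )
        corr = phase_correct(fft_boxcar(run.epochs, run.tag), foi=60.0)
        prof = lag_profile(corr.mean(axis=0))
        assert circdist_mod_pi(prof.peak_phase, lag) <= np.pi / 16

    def test_degenerate_profile_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            prof = lag_profile(np.zeros(4, dtype=complex))
        assert prof.degenerate


class TestDisentangleTwoStim:
    @staticmethod
    def _cosine(a, b):
        return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))

    def _noise_free_run(self, array32, lag=5 * np.pi / 16, seed=8, amp_right=None):
        left = occipital_source("right", extra_phase=lag)
        right = occipital_source("left", extra_phase=lag)
        if amp_right is not None:
            right = occipital_source("left", amplitude=amp_right, extra_phase=lag)
        return simulate_epochs(
            [left, right], array32, 16, noise=NoiseConfig().silent(),
            phase_mode="two_stim_orthogonal", seed=seed,
        )

    def test_topographies_match_source_forward_fields(self, array32):
        lag = 5 * np.pi / 16  # on the phase grid, so no projection leakage
        run = self._noise_free_run(array32, lag)
        spec = fft_boxcar(run.epochs, run.tag)
        topos = disentangle_two_stim(spec, peak_phase=lag % np.pi)
        cos_l = abs(self._cosine(topos.topo_at_peak, run.leadfields[0]))
        cos_r = abs(self._cosine(topos.topo_at_peak_plus_90, run.leadfields[1]))
        assert cos_l > 0.99 and cos_r > 0.99

    def test_orthogonality_no_cross_talk(self, array32):
        """With only the left source active, the 90 deg projection is empty."""
        run = self._noise_free_run(array32, amp_right=0.0)
        spec = fft_boxcar(run.epochs, run.tag)
        topos = disentangle_two_stim(spec, peak_phase=(5 * np.pi / 16) % np.pi)
        leak = np.linalg.norm(topos.topo_at_peak_plus_90)
        assert leak < 1e-6 * np.linalg.norm(topos.topo_at_peak)

    def test_swapping_stimulus_sources_swaps_topographies(self, array32):
        lag = 5 * np.pi / 16
        run = self._noise_free_run(array32, lag)
        swapped = simulate_epochs(
            [occipital_source("left", extra_phase=lag),
             occipital_source("right", extra_phase=lag)],
            array32, 16, noise=NoiseConfig().silent(),
            phase_mode="two_stim_orthogonal", seed=8,
        )
        t0 = disentangle_two_stim(fft_boxcar(run.epochs, run.tag), lag % np.pi)
        t1 = disentangle_two_stim(fft_boxcar(swapped.epochs, swapped.tag), lag % np.pi)
        assert abs(self._cosine(t1.topo_at_peak, run.leadfields[1])) > 0.99
        assert abs(self._cosine(t1.topo_at_peak_plus_90, run.leadfields[0])) > 0.99
        assert abs(self._cosine(t0.topo_at_peak, t1.topo_at_peak_plus_90)) > 0.99

    def test_requires_two_stim_metadata(self, array32):
        run = simulate_epochs(
            [occipital_source()], array32, 4, noise=NoiseConfig().silent(),
            phase_mode="random", seed=9,
        )
        with pytest.raises(ValueError, match="two_stim"):
            disentangle_two_stim(fft_boxcar(run.epochs, run.tag), 0.3)
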