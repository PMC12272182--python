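"""Boxcar-taper Fourier analysis: power, ITC, brain-to-tagging coherence, SNR.

Epochs are windowed to a 1 s segment (default 0.2..1.2 s after
stimulus onset, giving 1 Hz frequency resolution) and Fourier
transformed with a flat (boxcar) taper to minimize power smearing.
Three trial-aggregated measures are derived from the complex
coefficients:

* power: mean over trials of the squared coefficient magnitude;
* inter-trial coherence (ITC): magnitude of the across-trial mean of
  unit-normalized coefficients -- sensitive only when the stimulation
  phase is constant across trials;
* brain-to-tagging coherence: coherence between the sensor
  coefficients and the Fourier coefficient of each trial's *corrected
  tagging signal*, i.e. consistency of the brain-to-tagging phase
  *difference* -- robust to trial-varying stimulation phase and to any
  constant apparatus delay.

The tagging response strength is summarized as an SNR in dB: the value
at the frequency of interest against the mean over neighbouring bins
[foi-5, foi-2] and [foi+2, foi+5] Hz (endpoints included, the bins
immediately adjacent to foi excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .synthmeg import Epochs, TrialTagSignals

__all__ = [
    "SpectralSet",
    "fft_boxcar",
    "power_spectrum",
    "itc",
    "tag_coherence",
    "snr_db",
]


@dataclass(frozen=True)
class SpectralSet:
    """One-sided complex Fourier coefficients of windowed epochs.

    ``coefficients`` has shape (trials, channels, frequencies) and is
    normalized by the window length, so a unit sinusoid at a bin
    frequency has coefficient magnitude 0.5.  ``tag_coefficients``
    (trials, frequencies) are computed identically from each trial's
    corrected tagging signal and provide the phase reference for
    :func:`tag_coherence`.
    """

    coefficients: np.ndarray
    frequencies: np.ndarray
    window: tuple[float, float] = (0.2, 1.2)
    tag_coefficients: np.ndarray | None = None
    trial_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_trials(self) -> int:
        return self.coefficients.shape[0]

    def freq_index(self, foi: float) -> int:
        idx = int(np.argmin(np.abs(self.frequencies - foi)))
        if abs(self.frequencies[idx] - foi) > 1e-6:
            raise ValueError(f"frequency {foi} Hz not on the spectral grid")
        return idx


def fft_boxcar(
    epochs: Epochs,
    tag_signals: TrialTagSignals | np.ndarray | None = None,
    window: tuple[float, float] = (0.2, 1.2),
) -> SpectralSet:
    """Flat-taper DFT of the windowed epochs (and tag signals).

    The window is half-open ``[w0, w1)`` relative to stimulus onset and
    must lie inside the epoch; its length times the sample rate must be
    a whole number of samples.  No taper is applied (boxcar).
    """
    fs = epochs.sample_rate
    t0, t1 = epochs.epoch_window
    w0, w1 = window
    if w0 < t0 - 1e-9 or w1 > t1 + 1e-9:
        raise ValueError(f"window {window} outside epoch window {epochs.epoch_window}")
    n_win = (w1 - w0) * fs
    if abs(n_win - round(n_win)) > 1e-6:
        raise ValueError("window length times sample rate must be an integer")
    n_win = int(round(n_win))
    i0 = int(round((w0 - t0) * fs))

    seg = epochs.data[..., i0 : i0 + n_win]
    coeffs = np.fft.rfft(seg, axis=-1) / n_win
    freqs = np.fft.rfftfreq(n_win, 1.0 / fs)

    tag_coeffs = None
    if tag_signals is not None:
        values = tag_signals.values if isinstance(tag_signals, TrialTagSignals) else np.asarray(tag_signals)
        if values.shape != (epochs.n_trials, epochs.data.shape[-1]):
            raise ValueError("tag signals must be (n_trials, n_samples) on the epoch grid")
        tag_coeffs = np.fft.rfft(values[:, i0 : i0 + n_win], axis=-1) / n_win

    return SpectralSet(
        coefficients=coeffs,
        frequencies=freqs,
        window=(w0, w1),
        tag_coefficients=tag_coeffs,
        trial_meta=epochs.trial_meta.copy(),
    )


def power_spectrum(spec: SpectralSet) -> np.ndarray:
    """Mean over trials of |coefficient|^2, per channel x frequency."""
    if spec.n_trials < 1:
        raise ValueError("need at least one trial")
    return np.mean(np.abs(spec.coefficients) ** 2, axis=0)


def itc(spec: SpectralSet) -> np.ndarray:
    """Inter-trial coherence per channel x frequency, in [0, 1].

    The magnitude of the across-trial mean of unit-normalized
    coefficients.  Zero-magnitude coefficients carry no phase and are
    excluded from the mean; a bin with no valid trials is defined as 0
    (with a warning).  With a single trial the result is identically 1.
    """
    if spec.n_trials == 1:
        warnings.warn("ITC of a single trial is identically 1", stacklevel=2)
    mags = np.abs(spec.coefficients)
    valid = mags > 0
    unit = np.where(valid, spec.coefficients / np.where(valid, mags, 1.0), 0.0)
    counts = valid.sum(axis=0)
    if np.any(counts == 0):
        warnings.warn("bins with all-zero coefficients; ITC set to 0 there", stacklevel=2)
    with np.errstate(invalid="ignore"):
        out = np.abs(unit.sum(axis=0)) / np.maximum(counts, 1)
    return np.where(counts == 0, 0.0, out)


def tag_coherence(spec: SpectralSet, phase_only: bool = False) -> np.ndarray:
    """Brain-to-tagging coherence per channel x frequency, in [0, 1].

    Default (magnitude-weighted) estimator::

        coh_k(f) = |sum_t F_kt conj(G_t)| /
                   sqrt(sum_t |F_kt|^2 * sum_t |G_t|^2)

    with F the sensor and G the tagging-signal coefficients.  With
    ``phase_only=True`` the ITC of the phase-corrected unit
    coefficients is returned instead (each trial weighted equally);
    both readings measure the across-trial consistency of the
    brain-to-tagging phase difference.
    """
    if spec.tag_coefficients is None:
        raise ValueError("SpectralSet has no tag coefficients")
    F = spec.coefficients
    G = spec.tag_coefficients[:, None, :]
    if phase_only:
        prod = F * np.conj(G)
        mags = np.abs(prod)
        valid = mags > 0
        unit = np.where(valid, prod / np.where(valid, mags, 1.0), 0.0)
        counts = valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            out = np.abs(unit.sum(axis=0)) / np.maximum(counts, 1)
        return np.where(counts == 0, 0.0, out)
    num = np.abs(np.sum(F * np.conj(G), axis=0))
    den = np.sqrt(np.sum(np.abs(F) ** 2, axis=0) * np.sum(np.abs(G) ** 2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = num / den
    return np.where(den > 0, coh, 0.0)


def snr_db(
    values: np.ndarray,
    frequencies: Sequence[float],
    foi: float = 60.0,
    gap: float = 2.0,
    halfwidth: float = 5.0,
) -> float:
    """SNR of a nonnegative spectrum at ``foi``, in decibels.

    ``SNR = 10 * log10(x(foi) / mean(x over neighbours))`` with the
    neighbour bands ``[foi-halfwidth, foi-gap]`` and
    ``[foi+gap, foi+halfwidth]``, endpoints inclusive; bins closer than
    ``gap`` to foi are excluded.
    """
    values = np.asarray(values, dtype=float)
    freqs = np.asarray(frequencies, dtype=float)
    if values.shape[-1] != len(freqs):
        raise ValueError("values and frequencies have mismatched lengths")
    if np.any(values < 0):
        raise ValueError("spectrum values must be nonnegative")
    df = np.abs(freqs - foi)
    fidx = int(np.argmin(df))
    if df[fidx] > 1e-6:
        raise ValueError(f"frequency of interest {foi} Hz not on the grid")
    nb = (df >= gap - 1e-9) & (df <= halfwidth + 1e-9)
    expected = 2 * (int(round(halfwidth)) - int(round(gap)) + 1)
    if nb.sum() < expected:
        raise ValueError("neighbour band extends beyond the spectral grid")
    neighbour_mean = float(values[..., nb].mean())
    if neighbour_mean <= 0:
        raise ZeroDivisionError("neighbour mean is zero; SNR undefined")
    return float(10.0 * np.log10(values[..., fidx] / neighbour_mean))
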