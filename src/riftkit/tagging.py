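"""Tagging waveforms and tagging reference signals.

Rapid invisible frequency tagging (RIFT) modulates stimulus luminance
sinusoidally at a frequency around 60 Hz, above the flicker-fusion
threshold, using high-refresh-rate projection (1440 frames/s).  Four
tagging protocols ("types") are supported, differing in which luminance
bands of a black/white grating oscillate and with what amplitude:

* type 1 -- full-amplitude luminance tagging: white bands oscillate
  0..100 %, black bands stay black.
* type 2 -- half-amplitude luminance tagging: white bands oscillate
  50..100 %, black bands stay black.
* type 3 -- additive luminance tagging: white bands 50..100 % and black
  bands 0..50 %, in phase (constant contrast).
* type 4 -- contrast tagging: white bands 50..100 % and black bands
  50..0 %, in anti-phase (constant mean luminance).

This module also reconstructs the *corrected tagging signal*: the
tagging sinusoid as it was actually displayed, recovered from the stored
(ideal) sinusoid, a light-sensor trace, and a log of missed projector
frame flips.  The corrected signal is the phase reference for
brain-to-tagging coherence (see :mod:`riftkit.spectral`).

Phase convention used throughout the package: ``sin(2*pi*f*t + phi)``
with ``t = 0`` at stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaggingSpec",
    "TaggingWaveform",
    "TagSignal",
    "FlipLog",
    "OnsetNotDetectedError",
    "generate_waveform",
    "analytic_tag_signal",
    "reconstruct_corrected_tag",
]

#: (white offset, white amplitude, black offset, black amplitude) per type
_TYPE_COEFFS = {
    1: (0.50, 0.50, 0.00, 0.00),
    2: (0.75, 0.25, 0.00, 0.00),
    3: (0.75, 0.25, 0.25, 0.25),
    4: (0.75, 0.25, 0.25, -0.25),
}


class OnsetNotDetectedError(ValueError):
    """The light-sensor trace never rose above the baseline threshold."""


@dataclass(frozen=True)
class TaggingSpec:
    """Parameters of one tagging protocol.

    Parameters
    ----------
    tag_type
        Tagging protocol, 1-4 (see module docstring).
    frequency
        Tagging frequency in Hz.
    phase
        Tagging phase in radians, wrapped to ``[0, 2*pi)``.
    frame_rate
        Projector refresh rate in frames/s.
    duration
        Stimulus duration in seconds.
    """

    tag_type: int = 1
    frequency: float = 60.0
    phase: float = 0.0
    frame_rate: float = 1440.0
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.tag_type not in _TYPE_COEFFS:
            raise ValueError(f"unknown tag_type {self.tag_type!r}; expected 1-4")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.frame_rate < 2 * self.frequency:
            raise ValueError(
                f"frame_rate {self.frame_rate} Hz below Nyquist for "
                f"{self.frequency} Hz tagging"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        object.__setattr__(self, "phase", float(self.phase) % (2 * np.pi))


@dataclass(frozen=True)
class TaggingWaveform:
    """Per-frame luminance of the white/black grating bands.

    ``white`` and ``black`` are luminance fractions in ``[0, 1]``;
    ``modulation`` is the underlying unit sinusoid; ``frame_times`` are
    frame-start times in seconds (zero-order hold within a frame).
    """

    white: np.ndarray
    black: np.ndarray
    modulation: np.ndarray
    frame_times: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.frame_times,
                "white": self.white,
                "black": self.black,
                "modulation": self.modulation,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class TagSignal:
    """A tagging sinusoid sampled at the MEG analysis rate.

    ``onset_index`` is the sample index of stimulus onset (``t = 0``).
    The sinusoid is full length: samples before onset are *not* zeroed;
    windowing is the spectral module's responsibility.
    """

    values: np.ndarray
    sample_rate: float
    onset_index: int
    frequency: float
    phase: float

    def __post_init__(self) -> None:
        if self.sample_rate <= 2 * self.frequency:
            raise ValueError("sample_rate must exceed twice the tag frequency")


@dataclass(frozen=True)
class FlipLog:
    """Scheduled and actual times (s, relative to onset) of frame flips."""

    scheduled: np.ndarray
    actual: np.ndarray

    def __post_init__(self) -> None:
        sched = np.asarray(self.scheduled, dtype=float)
        act = np.asarray(self.actual, dtype=float)
        if sched.shape != act.shape:
            raise ValueError("scheduled and actual must have equal length")
        object.__setattr__(self, "scheduled", sched)
        object.__setattr__(self, "actual", act)

    def validate(self) -> None:
        if np.any(np.diff(self.scheduled) < 0) or np.any(np.diff(self.actual) < 0):
            raise ValueError("flip log times must be monotone nondecreasing")
        if np.any(self.actual < self.scheduled - 1e-12):
            raise ValueError("actual flip times cannot precede scheduled times")

    @property
    def miss(self) -> np.ndarray:
        """Per-flip lateness (actual - scheduled), seconds."""
        return self.actual - self.scheduled


def generate_waveform(spec: TaggingSpec) -> TaggingWaveform:
    """Generate per-frame band luminances for a tagging protocol.

    Frames are sampled at ``spec.frame_rate`` starting at ``t = 0``
    (frame-start convention).  With ``s = sin(2*pi*f*t + phi)``:

    ======  ====================  ====================
    type    white                 black
    ======  ====================  ====================
    1       ``0.5 + 0.5 s``       ``0``
    2       ``0.75 + 0.25 s``     ``0``
    3       ``0.75 + 0.25 s``     ``0.25 + 0.25 s``
    4       ``0.75 + 0.25 s``     ``0.25 - 0.25 s``
    ======  ====================  ====================
    """
    n_frames = int(round(spec.duration * spec.frame_rate))
    t = np.arange(n_frames) / spec.frame_rate
    s = np.sin(2 * np.pi * spec.frequency * t + spec.phase)
    w0, w1, b0, b1 = _TYPE_COEFFS[spec.tag_type]
    white = w0 + w1 * s
    black = b0 + b1 * s
    return TaggingWaveform(white=white, black=black, modulation=s, frame_times=t)


def analytic_tag_signal(
    frequency: float,
    phase: float,
    sample_rate: float,
    n_samples: int,
    onset_index: int = 0,
) -> TagSignal:
    """The ideal tagging sinusoid on the MEG sample grid.

    ``values[k] = sin(2*pi*f*(k - onset_index)/fs + phase)``.
    """
    if sample_rate <= 2 * frequency:
        raise ValueError("sample_rate must exceed twice the tag frequency")
    k = np.arange(int(n_samples))
    values = np.sin(
        2 * np.pi * frequency * (k - onset_index) / sample_rate + phase
    )
    return TagSignal(
        values=values,
        sample_rate=float(sample_rate),
        onset_index=int(onset_index),
        frequency=float(frequency),
        phase=float(phase),
    )


def _shift_samples(values: np.ndarray, shift: int) -> np.ndarray:
    """Shift right by `shift` samples (left if negative), zero-filled."""
    out = np.zeros_like(values)
    if shift == 0:
        out[:] = values
    elif shift > 0:
        out[shift:] = values[: len(values) - shift]
    else:
        out[:shift] = values[-shift:]
    return out


def reconstruct_corrected_tag(
    stored: TagSignal,
    sensor_trace: np.ndarray,
    flip_log: FlipLog,
    baseline_threshold: float = 0.5,
) -> TagSignal:
    """Reconstruct the tagging signal as actually displayed.

    Two corrections are applied to a copy of ``stored``:

    1. *Onset alignment*: the signal is shifted so that its onset
       coincides with the first sample at which ``sensor_trace`` exceeds
       ``baseline_threshold * max(sensor_trace)``.
    2. *Missed-flip delays*: the flip log records scheduled and actual
       flip times.  Whenever a flip adds more than 1 ms of new delay
       (lateness in excess of the delay already accumulated by earlier
       flips), all subsequent samples are delayed by that amount,
       rounded to the nearest whole sample (ties rounding down), and the
       gap is filled by holding the last displayed sample -- the
       projector freezes the current frame during a stall.

    Raises
    ------
    OnsetNotDetectedError
        If the trace never crosses the threshold.
    ValueError
        If the flip log is invalid (non-monotone, or actual earlier
        than scheduled).
    """
    if not 0.0 < baseline_threshold < 1.0:
        raise ValueError("baseline_threshold must lie in (0, 1)")
    flip_log.validate()
    trace = np.asarray(sensor_trace, dtype=float)
    fs = stored.sample_rate

    thr = baseline_threshold * trace.max()
    above = trace > thr
    if not above.any():
        raise OnsetNotDetectedError(
            "light-sensor trace never exceeded the baseline threshold"
        )
    k0 = int(np.argmax(above))

    values = _shift_samples(np.asarray(stored.values, dtype=float), k0 - stored.onset_index)

    # New delay contributed by each flip, beyond what earlier flips already added.
    increments = np.diff(flip_log.miss, prepend=0.0)
    for i in np.nonzero(increments > 1e-3)[0]:
        n = int(np.ceil(increments[i] * fs - 0.5))  # nearest sample, ties down
        if n <= 0:
            continue
        j = k0 + int(round(flip_log.actual[i] * fs))
        j = max(min(j, len(values)), 0)
        if j >= len(values):
            continue
        values[j + n :] = values[j : len(values) - n]
        values[j : j + n] = values[j - 1] if j > 0 else values[j]

    return TagSignal(
        values=values,
        sample_rate=fs,
        onset_index=k0,
        frequency=stored.frequency,
        phase=stored.phase,
    )
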