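"""Synthetic epoched MEG, light-sensor traces, flip logs, and behaviour.

The generator emulates the statistical structure the analysis modules
assume: occipital dipole sources driven by a 60 Hz tagging sinusoid
(with a per-participant tagging-to-brain phase lag), projected to a
spherical cap of radial magnetometers through the spherical-conductor
forward model, on top of 1/f background noise, a ~10 Hz alpha rhythm
with posterior weighting, 50 Hz common-mode line noise, and white
sensor noise.  Epochs span -0.4..+1.2 s around stimulus onset at
600 Hz.  Ground truth (trial phases, lags, apparatus delays, source
positions) is kept in the trial metadata so analyses can be scored
against it.

Apparatus imperfections are optional and configurable: a per-trial
display-pipeline delay (uniform up to ``apparatus_jitter_ms``) and
projector stalls (``stall_rate`` per trial, ``stall_frames`` frames
long) that show up in the light trace and the flip log exactly as the
correction procedure in :mod:`riftkit.tagging` expects.

It also simulates AXB discrimination behaviour: per-subject accuracies
drawn around a true accuracy, trial-level Bernoulli responses, and
response timeouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dipole import HeadModel, forward_radial
from .tagging import FlipLog, TagSignal, TaggingSpec, analytic_tag_signal

__all__ = [
    "SensorArray",
    "SourceSpec",
    "Epochs",
    "NoiseConfig",
    "TrialTagSignals",
    "SimulatedRun",
    "make_sensor_array",
    "occipital_source",
    "simulate_epochs",
    "simulate_behavior",
    "posterior_channels",
    "BEHAVIOUR_CONDITIONS",
    "DEFAULT_SOURCE_AMPLITUDE",
    "TYPE_RESPONSE_GAIN",
]

#: The three AXB discrimination block conditions.
BEHAVIOUR_CONDITIONS = ("type1_vs_none", "type4_vs_none", "60_vs_66")

#: Assumed neural response gain per tagging type, relative to type 1.
#: Full-amplitude luminance (1) and contrast (4) modulation drive the
#: strongest steady-state responses; the half-amplitude variants (2, 3)
#: are substantially weaker.  Used by the generator when emulating
#: tagging-type comparisons.
TYPE_RESPONSE_GAIN = {1: 1.0, 2: 0.55, 3: 0.45, 4: 1.0}

#: Default occipital source strength (sensor units per unit-RMS leadfield),
#: calibrated once so that 100 random-phase trials under the default noise
#: yield a brain-to-tagging coherence SNR of ~5 dB over posterior sensors,
#: the operating regime of real tagging recordings.
DEFAULT_SOURCE_AMPLITUDE = 0.02

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class SensorArray:
    """Radial magnetometers on a spherical cap.

    ``positions`` in mm (all at the helmet radius), ``orientations``
    unit radial vectors, ``names`` channel labels.
    """

    positions: np.ndarray
    orientations: np.ndarray
    names: tuple[str, ...]

    @property
    def n_channels(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class SourceSpec:
    """A tagged cortical source.

    ``extra_phase`` is the participant's tagging-to-brain phase lag
    (radians), added to the stimulation phase in the source time course.
    ``moment_direction`` is projected onto the tangential plane (radial
    dipoles are magnetically silent in a sphere) and normalized.
    """

    position: np.ndarray = field(default_factory=lambda: np.array([20.0, -85.0, -5.0]))
    moment_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    amplitude: float = 1.0
    tag: TaggingSpec = field(default_factory=TaggingSpec)
    extra_phase: float = 0.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        m = np.asarray(self.moment_direction, dtype=float)
        n = np.linalg.norm(pos)
        if n > 0:
            m = m - (m @ pos) / n**2 * pos
        norm = np.linalg.norm(m)
        if norm < 1e-12:
            raise ValueError("moment_direction is (numerically) radial")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "moment_direction", m / norm)


def occipital_source(
    side: str = "right",
    amplitude: float = DEFAULT_SOURCE_AMPLITUDE,
    extra_phase: float = 0.0,
    tag: TaggingSpec | None = None,
) -> SourceSpec:
    """A canonical occipital source in the requested hemisphere.

    ``side="right"`` places the source at (+20, -85, -5) mm -- the
    hemisphere that responds to a *left*-hemifield stimulus.
    """
    x = {"right": 20.0, "left": -20.0}[side]
    return SourceSpec(
        position=np.array([x, -85.0, -5.0]),
        amplitude=amplitude,
        extra_phase=extra_phase,
        tag=tag if tag is not None else TaggingSpec(),
    )


@dataclass(frozen=True)
class Epochs:
    """Trials x channels x time sensor data with per-trial metadata."""

    data: np.ndarray
    sample_rate: float = 600.0
    epoch_window: tuple[float, float] = (-0.4, 1.2)
    trial_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        t0, t1 = self.epoch_window
        expected = int(round((t1 - t0) * self.sample_rate))
        if self.data.shape[-1] != expected:
            raise ValueError(
                f"time axis has {self.data.shape[-1]} samples; window "
                f"{self.epoch_window} at {self.sample_rate} Hz needs {expected}"
            )

    @property
    def times(self) -> np.ndarray:
        t0, _ = self.epoch_window
        return t0 + np.arange(self.data.shape[-1]) / self.sample_rate

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class TrialTagSignals:
    """Per-trial stored tagging sinusoids on the epoch sample grid."""

    values: np.ndarray  # (n_trials, n_samples)
    sample_rate: float
    onset_index: int
    frequency: float
    phases: np.ndarray  # (n_trials,)

    def signal(self, trial: int) -> TagSignal:
        return TagSignal(
            values=self.values[trial],
            sample_rate=self.sample_rate,
            onset_index=self.onset_index,
            frequency=self.frequency,
            phase=float(self.phases[trial]),
        )


@dataclass(frozen=True)
class NoiseConfig:
    """Amplitudes (sensor units, per-channel RMS) of the noise components.

    Defaults are calibrated so that, together with the default source
    amplitude, 100 random-phase trials yield a brain-to-tagging
    coherence SNR of roughly 5 dB over the posterior sensors --
    the regime the method operates in on real recordings.
    """

    pink: float = 1.0
    pink_exponent: float = 1.0
    alpha: float = 1.0
    alpha_freq: float = 10.0
    line: float = 0.7
    line_freq: float = 50.0
    white: float = 0.3

    def silent(self) -> "NoiseConfig":
        return replace(self, pink=0.0, alpha=0.0, line=0.0, white=0.0)


@dataclass(frozen=True)
class SimulatedRun:
    """One simulated recording block, with full ground truth."""

    epochs: Epochs
    tag: TrialTagSignals
    light: np.ndarray          # (n_trials, n_samples)
    flip_logs: list
    displayed: np.ndarray      # ground-truth displayed tagging signal
    array: SensorArray
    head: HeadModel
    sources: tuple
    leadfields: np.ndarray     # (n_sources, n_channels), unit-RMS


def make_sensor_array(
    n_channels: int = 64,
    helmet_radius: float = 110.0,
    sphere_radius: float = 90.0,
    seed: int = 0,
    cap_halfangle_deg: float = 115.0,
) -> SensorArray:
    """Quasi-uniform spiral layout of radial sensors on a spherical cap.

    The cap spans polar angles 0..``cap_halfangle_deg`` from +z, which
    covers the superior and posterior head down to below the occipital
    sources.  The layout is a deterministic Fibonacci spiral; the seed
    only rotates the spiral's azimuthal origin, so identical seeds give
    bit-identical arrays.
    """
    if n_channels < 8:
        raise ValueError("need at least 8 channels")
    if helmet_radius <= sphere_radius:
        raise ValueError("helmet_radius must exceed sphere_radius")
    rng = np.random.default_rng(seed)
    az_offset = rng.uniform(0.0, 2 * np.pi)
    i = np.arange(n_channels)
    cos_max = np.cos(np.deg2rad(cap_halfangle_deg))
    cos_theta = 1.0 - (1.0 - cos_max) * (i + 0.5) / n_channels
    sin_theta = np.sqrt(1.0 - cos_theta**2)
    phi = i * _GOLDEN_ANGLE + az_offset
    pos = helmet_radius * np.column_stack(
        [sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta]
    )
    ori = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    names = tuple(f"MEG{k:03d}" for k in range(n_channels))
    return SensorArray(positions=pos, orientations=ori, names=names)


def posterior_channels(array: SensorArray, fraction: float = 1 / 3) -> np.ndarray:
    """Indices of the posterior-most channels (smallest y), default third."""
    n = max(1, int(round(array.n_channels * fraction)))
    return np.argsort(array.positions[:, 1])[:n]


def _pink_noise(rng, n_channels, n_samples, sample_rate, exponent):
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sample_rate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def simulate_epochs(
    sources: Sequence[SourceSpec],
    array: SensorArray,
    n_trials: int,
    noise: NoiseConfig | None = None,
    phase_mode: str = "fixed",
    seed: int | None = None,
    fixed_phase: float = 0.0,
    sample_rate: float = 600.0,
    epoch_window: tuple[float, float] = (-0.4, 1.2),
    frame_rate: float = 1440.0,
    apparatus_jitter_ms: float = 0.0,
    stall_rate: float = 0.0,
    stall_frames: int = 2,
    sphere_radius: float = 90.0,
) -> SimulatedRun:
    """Simulate one block of tagged passive-viewing epochs.

    ``phase_mode`` is one of ``"fixed"`` (stimulation phase
    ``fixed_phase`` on every trial), ``"random"`` (uniform per trial),
    or ``"two_stim_orthogonal"`` (exactly two sources; the second --
    right-stimulus -- source is tagged at +90 degrees relative to the
    first).  Each source contributes
    ``amplitude * sin(2*pi*f*t + phi_trial + extra_phase)`` from
    stimulus onset to the end of the epoch, mapped to sensors through
    the unit-RMS-normalized spherical forward field of its dipole.

    Returns the epochs plus everything the tagging-correction machinery
    consumes (per-trial stored tag signals, light traces, flip logs)
    and ground truth (displayed signal, leadfields, metadata).
    """
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    if not sources:
        raise ValueError("need at least one source")
    if phase_mode not in ("fixed", "random", "two_stim_orthogonal"):
        raise ValueError(f"unknown phase_mode {phase_mode!r}")
    if phase_mode == "two_stim_orthogonal" and len(sources) != 2:
        raise ValueError("two_stim_orthogonal requires exactly 2 sources")
    noise = noise if noise is not None else NoiseConfig()

    rng = np.random.default_rng(seed)
    head = HeadModel(array=array, sphere_radius=sphere_radius)
    t0, t1 = epoch_window
    n_samples = int(round((t1 - t0) * sample_rate))
    times = t0 + np.arange(n_samples) / sample_rate
    onset_index = int(round(-t0 * sample_rate))
    freq = sources[0].tag.frequency

    # Unit-RMS leadfields: `amplitude` then sets the per-channel signal scale.
    leadfields = np.empty((len(sources), array.n_channels))
    for i, src in enumerate(sources):
        lf = forward_radial(src.position, src.moment_direction, head)
        leadfields[i] = lf / np.sqrt(np.mean(lf**2))

    alpha_w = 0.1 + np.clip(-array.positions[:, 1] / np.max(np.linalg.norm(array.positions, axis=1)), 0.0, 1.0)

    n_frames = int(round(t1 * frame_rate))
    frame_grid = np.arange(n_frames) / frame_rate

    data = np.empty((n_trials, array.n_channels, n_samples))
    tag_values = np.empty((n_trials, n_samples))
    displayed = np.empty((n_trials, n_samples))
    light = np.empty((n_trials, n_samples))
    flip_logs = []
    meta_rows = []

    for tr in range(n_trials):
        if phase_mode == "fixed":
            phi_left = float(fixed_phase) % (2 * np.pi)
        else:
            phi_left = float(rng.uniform(0.0, 2 * np.pi))
        phi_right = (phi_left + np.pi / 2) % (2 * np.pi)

        d0 = rng.uniform(0.0, apparatus_jitter_ms / 1000.0) if apparatus_jitter_ms > 0 else 0.0
        if stall_rate > 0 and rng.uniform() < stall_rate:
            stall_time = float(rng.uniform(0.25, 0.9))
            stall_delay = stall_frames / frame_rate
        else:
            stall_time, stall_delay = np.nan, 0.0

        # effective stimulus time: display-pipeline delay + stall step
        delay = np.full(n_samples, d0)
        if stall_delay > 0:
            delay += stall_delay * (times >= d0 + stall_time)
        t_eff = times - delay
        on = times >= d0

        trial = np.zeros((array.n_channels, n_samples))
        phases = (phi_left, phi_right)
        for i, src in enumerate(sources):
            phi = phases[i] if phase_mode == "two_stim_orthogonal" else phi_left
            wave = np.sin(2 * np.pi * src.tag.frequency * t_eff + phi + src.extra_phase)
            trial += src.amplitude * np.outer(leadfields[i], wave * on)

        if noise.pink > 0:
            trial += noise.pink * _pink_noise(
                rng, array.n_channels, n_samples, sample_rate, noise.pink_exponent
            )
        if noise.alpha > 0:
            a_amp = noise.alpha * rng.uniform(0.5, 1.5)
            a_phase = rng.uniform(0.0, 2 * np.pi)
            trial += a_amp * np.outer(
                alpha_w, np.sin(2 * np.pi * noise.alpha_freq * times + a_phase)
            )
        if noise.line > 0:
            l_phase = rng.uniform(0.0, 2 * np.pi)
            trial += noise.line * np.sin(2 * np.pi * noise.line_freq * times + l_phase)[None, :]
        if noise.white > 0:
            trial += noise.white * rng.standard_normal((array.n_channels, n_samples))

        data[tr] = trial
        tag_values[tr] = analytic_tag_signal(
            freq, phi_left, sample_rate, n_samples, onset_index
        ).values
        displayed[tr] = np.sin(2 * np.pi * freq * t_eff + phi_left)
        light[tr] = np.where(on, 0.8 + 0.2 * displayed[tr], 0.0)

        scheduled = d0 + frame_grid
        actual = scheduled.copy()
        if stall_delay > 0:
            actual += stall_delay * (frame_grid >= stall_time)
        flip_logs.append(FlipLog(scheduled=scheduled, actual=actual))

        meta_rows.append(
            {
                "trial": tr,
                "condition": phase_mode,
                "n_stimuli": 2 if phase_mode == "two_stim_orthogonal" else 1,
                "tag_type": sources[0].tag.tag_type,
                "frequency": freq,
                "phase_left": phi_left,
                "phase_right": phi_right if phase_mode == "two_stim_orthogonal" else np.nan,
                "fixed_phase": phase_mode == "fixed",
                "extra_phase": sources[0].extra_phase,
                "apparatus_delay_s": d0,
                "stall_time_s": stall_time,
                "stall_delay_s": stall_delay,
            }
        )

    epochs = Epochs(
        data=data,
        sample_rate=sample_rate,
        epoch_window=epoch_window,
        trial_meta=pd.DataFrame(meta_rows),
    )
    tag = TrialTagSignals(
        values=tag_values,
        sample_rate=sample_rate,
        onset_index=onset_index,
        frequency=freq,
        phases=epochs.trial_meta["phase_left"].to_numpy(),
    )
    return SimulatedRun(
        epochs=epochs,
        tag=tag,
        light=light,
        flip_logs=flip_logs,
        displayed=displayed,
        array=array,
        head=head,
        sources=tuple(sources),
        leadfields=leadfields,
    )


def simulate_behavior(
    n_subjects: int = 12,
    n_trials_per_block: int = 50,
    true_accuracy: float = 0.5,
    between_subject_sd: float = 0.05,
    timeout_rate: float = 0.023,
    seed: int | None = None,
    conditions: Sequence[str] = BEHAVIOUR_CONDITIONS,
) -> pd.DataFrame:
    """Simulate AXB discrimination response tables.

    Per subject an accuracy is drawn from
    ``Normal(true_accuracy, between_subject_sd)`` truncated to (0, 1)
    and shared across blocks; each non-timeout trial is correct with
    that probability.  Timeouts are i.i.d. with ``timeout_rate`` and
    recorded with ``response_side == "none"``.  The correct side is
    balanced-random within each block.
    """
    if not 0.0 < true_accuracy < 1.0:
        raise ValueError("true_accuracy must lie in (0, 1)")
    if between_subject_sd < 0:
        raise ValueError("between_subject_sd must be nonnegative")
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    rng = np.random.default_rng(seed)

    rows = []
    for s in range(n_subjects):
        acc = true_accuracy
        if between_subject_sd > 0:
            while True:
                acc = rng.normal(true_accuracy, between_subject_sd)
                if 0.0 < acc < 1.0:
                    break
        for cond in conditions:
            n = n_trials_per_block
            correct_side = np.array(["left", "right"])[
                rng.permutation(np.arange(n) % 2)
            ]
            timeout = rng.uniform(size=n) < timeout_rate
            is_correct = rng.uniform(size=n) < acc
            other = np.where(correct_side == "left", "right", "left")
            response = np.where(is_correct, correct_side, other)
            response = np.where(timeout, "none", response)
            for i in range(n):
                rows.append(
                    {
                        "subject_id": f"S{s:02d}",
                        "block_condition": cond,
                        "correct_side": correct_side[i],
                        "response_side": response[i],
                        "timeout": bool(timeout[i]),
                    }
                )
    return pd.DataFrame(rows)
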