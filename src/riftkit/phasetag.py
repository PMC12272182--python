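"""Phase machinery for orthogonal-phase tagging.

Four steps disentangle two stimuli tagged at the same frequency but 90
degrees apart in phase:

1. :func:`phase_correct` removes each trial's (random) stimulation
   phase from the sensor Fourier coefficients by dividing out the
   tagging-signal coefficient's phase, so trials become averageable.
2. :func:`lag_profile` projects the trial-averaged corrected
   coefficients onto a grid of candidate phases (0..2*pi in steps of
   pi/16) and finds the phase lag at which the summed squared projected
   amplitude across channels (global field power) peaks -- the
   participant's tagging-to-brain phase lag.  The profile is
   pi-periodic (projections at phi and phi+pi differ only in sign), so
   the peak is reported in [0, pi).
3. :func:`disentangle_two_stim` corrects two-stimulus data by the
   *left* stimulus's tagging signal and projects the trial-averaged
   coefficients at the peak phase (left-stimulus topography) and at the
   peak phase + 90 degrees (right-stimulus topography).
4. The topographies go to :mod:`riftkit.dipole` for source modelling.

The estimated lag is meant to come from an independent single-stimulus
random-phase run of the same participant (a phase localizer), then be
applied to the two-stimulus run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectral import SpectralSet

__all__ = [
    "PHASE_GRID",
    "PhaseProfile",
    "PhaseTopographies",
    "phase_correct",
    "project_phase",
    "lag_profile",
    "disentangle_two_stim",
]

#: Candidate phase lags: 0 to 2*pi in steps of pi/16 (32 points).
PHASE_GRID = np.arange(32) * (np.pi / 16.0)


@dataclass(frozen=True)
class PhaseProfile:
    """Projected global field power per candidate phase lag.

    ``peak_phase`` is reported in [0, pi); the profile's pi-ambiguity
    (gfp(phi) == gfp(phi + pi)) means the lag is only identified up to
    a joint sign flip of the projected topographies, which flips fitted
    dipole moments but not positions.
    """

    phases: np.ndarray
    gfp: np.ndarray
    peak_phase: float
    degenerate: bool = False


@dataclass(frozen=True)
class PhaseTopographies:
    """Real per-channel amplitudes attributed to each stimulus."""

    topo_at_peak: np.ndarray           # left stimulus
    topo_at_peak_plus_90: np.ndarray   # right stimulus
    peak_phase: float


def phase_correct(
    spec: SpectralSet, foi: float = 60.0, tol: float = 1e-12
) -> np.ndarray:
    """Phase-corrected sensor coefficients at ``foi``, (trials, channels).

    Each trial's coefficients are multiplied by the unit conjugate of
    that trial's tagging coefficient, ``F * conj(G)/|G|`` -- equal to
    the division ``F / G`` up to a positive per-trial scale, so phases
    match exactly and magnitudes are preserved.  Trials whose tagging
    coefficient magnitude is below ``tol`` carry no usable phase and are
    dropped with a warning.
    """
    if spec.tag_coefficients is None:
        raise ValueError("SpectralSet has no tag coefficients")
    fidx = spec.freq_index(foi)
    F = spec.coefficients[:, :, fidx]
    G = spec.tag_coefficients[:, fidx]
    mag = np.abs(G)
    keep = mag > tol
    if not np.all(keep):
        warnings.warn(
            f"{int((~keep).sum())} trial(s) with near-zero tagging coefficient "
            "excluded from phase correction",
            stacklevel=2,
        )
    return F[keep] * (np.conj(G[keep]) / mag[keep])[:, None]


def project_phase(coeffs: np.ndarray, phi: float) -> np.ndarray:
    """Project complex coefficients onto a phase: Re{conj(F) e^{i phi}}."""
    return coeffs.real * np.cos(phi) + coeffs.imag * np.sin(phi)


def lag_profile(mean_coeffs: np.ndarray) -> PhaseProfile:
    """Global-field-power profile of the trial-averaged corrected coefficients.

    ``gfp(phi) = sum_k A_k(phi)^2`` over the 32-point phase grid; the
    peak phase (grid argmax, no interpolation) estimates the
    tagging-to-brain lag modulo pi.
    """
    mean_coeffs = np.asarray(mean_coeffs)
    if mean_coeffs.ndim != 1 or len(mean_coeffs) < 1:
        raise ValueError("mean_coeffs must be a per-channel complex vector")
    degenerate = not np.any(np.abs(mean_coeffs) > 0)
    if degenerate:
        warnings.warn("all-zero coefficients: degenerate lag profile", stacklevel=2)
    proj = project_phase(mean_coeffs[:, None], PHASE_GRID[None, :])
    gfp = np.sum(proj**2, axis=0)
    peak = float(PHASE_GRID[int(np.argmax(gfp))] % np.pi)
    return PhaseProfile(phases=PHASE_GRID.copy(), gfp=gfp, peak_phase=peak,
                        degenerate=degenerate)


def disentangle_two_stim(
    spec: SpectralSet, peak_phase: float, foi: float = 60.0
) -> PhaseTopographies:
    """Split two-stimulus orthogonal-phase data into per-stimulus topographies.

    ``spec`` must come from a two-stimulus run whose tag coefficients
    were computed from the *left* stimulus's tagging signal; by the
    design constraint the right stimulus is then 90 degrees ahead.
    Coefficients are phase-corrected, averaged over trials, and
    projected at ``peak_phase`` (left stimulus) and
    ``peak_phase + pi/2`` (right stimulus).
    """
    meta = spec.trial_meta
    if (
        meta.empty
        or "condition" not in meta
        or not (meta["condition"] == "two_stim_orthogonal").all()
        or "phase_left" not in meta
        or "phase_right" not in meta
        or meta["phase_right"].isna().any()
    ):
        raise ValueError(
            "spectral set lacks two_stim_orthogonal trial metadata "
            "(per-trial left/right phases)"
        )
    corrected = phase_correct(spec, foi)
    mean_coeffs = corrected.mean(axis=0)
    return PhaseTopographies(
        topo_at_peak=project_phase(mean_coeffs, peak_phase),
        topo_at_peak_plus_90=project_phase(mean_coeffs, peak_phase + np.pi / 2),
        peak_phase=float(peak_phase),
    )
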