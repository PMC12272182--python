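# Methods

This note documents the models, conventions, and design choices behind
riftkit, in the order data flow through the package.

## Conventions

All sinusoids are `sin(2*pi*f*t + phi)` with `t = 0` at stimulus
onset; phases are radians in `[0, 2*pi)`. Positions are mm in a
right-handed frame with the origin at the conductor-sphere center,
+x = right hemisphere, −y = posterior. Every stochastic function takes
an explicit seed; the pipeline derives per-stage seeds from a master
seed via `SeedSequence(master, spawn_key=(stage_index, item))`, so
stages can be rerun in isolation and whole runs are byte-reproducible.

## Tagging waveforms and the corrected tagging signal

Projector frames are frame starts at the frame rate (default 1440
frames/s) with zero-order hold; with `s = sin(2*pi*f*t + phi)` the four
protocols are type 1: white `0.5 + 0.5 s`, black 0; type 2: white
`0.75 + 0.25 s`, black 0; type 3: white `0.75 + 0.25 s`, black
`0.25 + 0.25 s` (constant contrast); type 4: white `0.75 + 0.25 s`,
black `0.25 − 0.25 s` (constant mean luminance). Over whole cycles the
type 1 white band averages 50 % and types 2–4 average 75 %.

The corrected tagging signal re-aligns the stored sinusoid to the
sample at which the light-sensor trace first exceeds a threshold
(default 0.5 of the trace maximum; the emulated sensor is idealized
monotone, so the crossing is the onset sample) and inserts a delay at
every flip that is late by more than 1 ms. "Late" is judged on the
*new* delay a flip introduces beyond what earlier flips already
accumulated — a projector stall shifts all subsequent flips equally,
and only the stall itself should insert a delay. Delays are quantized
to whole samples (ties down) and the gap is filled by holding the last
displayed sample, which is what a frozen frame looks like. Each
quantization contributes at most one sample (1.67 ms at 600 Hz) of
timing error.

## Synthetic MEG

Sensors are radial magnetometers on a Fibonacci-spiral spherical cap
(default 64 channels, helmet radius 110 mm, cap half-angle 115°)
around a homogeneous conducting sphere (radius 90 mm). Radial
magnetometers are used instead of axial gradiometers because the radial
field of a current dipole in a sphere has the closed form
`B_r = (r_q x Q) . r_hat / |r - r_q|^3` (volume currents contribute
nothing to it), which preserves the left/right topography logic the
analyses test at desk scale. Positions are in the synthetic head frame,
not true MNI space; the x > 0 = right convention is kept.

Tagged sources are tangential dipoles at (±20, −85, −5) mm near the
calcarine start point, driven by
`amplitude * sin(2*pi*f*t + phi_trial + delta)` from onset to the end
of the epoch, where `delta` is the participant's tagging-to-brain phase
lag. Leadfields are normalized to unit RMS across channels so
`amplitude` is the per-channel signal scale. The default amplitude
(0.02) was calibrated once so that 100 random-phase trials under the
default noise yield a brain-to-tagging coherence SNR of ~5 dB over the
posterior third of the sensors — the operating regime reported for real
recordings; it is not adjusted per analysis. Noise comprises per-channel
spectrally-shaped 1/f background (unit RMS times the `pink` amplitude),
a 10 Hz alpha sinusoid with random phase/amplitude per trial and
posterior channel weighting, 50 Hz common-mode line noise, and white
sensor noise. The no-tagging control and the null checks use source
amplitude 0.

Tagging-type comparisons use an assumed neural gain per type
(1.0 / 0.55 / 0.45 / 1.0 for types 1–4): full-amplitude luminance and
contrast modulation drive the strongest steady-state responses, the
half-amplitude variants are substantially weaker. This emulates the
empirical ordering; the generator makes no claim about its mechanism.

Apparatus imperfections are configurable and default off except in the
demo: a per-trial display-pipeline delay (uniform up to
`apparatus_jitter_ms`, demo default 2 ms) and projector stalls
(`stall_rate`, `stall_frames`). The light trace is
`0.8 + 0.2 * displayed` after the true onset and 0 before, so threshold
crossing recovers the onset exactly at sample resolution; the flip log
is scheduled-vs-actual flip times consistent with the stalls.

What the generator does **not** emulate: realistic anatomy and
single-shell conduction, gradiometry, eye/cardiac artifacts, head
motion, nonstationary noise, evoked transients, or any dependence of
the response on stimulus content. Passing tests therefore demonstrate
the correctness and internal consistency of the analysis chain under
the stated statistical structure, not robustness to real-data artifacts.

## Spectral analysis

Epochs are windowed to `[0.2, 1.2)` s after onset (600 samples at
600 Hz, 1 Hz resolution) and transformed with a flat (boxcar) taper;
coefficients are normalized by the window length. Power is the trial
mean of squared magnitudes. ITC excludes zero-magnitude bins from the
unit-vector mean (a bin with no valid trials is 0, with a warning).
Brain-to-tagging coherence is magnitude-weighted by default
(cross-spectrum normalized by auto-spectra); a phase-only variant — the
ITC of phase-corrected unit coefficients, weighting every trial
equally — is available via `tag_coherence(..., phase_only=True)`. Both
read "consistency of the brain-to-tagging phase difference"; the
magnitude-weighted form is the default because it is the standard
coherence estimator and downweights noise-dominated trials. No
trial-count bias correction is applied. The SNR statistic uses
base-10 log and neighbour bands inclusive of endpoints (8 bins at 1 Hz
spacing by default); sensor averaging defaults to the posterior third
of the array.

## Phase machinery

Phase correction multiplies each trial's coefficients by the unit
conjugate of its tagging coefficient (`F * conj(G)/|G|`), equal to the
division `F/G` up to a positive per-trial scale — phases are identical,
and magnitudes are preserved, which keeps the subsequent least-squares
geometry interpretable. The lag profile projects the *trial-averaged*
corrected coefficients onto 32 phases (projecting per-trial and
averaging is algebraically identical by linearity); the peak is the
grid argmax, no interpolation. Because projections at `phi` and
`phi + pi` differ only in sign, the profile is pi-periodic and the peak
is reported in `[0, pi)`. The unresolved pi-ambiguity jointly flips the
sign of both projected topographies, which flips fitted dipole
*moments*, never positions, so the Δx contrast is unaffected.

Two-stimulus runs are corrected by the **left** stimulus's tagging
signal (a convention; the design constraint then places the right
stimulus at +90°). The participant's lag is estimated on an
independent single-stimulus random-phase run and applied to the
two-stimulus run, mirroring the localizer-then-test protocol.

## Dipole fitting

The ECD fit searches position with Nelder–Mead (tolerance 1e−3 mm, 5
seeded restarts jittered 10 mm s.d. around the fixed start
(0, −88, −9) mm) while solving the tangential moment linearly at every
candidate; positions are kept inside 97 % of the sphere radius by a
quadratic penalty. Explained variance is
`r^2 = 1 − ||residual||^2 / ||topography||^2`. On noise-free forward
fields the round trip recovers positions to well under 1 mm. The KDE
difference map uses an isotropic Gaussian kernel (s.d. 15 mm) on a
lattice (default 5 mm), each density discretely normalized
(sum × voxel volume = 1) before subtraction.

## Hierarchical Bayesian models

*Logistic (AXB).* Response side (right = 1) ~ Bernoulli with logit
`alpha + alpha_s + (beta + beta_s) * x`, `x = ±0.5` the correct side.
With this coding, accuracy = logistic(beta/2) at zero intercept, so
`beta` isolates sensitivity from bias. Priors: Normal(0, 2.5) on
`alpha` and `beta` (the standard weakly-informative logit scale),
HalfNormal(1) on the random-effect s.d.s. Timeout trials are excluded
everywhere; subject-condition cells with ≤1 responded trial are dropped
from the accuracy *summary* only, never from the model.

*Gaussian (paired contrasts).* `y = mu + u_s + beta * x + eps` with
`x = ±0.5` coding the two conditions; priors auto-scale with the data
(Normal(0, 2.5·sd(y)) on coefficients, LogNormal(log sd(y), 1) on both
s.d.s — the log-normal keeps the posterior proper when residuals
degenerate to zero).

*Sampling.* Subject effects are marginalized — by 9-point-per-dimension
Gauss–Hermite quadrature in the logistic model, analytically in the
Gaussian one — and the 4-dimensional marginal posterior is sampled with
the emcee ensemble sampler (differential-evolution moves, default 32
walkers, 500 burn-in + 1000 kept iterations, fully seeded).
Marginalization makes each fit fast and removes the funnel geometry;
subject-effect posterior means are recovered afterwards from the
quadrature weights. The Gelman–Rubin r̂ is computed per parameter over
walker groups; since walkers interact, this r̂ is conservative, and
values above 1.01 raise a warning flag rather than being silently
accepted. Bulk simulation studies (sensitivity analysis, replicate
batteries) use reduced settings (24 walkers, 300 + 500), which
sometimes flag; the flags are recorded.

*Bayes factors.* Savage–Dickey density ratio at the point null:
posterior density at 0 from a Gaussian KDE of the draws over the prior
density at 0. When the posterior mass is far from 0 the KDE
underestimates the true tail density; BF01 is floored at 2^−50 and
flagged. Because prior scales and sampler settings influence the
absolute BF, Bayes factors are reproducible in order of magnitude, not
digit-for-digit, across reasonable prior choices.

*Sensitivity analysis.* For each true accuracy in 0.40–0.60 (step
0.01), response tables of the study's size (12 subjects × 50 trials,
between-subject s.d. 0.05, timeout rate 0.023) are simulated and
refit; the per-level BF01 median and IQR are summarized by a quadratic
in accuracy fit to median log2(BF01), whose vertex estimates where null
evidence peaks, and an inverse lookup maps an observed BF01 to the
accuracies whose median matches it. The between-subject s.d. of the
sensitivity simulation is a free parameter (0.05 default); the full
study uses 300 simulations per level, the test suite and acceptance
script use reduced counts (20 and 6) to keep runtimes in minutes —
enough for the curve's vertex, which is very stable, though individual
flank medians remain noisy.

## Numerical and degenerate-input behaviour

Frequency-of-interest and window bounds are validated against the
spectral grid; zero neighbour power raises rather than returning ±inf.
Phase correction drops (with a warning) trials whose tagging
coefficient magnitude is below tolerance; an all-zero lag profile is
flagged degenerate. The ECD fit refuses identically-zero topographies
and reports `converged=False` with the best-so-far solution instead of
raising on optimizer non-convergence. Log-posteriors return −inf
outside hard parameter ranges (|log sd| bounds) so the samplers cannot
wander into overflow.

## Known limitations

- The spherical-conductor frame is not MNI space; absolute positions
  and Δx magnitudes are internally consistent but not anatomically
  calibrated.
- ITC-based SNR at a null frequency bin is an inherently noisy
  statistic (its dispersion does not shrink with trial count, only with
  averaging over channels/participants); group-averaged spectra are
  used wherever it is reported.
- The behavioural sensitivity curve's extreme flanks depend on the KDE
  tail behaviour (see the BF floor above); its vertex and near-chance
  region do not.
- Apparatus jitter below one sample (1.67 ms) is invisible to the
  sample-quantized correction; the residual enters as a small constant
  coherence loss.
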