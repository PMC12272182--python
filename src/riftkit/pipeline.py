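"""Configuration, seed bookkeeping, and the end-to-end demonstration run.

:func:`run_demo` re-enacts the four analyses on synthetic data:

1. tagging-type comparison -- power and coherence SNR at 60 Hz for the
   four tagging types plus a no-tagging control;
2. phase randomization -- the 2x2 table of SNR by analysis method
   (ITC vs phase-corrected coherence) and stimulation phase
   (fixed vs random across trials);
3. orthogonal phase tagging -- per-participant lag estimation on a
   single-stimulus localizer, disentangling of a two-stimulus run,
   dipole fits, the left/right x-displacement contrast with a
   hierarchical Bayesian test, and a kernel-density difference map;
4. behaviour -- hierarchical logistic Bayes factors for the three AXB
   blocks simulated at chance accuracy, plus a reduced sensitivity
   curve.

Every stochastic stage receives its own seed derived from the master
seed through a fixed counter scheme (`SeedSequence(master,
spawn_key=(stage_index, item))`), so any stage can be rerun in
isolation.  CSV/JSON outputs are byte-reproducible for a given master
seed; figures and the timing log are non-normative.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dipole import HeadModel, dx_contrast, fit_ecd, kde_diff
from .inference import (
    MCMCConfig,
    accuracy_table,
    bayes_factor_01,
    fit_hier_linear,
    fit_hier_logistic,
    sensitivity_analysis,
)
from .phasetag import disentangle_two_stim, lag_profile, phase_correct
from .spectral import fft_boxcar, itc, power_spectrum, snr_db, tag_coherence
from .synthmeg import (
    BEHAVIOUR_CONDITIONS,
    DEFAULT_SOURCE_AMPLITUDE,
    NoiseConfig,
    SourceSpec,
    TaggingSpec,
    make_sensor_array,
    occipital_source,
    posterior_channels,
    simulate_behavior,
    simulate_epochs,
)
from .tagging import reconstruct_corrected_tag

__all__ = ["RunConfig", "SimulationConfig", "SpectralConfig", "DipoleConfig",
           "InferenceConfig", "stage_seed", "run_demo", "corrected_tag_values"]

#: Fixed stage indices for master-seed derivation.
STAGES = {
    "tagging_types": 0,
    "phase_randomization": 1,
    "phase_tagging": 2,
    "behaviour": 3,
    "sensitivity": 4,
}


def stage_seed(master: int, stage: str, item: int = 0) -> int:
    """Per-stage seed derived from the master seed by a counter scheme."""
    ss = np.random.SeedSequence(master, spawn_key=(STAGES[stage], item))
    return int(ss.generate_state(1)[0] % 2**31)


def _strict(cls, d: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return d


@dataclass(frozen=True)
class SimulationConfig:
    n_channels: int = 64
    helmet_radius: float = 110.0
    sphere_radius: float = 90.0
    source_amplitude: float = DEFAULT_SOURCE_AMPLITUDE
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    apparatus_jitter_ms: float = 2.0
    n_trials_fixed: int = 40
    n_trials_random: int = 60
    n_trials_two_stim: int = 60
    n_participants: int = 6

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(_strict(cls, d))
        if "noise" in d:
            d["noise"] = NoiseConfig(**_strict(NoiseConfig, d["noise"]))
        return cls(**d)


@dataclass(frozen=True)
class SpectralConfig:
    window: tuple[float, float] = (0.2, 1.2)
    foi: float = 60.0
    gap: float = 2.0
    halfwidth: float = 5.0
    channel_fraction: float = 1 / 3

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralConfig":
        d = dict(_strict(cls, d))
        if "window" in d:
            d["window"] = tuple(d["window"])
        return cls(**d)


@dataclass(frozen=True)
class DipoleConfig:
    start: tuple[float, float, float] = (0.0, -88.0, -9.0)
    n_restarts: int = 5
    kde_bandwidth: float = 15.0
    kde_grid_step: float = 10.0

    @classmethod
    def from_dict(cls, d: dict) -> "DipoleConfig":
        d = dict(_strict(cls, d))
        if "start" in d:
            d["start"] = tuple(d["start"])
        return cls(**d)


@dataclass(frozen=True)
class InferenceConfig:
    nwalkers: int = 32
    burn: int = 500
    draws: int = 1000
    n_subjects: int = 12
    n_trials_behaviour: int = 50
    between_subject_sd: float = 0.05
    timeout_rate: float = 0.023
    sensitivity_levels: tuple = (0.40, 0.45, 0.50, 0.55, 0.60)
    sensitivity_n_sims: int = 3

    @classmethod
    def from_dict(cls, d: dict) -> "InferenceConfig":
        d = dict(_strict(cls, d))
        if "sensitivity_levels" in d:
            d["sensitivity_levels"] = tuple(d["sensitivity_levels"])
        return cls(**d)

    def mcmc(self, seed: int) -> MCMCConfig:
        return MCMCConfig(seed=seed, nwalkers=self.nwalkers, burn=self.burn,
                          draws=self.draws)


@dataclass(frozen=True)
class RunConfig:
    """Master configuration for a demonstration run."""

    seed: int = 1
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    dipole: DipoleConfig = field(default_factory=DipoleConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(_strict(cls, d))
        for key, sub in (
            ("simulation", SimulationConfig),
            ("spectral", SpectralConfig),
            ("dipole", DipoleConfig),
            ("inference", InferenceConfig),
        ):
            if key in d:
                d[key] = sub.from_dict(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def corrected_tag_values(run) -> np.ndarray:
    """Reconstructed (corrected) tagging signal for every trial of a run."""
    return np.stack(
        [
            reconstruct_corrected_tag(
                run.tag.signal(t), run.light[t], run.flip_logs[t]
            ).values
            for t in range(run.epochs.n_trials)
        ]
    )


def _sensor_setup(cfg: SimulationConfig):
    array = make_sensor_array(
        cfg.n_channels, cfg.helmet_radius, cfg.sphere_radius, seed=0
    )
    return array, HeadModel(array=array, sphere_radius=cfg.sphere_radius)


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_demo(config: RunConfig, out_dir) -> dict:
    """Run the full synthetic re-enactment; returns the report dict.

    Writes CSV/JSON artifacts (reference outputs), PNG figures
    (non-normative), and a timing log to ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("riftkit.demo")
    if not log.handlers:
        log.addHandler(logging.StreamHandler())
        log.setLevel(logging.INFO)
    fh = logging.FileHandler(out / "run.log", mode="w")
    log.addHandler(fh)
    report: dict = {"version": __version__, "seed": config.seed}
    scfg, pcfg = config.simulation, config.spectral
    array, head = _sensor_setup(scfg)
    sel = posterior_channels(array, pcfg.channel_fraction)
    t_start = time.perf_counter()

    def _stage(name):
        log.info("stage %-22s t=%.1fs", name, time.perf_counter() - t_start)

    try:
        # -- 1. tagging types ------------------------------------------------
        _stage("tagging_types")
        rows = []
        for i, tag_type in enumerate([1, 2, 3, 4, 0]):
            from .synthmeg import TYPE_RESPONSE_GAIN

            amp = scfg.source_amplitude * TYPE_RESPONSE_GAIN[tag_type] if tag_type else 0.0
            tag = TaggingSpec(tag_type=tag_type or 1, frequency=pcfg.foi)
            src = occipital_source("right", amplitude=amp, extra_phase=0.7, tag=tag)
            run = simulate_epochs(
                [src], array, scfg.n_trials_fixed, noise=scfg.noise,
                phase_mode="fixed", seed=stage_seed(config.seed, "tagging_types", i),
            )
            spec = fft_boxcar(run.epochs, corrected_tag_values(run), window=pcfg.window)
            pw = power_spectrum(spec)[sel].mean(axis=0)
            coh = tag_coherence(spec)[sel].mean(axis=0)
            rows.append(
                {
                    "tag_type": "none" if tag_type == 0 else f"type{tag_type}",
                    "snr_power_db": snr_db(pw, spec.frequencies, pcfg.foi, pcfg.gap, pcfg.halfwidth),
                    "snr_coherence_db": snr_db(coh, spec.frequencies, pcfg.foi, pcfg.gap, pcfg.halfwidth),
                }
            )
        tagging_table = pd.DataFrame(rows)
        tagging_table.to_csv(out / "tagging_types_snr.csv", index=False)
        report["tagging_types"] = rows

        # -- 2. fixed vs random phase, ITC vs coherence ----------------------
        _stage("phase_randomization")
        rows = []
        for p in range(scfg.n_participants):
            lag = float(
                np.random.default_rng(
                    stage_seed(config.seed, "phase_randomization", 1000 + p)
                ).uniform(0, 2 * np.pi)
            )
            src = occipital_source("right", amplitude=scfg.source_amplitude, extra_phase=lag)
            for mode in ("fixed", "random"):
                run = simulate_epochs(
                    [src], array, scfg.n_trials_random, noise=scfg.noise,
                    phase_mode=mode,
                    seed=stage_seed(config.seed, "phase_randomization",
                                    2 * p + (mode == "random")),
                    apparatus_jitter_ms=scfg.apparatus_jitter_ms,
                )
                spec = fft_boxcar(run.epochs, corrected_tag_values(run), window=pcfg.window)
                rows.append(
                    {
                        "participant": p,
                        "phase_mode": mode,
                        "snr_itc_db": snr_db(itc(spec)[sel].mean(axis=0),
                                             spec.frequencies, pcfg.foi, pcfg.gap, pcfg.halfwidth),
                        "snr_coherence_db": snr_db(tag_coherence(spec)[sel].mean(axis=0),
                                                   spec.frequencies, pcfg.foi, pcfg.gap, pcfg.halfwidth),
                    }
                )
        two_by_two = pd.DataFrame(rows)
        two_by_two.to_csv(out / "phase_randomization_snr.csv", index=False)
        report["phase_randomization"] = {
            f"{meas}_{mode}": float(
                two_by_two[two_by_two["phase_mode"] == mode][f"snr_{meas}_db"].mean()
            )
            for meas in ("itc", "coherence")
            for mode in ("fixed", "random")
        }

        # -- 3. orthogonal phase tagging -------------------------------------
        _stage("phase_tagging")
        fits_left, fits_right, peak_rows = [], [], []
        for p in range(scfg.n_participants):
            lag = float(
                np.random.default_rng(
                    stage_seed(config.seed, "phase_tagging", 1000 + p)
                ).uniform(0, 2 * np.pi)
            )
            left_stim = occipital_source("right", amplitude=scfg.source_amplitude, extra_phase=lag)
            right_stim = occipital_source("left", amplitude=scfg.source_amplitude, extra_phase=lag)
            loc = simulate_epochs(
                [left_stim], array, scfg.n_trials_random, noise=scfg.noise,
                phase_mode="random", seed=stage_seed(config.seed, "phase_tagging", 2 * p),
            )
            spec_loc = fft_boxcar(loc.epochs, corrected_tag_values(loc), window=pcfg.window)
            profile = lag_profile(phase_correct(spec_loc, pcfg.foi).mean(axis=0))
            two = simulate_epochs(
                [left_stim, right_stim], array, scfg.n_trials_two_stim,
                noise=scfg.noise, phase_mode="two_stim_orthogonal",
                seed=stage_seed(config.seed, "phase_tagging", 2 * p + 1),
            )
            spec_two = fft_boxcar(two.epochs, corrected_tag_values(two), window=pcfg.window)
            topos = disentangle_two_stim(spec_two, profile.peak_phase, pcfg.foi)
            fits_left.append(fit_ecd(topos.topo_at_peak, head, start=config.dipole.start,
                                     n_restarts=config.dipole.n_restarts, seed=p))
            fits_right.append(fit_ecd(topos.topo_at_peak_plus_90, head,
                                      start=config.dipole.start,
                                      n_restarts=config.dipole.n_restarts, seed=p))
            peak_rows.append({"participant": p, "true_lag": lag,
                              "peak_phase": profile.peak_phase})
        dx_table, dx_summary = dx_contrast(fits_left, fits_right)
        dx_table.to_csv(out / "phase_tagging_dx.csv", index=False)
        x_long = pd.concat(
            [
                pd.DataFrame({"subject_id": dx_table["participant"],
                              "condition": "left_stim", "value": dx_table["x_left_stim"]}),
                pd.DataFrame({"subject_id": dx_table["participant"],
                              "condition": "right_stim", "value": dx_table["x_right_stim"]}),
            ]
        )
        _, dx_bf = fit_hier_linear(
            x_long, contrast=("right_stim", "left_stim"),
            mcmc=config.inference.mcmc(stage_seed(config.seed, "phase_tagging", 5000)),
        )
        dx_summary.update(
            {
                "bf10_dx": dx_bf.bf10,
                "mean_r_squared": float(np.mean([f.r_squared for f in fits_left + fits_right])),
            }
        )
        report["phase_tagging"] = dx_summary
        _json_dump(dx_summary, out / "phase_tagging_summary.json")
        kd = kde_diff(
            [f.position for f in fits_left], [f.position for f in fits_right],
            bandwidth=config.dipole.kde_bandwidth, grid_step=config.dipole.kde_grid_step,
        )
        kd.to_frame().to_csv(out / "kde_diff.csv", index=False)

        # -- 4. behaviour ----------------------------------------------------
        _stage("behaviour")
        icfg = config.inference
        table = simulate_behavior(
            n_subjects=icfg.n_subjects, n_trials_per_block=icfg.n_trials_behaviour,
            true_accuracy=0.5, between_subject_sd=icfg.between_subject_sd,
            timeout_rate=icfg.timeout_rate,
            seed=stage_seed(config.seed, "behaviour", 0),
        )
        accuracy_table(table).to_csv(out / "behaviour_accuracy.csv", index=False)
        behaviour = {}
        for i, cond in enumerate(BEHAVIOUR_CONDITIONS):
            post = fit_hier_logistic(
                table[table["block_condition"] == cond],
                mcmc=icfg.mcmc(stage_seed(config.seed, "behaviour", 1 + i)),
            )
            bf = bayes_factor_01(post)
            behaviour[cond] = {
                "bf01": bf.bf01,
                "beta_mean": post.mean("beta"),
                "beta_sd": post.sd("beta"),
                "max_rhat": max(post.rhat.values()),
            }
        _json_dump(behaviour, out / "behaviour_bf.json")
        report["behaviour"] = behaviour

        _stage("sensitivity")
        sens = sensitivity_analysis(
            grid=icfg.sensitivity_levels, n_sims=icfg.sensitivity_n_sims,
            n_subjects=icfg.n_subjects, n_trials=icfg.n_trials_behaviour,
            between_subject_sd=icfg.between_subject_sd, timeout_rate=icfg.timeout_rate,
            seed=stage_seed(config.seed, "sensitivity", 0),
        )
        sens.to_frame().to_csv(out / "sensitivity_curve.csv", index=False)
        report["sensitivity"] = {
            "vertex_accuracy": sens.vertex,
            "n_failures": sens.n_failures,
        }

        _json_dump(report, out / "report.json")
        _make_figures(out, tagging_table, two_by_two, dx_table, sens)
        _stage("done")
    except Exception as exc:  # echo the stage and config on failure
        log.error("demo failed: %s (config: %s)", exc, config.to_dict())
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
    return report


def _make_figures(out: Path, tagging_table, two_by_two, dx_table, sens) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    ax = axes[0]
    ax.bar(tagging_table["tag_type"], tagging_table["snr_coherence_db"])
    ax.set_ylabel("coherence SNR (dB)")
    ax.set_title("tagging types")
    ax = axes[1]
    for meas, marker in (("itc", "o"), ("coherence", "s")):
        means = two_by_two.groupby("phase_mode")[f"snr_{meas}_db"].mean()
        ax.plot(["fixed", "random"], means[["fixed", "random"]], marker=marker, label=meas)
    ax.legend()
    ax.set_ylabel("SNR (dB)")
    ax.set_title("phase randomization")
    ax = axes[2]
    ax.plot(sens.grid, np.log2(sens.median), "o-")
    ax.set_xlabel("true accuracy")
    ax.set_ylabel("log2 BF01")
    ax.set_title("sensitivity")
    fig.tight_layout()
    fig.savefig(out / "fig_overview.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 3.5))
    ax.scatter(np.zeros(len(dx_table)), dx_table["x_left_stim"], label="left stim")
    ax.scatter(np.ones(len(dx_table)), dx_table["x_right_stim"], label="right stim")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xticks([0, 1], ["left stim", "right stim"])
    ax.set_ylabel("fitted dipole x (mm)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "fig_dx.png", dpi=100)
    plt.close(fig)
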