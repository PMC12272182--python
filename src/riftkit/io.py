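"""HDF5 container round-tripping for epochs, tagging signals, and spectra.

The container layout::

    epochs/data   (trials, channels, time)   attrs: sample_rate, window
    epochs/time   (time,)
    tag/values    (trials, time)             attrs: frequency, sample_rate,
                                                    onset_index
    tag/phases    (trials,)
    light/trace   (trials, time)
    flips/scheduled, flips/actual  (trials, frames)
    meta          trial metadata, JSON-encoded pandas table

    spectra/coeffs     (trials, channels, freqs) complex
    spectra/freqs      (freqs,)
    spectra/tag_coeffs (trials, freqs) complex   attrs: window

The HDF5 container is the package's only binary format; tables and
report outputs are CSV/JSON.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import h5py
import numpy as np
import pandas as pd

from .spectral import SpectralSet
from .synthmeg import Epochs, TrialTagSignals
from .tagging import FlipLog

__all__ = ["Container", "save_container", "load_container", "save_spectra", "load_spectra"]


@dataclass(frozen=True)
class Container:
    epochs: Epochs
    tag: TrialTagSignals | None = None
    light: np.ndarray | None = None
    flip_logs: list | None = None


def _write_meta(h: h5py.File, meta: pd.DataFrame) -> None:
    h.create_dataset("meta", data=meta.to_json(orient="split"))


def _read_meta(h: h5py.File) -> pd.DataFrame:
    if "meta" not in h:
        return pd.DataFrame()
    raw = h["meta"][()]
    if isinstance(raw, bytes):
        raw = raw.decode()
    return pd.read_json(StringIO(raw), orient="split")


def save_container(path, epochs: Epochs, tag: TrialTagSignals | None = None,
                   light: np.ndarray | None = None, flip_logs=None) -> None:
    with h5py.File(path, "w") as h:
        g = h.create_group("epochs")
        g.create_dataset("data", data=epochs.data)
        g.create_dataset("time", data=epochs.times)
        g.attrs["sample_rate"] = epochs.sample_rate
        g.attrs["window"] = epochs.epoch_window
        if tag is not None:
            gt = h.create_group("tag")
            gt.create_dataset("values", data=tag.values)
            gt.create_dataset("phases", data=tag.phases)
            gt.attrs["frequency"] = tag.frequency
            gt.attrs["sample_rate"] = tag.sample_rate
            gt.attrs["onset_index"] = tag.onset_index
        if light is not None:
            h.create_group("light").create_dataset("trace", data=light)
        if flip_logs:
            gf = h.create_group("flips")
            gf.create_dataset("scheduled", data=np.stack([f.scheduled for f in flip_logs]))
            gf.create_dataset("actual", data=np.stack([f.actual for f in flip_logs]))
        _write_meta(h, epochs.trial_meta)


def load_container(path) -> Container:
    with h5py.File(path, "r") as h:
        g = h["epochs"]
        epochs = Epochs(
            data=g["data"][()],
            sample_rate=float(g.attrs["sample_rate"]),
            epoch_window=tuple(g.attrs["window"]),
            trial_meta=_read_meta(h),
        )
        tag = None
        if "tag" in h:
            gt = h["tag"]
            tag = TrialTagSignals(
                values=gt["values"][()],
                sample_rate=float(gt.attrs["sample_rate"]),
                onset_index=int(gt.attrs["onset_index"]),
                frequency=float(gt.attrs["frequency"]),
                phases=gt["phases"][()],
            )
        light = h["light/trace"][()] if "light" in h else None
        flip_logs = None
        if "flips" in h:
            sched = h["flips/scheduled"][()]
            act = h["flips/actual"][()]
            flip_logs = [FlipLog(scheduled=s, actual=a) for s, a in zip(sched, act)]
    return Container(epochs=epochs, tag=tag, light=light, flip_logs=flip_logs)


def save_spectra(path, spec: SpectralSet) -> None:
    with h5py.File(path, "w") as h:
        g = h.create_group("spectra")
        g.create_dataset("coeffs", data=spec.coefficients)
        g.create_dataset("freqs", data=spec.frequencies)
        if spec.tag_coefficients is not None:
            g.create_dataset("tag_coeffs", data=spec.tag_coefficients)
        g.attrs["window"] = spec.window
        _write_meta(h, spec.trial_meta)


def load_spectra(path) -> SpectralSet:
    with h5py.File(path, "r") as h:
        g = h["spectra"]
        return SpectralSet(
            coefficients=g["coeffs"][()],
            frequencies=g["freqs"][()],
            window=tuple(g.attrs["window"]),
            tag_coefficients=g["tag_coeffs"][()] if "tag_coeffs" in g else None,
            trial_meta=_read_meta(h),
        )
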