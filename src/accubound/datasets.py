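"""Synthetic MEG-like trial datasets generated from known Langevin models.

The generator emulates the structure of a button-press experiment recorded
by magnetometers: per-subject sets of trial epochs (default 3 s at 250 Hz,
i.e. 750 samples) whose within-trial dynamics follow a ground-truth
polynomial Langevin equation, mapped to Tesla through an amplitude scale
and per-channel gains.  Because the ground truth is known, every
reconstruction, selection, simulation and spectral stage of the package can
be validated end to end without access to recorded data.

Trials are integrated by Euler–Maruyama with one step per sample: the point
is to produce data carrying the assumed Markovian structure at the
recording resolution, not to be a high-accuracy SDE solver.

Randomness is counter-based: each (subject, channel, trial) owns a
substream derived from the master seed, so any single trial can be
regenerated independently of iteration order.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._kernels import em_path
from .langevin import LangevinModel

__all__ = [
    "GroundTruthConfig",
    "TrialEpoch",
    "TrialDataset",
    "generate_trial",
    "generate_dataset",
    "generate_ig_wt_sample",
    "save_dataset",
    "load_dataset",
]


@dataclass
class GroundTruthConfig:
    """Ground truth and bookkeeping for one synthetic dataset.

    ``drift_coeffs`` / ``noise_coeffs`` are highest-degree-first polynomial
    coefficients of the Langevin equation dz/dt = P_G(z) + P_H(z)Γ(t) in
    model units.  ``amplitude_scale`` maps model units to Tesla; the default
    1e-13 makes order-1 dynamics appear as ~100 fT signals, the inverse of
    the evidence convention z = 1e13 · x.
    """

    drift_coeffs: Sequence[float] = (-0.29, 1.43)
    noise_coeffs: Sequence[float] = (1.78,)
    n_subjects: int = 1
    n_trials: int = 60
    n_channels: int = 1
    fs: float = 250.0
    epoch_duration: float = 3.0
    event_latency: float = 2.5
    amplitude_scale: float = 1e-13
    channel_gain_profile: Sequence[float] | None = None
    seed: int = 0
    z0: float = 0.0
    #: drive every channel of a trial with the same noise stream (then
    #: channels differ only by gain); default: independent streams
    common_noise: bool = False
    #: add a deterministic ramp-and-collapse event-related template
    #: (linear rise to the event, 0.5 s linear decay after), model units
    erf_template: bool = False
    erf_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.epoch_duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_duration*fs must be an integer sample count")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")
        if self.n_subjects < 1 or self.n_trials < 1 or self.n_channels < 1:
            raise ValueError("n_subjects, n_trials and n_channels must be >= 1")
        if not 0 <= self.event_latency <= self.epoch_duration:
            raise ValueError("event_latency must lie inside the epoch")
        if self.channel_gain_profile is None:
            self.channel_gain_profile = tuple([1.0] * self.n_channels)
        elif len(self.channel_gain_profile) != self.n_channels:
            raise ValueError("channel_gain_profile length must equal n_channels")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_duration * self.fs))

    @property
    def t0_index(self) -> int:
        return int(round(self.event_latency * self.fs))

    def ground_truth_model(self) -> LangevinModel:
        return LangevinModel(self.drift_coeffs, self.noise_coeffs,
                             state_units="model",
                             provenance={"source": "synthetic ground truth"})

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        for k in ("drift_coeffs", "noise_coeffs", "channel_gain_profile"):
            d[k] = list(map(float, d[k]))
        return d


@dataclass
class TrialEpoch:
    """One channel's samples for one trial, aligned to the event at t0_index."""

    subject_id: str
    channel_id: str
    trial_index: int
    samples: np.ndarray
    fs: float
    t0_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("epoch contains non-finite samples")
        # t0_index == len(samples) is allowed: cropping a purely pre-event
        # window leaves the event on the right edge
        if not 0 <= self.t0_index <= len(self.samples):
            raise ValueError("t0_index outside the epoch")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the event."""
        return (np.arange(self.n_samples) - self.t0_index) / self.fs

    def crop(self, start: float, end: float) -> "TrialEpoch":
        """Half-open window [start, end) in seconds relative to the event."""
        i0 = self.t0_index + int(round(start * self.fs))
        i1 = self.t0_index + int(round(end * self.fs))
        if i0 < 0 or i1 > self.n_samples or i1 <= i0:
            raise ValueError(
                f"window [{start}, {end}) s maps to samples [{i0}, {i1}) "
                f"outside the epoch of {self.n_samples} samples")
        return TrialEpoch(self.subject_id, self.channel_id, self.trial_index,
                          self.samples[i0:i1], self.fs, self.t0_index - i0)


class TrialDataset:
    """A flat collection of :class:`TrialEpoch` with uniform fs and length."""

    def __init__(self, epochs: Iterable[TrialEpoch], units: str = "T",
                 config: GroundTruthConfig | None = None):
        self.epochs = list(epochs)
        if not self.epochs:
            raise ValueError("dataset must contain at least one epoch")
        fs = {e.fs for e in self.epochs}
        ns = {e.n_samples for e in self.epochs}
        t0 = {e.t0_index for e in self.epochs}
        if len(fs) > 1 or len(ns) > 1 or len(t0) > 1:
            raise ValueError("epochs must share fs, length and event alignment")
        keys = [(e.subject_id, e.channel_id, e.trial_index) for e in self.epochs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (subject, channel, trial) epoch")
        self.units = units
        self.config = config

    @property
    def fs(self) -> float:
        return self.epochs[0].fs

    @property
    def n_samples(self) -> int:
        return self.epochs[0].n_samples

    @property
    def t0_index(self) -> int:
        return self.epochs[0].t0_index

    @property
    def subjects(self) -> list[str]:
        return sorted({e.subject_id for e in self.epochs})

    def channels(self, subject_id: str | None = None) -> list[str]:
        eps = self.epochs if subject_id is None else \
            [e for e in self.epochs if e.subject_id == subject_id]
        return sorted({e.channel_id for e in eps})

    def select(self, subject_id: str | None = None,
               channel_id: str | None = None) -> list[TrialEpoch]:
        out = [e for e in self.epochs
               if (subject_id is None or e.subject_id == subject_id)
               and (channel_id is None or e.channel_id == channel_id)]
        return sorted(out, key=lambda e: e.trial_index)

    def __len__(self) -> int:
        return len(self.epochs)


# ---------------------------------------------------------------------------
# generation


def _trial_rng(config: GroundTruthConfig, subject: int, channel: int,
               trial: int) -> np.random.Generator:
    chan_key = 0 if config.common_noise else channel + 1
    return np.random.default_rng(
        [int(config.seed), int(subject), int(chan_key), int(trial)])


def _erf_template(config: GroundTruthConfig) -> np.ndarray:
    t = (np.arange(config.n_samples) - config.t0_index) / config.fs
    tpl = np.zeros_like(t)
    rise = t <= 0
    if config.event_latency > 0:
        tpl[rise] = config.erf_amplitude * (1 + t[rise] / config.event_latency)
    decay = (t > 0) & (t < 0.5)
    tpl[decay] = config.erf_amplitude * (1 - t[decay] / 0.5)
    return tpl


def generate_trial(config: GroundTruthConfig, channel: int, trial: int,
                   subject: int = 0,
                   rng: np.random.Generator | None = None) -> TrialEpoch:
    """Simulate one epoch of the ground-truth Langevin process.

    The state z is integrated with one Euler–Maruyama step per sample
    (Itô convention, Δt = 1/fs) and mapped to Tesla by
    ``amplitude_scale * channel_gain``.
    """
    if not 0 <= channel < config.n_channels:
        raise ValueError(f"channel {channel} outside 0..{config.n_channels - 1}")
    if rng is None:
        rng = _trial_rng(config, subject, channel, trial)
    n = config.n_samples
    dt = 1.0 / config.fs
    normals = rng.standard_normal(n - 1)
    z = np.empty(n)
    # generation clamps h at 0 (not the simulation noise floor) so that a
    # zero noise polynomial yields exactly deterministic paths
    bad = em_path(config.z0,
                  np.asarray(config.drift_coeffs, dtype=float),
                  np.asarray(config.noise_coeffs, dtype=float),
                  dt, normals, 0.0, z)
    if bad >= 0:
        raise FloatingPointError(
            f"non-finite state at integration step {bad} "
            f"(subject {subject}, channel {channel}, trial {trial})")
    if config.erf_template:
        z = z + _erf_template(config)
    gain = config.channel_gain_profile[channel]
    samples = config.amplitude_scale * gain * z
    return TrialEpoch(subject_id=f"sub{subject:02d}",
                      channel_id=f"ch{channel:03d}",
                      trial_index=trial,
                      samples=samples,
                      fs=config.fs,
                      t0_index=config.t0_index)


def generate_dataset(config: GroundTruthConfig) -> TrialDataset:
    """All n_subjects × n_channels × n_trials epochs, reproducible from seed."""
    epochs = [
        generate_trial(config, channel=c, trial=t, subject=s)
        for s in range(config.n_subjects)
        for c in range(config.n_channels)
        for t in range(config.n_trials)
    ]
    return TrialDataset(epochs, units="T", config=config)


def generate_ig_wt_sample(mu: float, lam: float, n: int,
                          rng: np.random.Generator | int | None = None):
    """Draw n inverse-Gaussian(μ, λ) waiting times (for testing the fitters)."""
    from scipy import stats

    from .simulate import WTSample

    if mu <= 0 or lam <= 0:
        raise ValueError("mu and lam must be positive")
    if n < 2:
        raise ValueError("need n >= 2")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    w = stats.invgauss.rvs(mu / lam, scale=lam, size=n, random_state=rng)
    return WTSample(waiting_times=np.asarray(w, dtype=float), n_censored=0,
                    provenance={"source": "inverse-gaussian sampler",
                                "mu": float(mu), "lam": float(lam)})


# ---------------------------------------------------------------------------
# container I/O: one CSV matrix per subject-channel (rows = samples,
# columns = trials) plus one JSON sidecar per dataset; or a single HDF5 file
# with groups subject/channel and trials×samples datasets.

_SIDECAR = "dataset.json"


def save_dataset(dataset: TrialDataset, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    window = (-dataset.t0_index / dataset.fs,
              (dataset.n_samples - dataset.t0_index) / dataset.fs)
    meta = {
        "fs": dataset.fs,
        "units": dataset.units,
        "t0_index": dataset.t0_index,
        "n_samples": dataset.n_samples,
        "epoch_window_s": list(window),
        "subjects": dataset.subjects,
        "channels": {s: dataset.channels(s) for s in dataset.subjects},
        "ground_truth": None if dataset.config is None else dataset.config.to_dict(),
    }
    with open(os.path.join(out_dir, _SIDECAR), "w") as fh:
        json.dump(meta, fh, indent=2)
    for s in dataset.subjects:
        for c in dataset.channels(s):
            eps = dataset.select(s, c)
            mat = np.column_stack([e.samples for e in eps])
            df = pd.DataFrame(mat, columns=[f"trial{e.trial_index}" for e in eps])
            # %.17g keeps doubles bit-exact through the text roundtrip
            df.to_csv(os.path.join(out_dir, f"{s}_{c}.csv"), index=False,
                      float_format="%.17g")


def save_dataset_hdf5(dataset: TrialDataset, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["fs"] = dataset.fs
        fh.attrs["units"] = dataset.units
        fh.attrs["t0_index"] = dataset.t0_index
        for s in dataset.subjects:
            grp = fh.create_group(s)
            for c in dataset.channels(s):
                eps = dataset.select(s, c)
                grp.create_dataset(c, data=np.stack([e.samples for e in eps]))


def load_dataset(path: str) -> TrialDataset:
    """Read either the CSV+JSON directory layout or a single HDF5 file."""
    if os.path.isdir(path):
        return _load_csv_dir(path)
    return _load_hdf5(path)


def _load_csv_dir(in_dir: str) -> TrialDataset:
    with open(os.path.join(in_dir, _SIDECAR)) as fh:
        meta = json.load(fh)
    fs, t0 = meta["fs"], meta["t0_index"]
    config = None
    if meta.get("ground_truth"):
        config = GroundTruthConfig(**meta["ground_truth"])
    epochs = []
    for s in meta["subjects"]:
        for c in meta["channels"][s]:
            df = pd.read_csv(os.path.join(in_dir, f"{s}_{c}.csv"),
                             float_precision="round_trip")
            for col in df.columns:
                idx = int(col.removeprefix("trial"))
                epochs.append(TrialEpoch(s, c, idx, df[col].to_numpy(), fs, t0))
    return TrialDataset(epochs, units=meta.get("units", "T"), config=config)


def _load_hdf5(path: str) -> TrialDataset:
    import h5py

    epochs = []
    with h5py.File(path, "r") as fh:
        fs = float(fh.attrs["fs"])
        t0 = int(fh.attrs["t0_index"])
        units = str(fh.attrs.get("units", "T"))
        for s in fh:
            for c in fh[s]:
                mat = fh[s][c][()]
                for t in range(mat.shape[0]):
                    epochs.append(TrialEpoch(s, c, t, mat[t], fs, t0))
    return TrialDataset(epochs, units=units)
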