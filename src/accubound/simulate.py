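"""Integration-to-bound first-passage simulation.

The accumulated-evidence model dz/dt = P_G(z) + P_H(z)Γ(t) is integrated by
Euler–Maruyama (Itô convention) from z(0) = z0 with a constant step dt
(default 2^-8 s).  A run's waiting time is the first time its crossing
criterion holds at threshold β:

``band``
    |z − β| < band_halfwidth (default 0.01) — the reproduction default.
    Note that with noise amplitudes of order 1 and dt = 2^-8 the per-step
    increment (≈ h/16) is much wider than the 0.02 band, so a path can jump
    the band and be detected only on a later revisit; the band rule
    therefore reports systematically longer waiting times than the
    continuous-time first passage.
``upcross``
    z ≥ β — the conventional absorbing-bound first passage.

Runs that never satisfy the criterion before ``t_max`` are censored:
counted, but excluded from the waiting-time sample.

Each run draws its noise from a substream keyed by (seed, run_index), so
results are reproducible run-by-run and independent of n_runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._kernels import first_passage_kernel
from .langevin import NOISE_FLOOR, LangevinModel

__all__ = ["SimConfig", "WTSample", "step", "first_passage", "simulate_wt_sample"]

_BLOCK = 4096  # normals drawn per chunk; fixed so streams never reshuffle


@dataclass
class SimConfig:
    """Euler–Maruyama settings for first-passage simulation."""

    dt: float = 2.0 ** -8
    z0: float = 0.0
    n_runs: int = 100
    t_max: float = 60.0
    criterion: str = "band"
    band_halfwidth: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_max <= self.dt:
            raise ValueError("t_max must exceed dt")
        if self.band_halfwidth <= 0:
            raise ValueError("band_halfwidth must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.criterion not in ("band", "upcross"):
            raise ValueError("criterion must be 'band' or 'upcross'")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max / self.dt))


@dataclass
class WTSample:
    """First-passage waiting times plus censoring bookkeeping."""

    waiting_times: np.ndarray
    n_censored: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.waiting_times = np.asarray(self.waiting_times, dtype=float)

    @property
    def n_runs(self) -> int:
        return len(self.waiting_times) + self.n_censored

    def save_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# waiting times (s); censored={self.n_censored}\n")
            for w in self.waiting_times:
                fh.write(f"{float(w)!r}\n")

    @classmethod
    def load_csv(cls, path) -> "WTSample":
        censored = 0
        wts = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "censored=" in line:
                        censored = int(line.split("censored=")[1].split()[0])
                    continue
                wts.append(float(line))
        return cls(np.asarray(wts), n_censored=censored)


def step(z: float, model: LangevinModel, dt: float, gaussian_draw: float) -> float:
    """One Euler–Maruyama step: z + g(z)dt + max(h(z), ε)·sqrt(dt)·N."""
    out = z + model.drift(z) * dt + model.clamped_noise(z) * np.sqrt(dt) * gaussian_draw
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(f"non-finite state from z={z}, draw={gaussian_draw}")
    return out


def first_passage(model: LangevinModel, beta: float, config: SimConfig,
                  run_index: int = 0) -> tuple[float | None, bool]:
    """Waiting time of one run; ``(wt, censored)`` with wt None if censored."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    rng = np.random.default_rng([int(config.seed), int(run_index)])
    g = np.asarray(model.drift_coeffs, dtype=float)
    h = np.asarray(model.noise_coeffs, dtype=float)
    use_band = config.criterion == "band"
    z = config.z0
    done = 0
    while done < config.n_steps:
        n_block = min(_BLOCK, config.n_steps - done)
        normals = rng.standard_normal(n_block)
        k, z, status = first_passage_kernel(
            z, g, h, config.dt, normals, NOISE_FLOOR,
            float(beta), config.band_halfwidth, use_band, done)
        if status == -1:
            raise FloatingPointError(
                f"non-finite state at step {k} of run {run_index}")
        if status == 1:
            return k * config.dt, False
        done = k
    return None, True


def simulate_wt_sample(model: LangevinModel, beta: float,
                       config: SimConfig | None = None) -> WTSample:
    """First-passage times of ``config.n_runs`` independent runs."""
    if config is None:
        config = SimConfig()
    wts = []
    censored = 0
    for r in range(config.n_runs):
        wt, cens = first_passage(model, beta, config, run_index=r)
        if cens:
            censored += 1
        else:
            wts.append(wt)
    if not wts:
        raise RuntimeError(
            f"all {config.n_runs} runs censored at beta={beta}; "
            "increase t_max or choose a different threshold")
    return WTSample(
        waiting_times=np.asarray(wts),
        n_censored=censored,
        provenance={"beta": float(beta), "dt": config.dt, "z0": config.z0,
                    "criterion": config.criterion,
                    "band_halfwidth": config.band_halfwidth,
                    "t_max": config.t_max, "seed": config.seed,
                    "n_runs": config.n_runs,
                    "model": model.to_dict()})
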