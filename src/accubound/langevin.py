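"""Polynomial Langevin models dz/dt = P_G(z) + P_H(z) Γ(t).

The deterministic part (drift) ``P_G`` and the noise amplitude ``P_H`` are
ordinary polynomials in the state variable; Γ(t) is Gaussian white noise
with <Γ(t)Γ(t')> = δ(t−t').  The leaky stochastic accumulator (LSA) is the
special case G = 1, H = 0 (Ornstein–Uhlenbeck drift ``az + b`` with constant
noise); the nonlinear generalization used for MEG-derived evidence
accumulation has G = 3, H = 2.

Coefficient lists are highest-degree-first throughout, e.g. a cubic drift
``a z^3 + b z^2 + c z + d`` is ``[a, b, c, d]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["LangevinModel", "NOISE_FLOOR"]

#: lower clamp applied to the noise amplitude during simulation so the SDE
#: stays well defined when a fitted h(z) dips to or below zero (model units)
NOISE_FLOOR = 1e-6


@dataclass
class LangevinModel:
    """A time-homogeneous polynomial Langevin equation.

    Parameters
    ----------
    drift_coeffs : sequence of float
        Coefficients of the drift polynomial g(z), highest degree first.
    noise_coeffs : sequence of float
        Coefficients of the noise-amplitude polynomial h(z), highest degree
        first.  h(z) is the square root of the Fokker–Planck diffusion
        coefficient: D2(z) = h(z)^2.
    state_units : str
        Label for the state variable ("model" for dimensionless evidence,
        "T" when the state is a magnetic field).
    state_range : tuple or None
        Interval of state values over which the fit is supported.
    provenance : dict
        Free-form record: reconstruction mode, source identifiers, scale
        factors applied at I/O boundaries.
    """

    drift_coeffs: Sequence[float]
    noise_coeffs: Sequence[float]
    state_units: str = "model"
    state_range: tuple[float, float] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.drift_coeffs = np.atleast_1d(np.asarray(self.drift_coeffs, dtype=float))
        self.noise_coeffs = np.atleast_1d(np.asarray(self.noise_coeffs, dtype=float))
        if self.drift_coeffs.ndim != 1 or self.noise_coeffs.ndim != 1:
            raise ValueError("coefficient arrays must be one-dimensional")
        if not (np.all(np.isfinite(self.drift_coeffs)) and np.all(np.isfinite(self.noise_coeffs))):
            raise ValueError("non-finite Langevin coefficients")

    @property
    def degree_g(self) -> int:
        return len(self.drift_coeffs) - 1

    @property
    def degree_h(self) -> int:
        return len(self.noise_coeffs) - 1

    def drift(self, z):
        """Evaluate g(z)."""
        return np.polyval(self.drift_coeffs, z)

    def noise(self, z):
        """Evaluate h(z) (no positivity clamp; see :func:`clamped_noise`)."""
        return np.polyval(self.noise_coeffs, z)

    def clamped_noise(self, z):
        """h(z) clamped below at ``NOISE_FLOOR``, as used by simulation."""
        return np.maximum(self.noise(z), NOISE_FLOOR)

    def noise_is_positive(self, lo: float | None = None, hi: float | None = None,
                          n_grid: int = 512) -> bool:
        """Whether h(z) > 0 on [lo, hi] (defaults to ``state_range``)."""
        if lo is None or hi is None:
            if self.state_range is None:
                raise ValueError("no state_range available for positivity check")
            lo, hi = self.state_range
        grid = np.linspace(lo, hi, n_grid)
        return bool(np.all(self.noise(grid) > 0))

    # ---- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "drift_coeffs": list(map(float, self.drift_coeffs)),
            "noise_coeffs": list(map(float, self.noise_coeffs)),
            "degree_g": self.degree_g,
            "degree_h": self.degree_h,
            "state_units": self.state_units,
            "state_range": None if self.state_range is None else list(self.state_range),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LangevinModel":
        rng = d.get("state_range")
        return cls(
            drift_coeffs=d["drift_coeffs"],
            noise_coeffs=d["noise_coeffs"],
            state_units=d.get("state_units", "model"),
            state_range=None if rng is None else tuple(rng),
            provenance=d.get("provenance", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "LangevinModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g = np.poly1d(self.drift_coeffs).__str__().splitlines()[-1].strip()
        h = np.poly1d(self.noise_coeffs).__str__().splitlines()[-1].strip()
        return f"LangevinModel(g(z) = {g}, h(z) = {h})"
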