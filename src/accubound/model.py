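"""Model/Results interface for Langevin reconstruction.

:class:`LangevinReconstruction` is built from epoch data and, on
``fit()``, returns a :class:`LangevinResults` carrying the estimated
polynomial coefficients, bootstrap standard errors (over trials, where the
mode permits), diagnostics (the binned moment fields), and a ``summary()``
table.  First-passage simulation and threshold optimization hang off the
results object, so the full chain

    data → reconstructed SDE → waiting-time distribution → threshold fit

reads as fit-then-use, in the style of statistical modelling packages.
"""

from __future__ import annotations

import io
from typing import Sequence

import numpy as np

from . import km
from .datasets import TrialDataset, TrialEpoch
from .langevin import LangevinModel
from .simulate import SimConfig, WTSample, simulate_wt_sample
from .wt import ThresholdScan, fit_inverse_gaussian, optimize_threshold

__all__ = ["LangevinReconstruction", "LangevinResults"]


class LangevinReconstruction:
    """Kramers–Moyal reconstruction of a polynomial Langevin equation.

    Parameters
    ----------
    data : TrialDataset or sequence of TrialEpoch
    mode : "concatenated", "single_trial" or "pooled"
    degrees : (G, H) drift / noise polynomial degrees
    window : optional (start, end) seconds relative to the event
    scale : factor applied to samples before estimation (evidence units)
    n_bins, taus : moment-binning settings (see :mod:`accubound.km`)
    """

    def __init__(self, data, mode: str = "concatenated",
                 degrees: tuple[int, int] = (1, 2),
                 window: tuple[float, float] | None = None,
                 scale: float = 1.0,
                 n_bins: int = km.DEFAULT_N_BINS,
                 taus: Sequence[float] | None = None):
        if isinstance(data, TrialDataset):
            self.epochs = data.select()
        else:
            self.epochs = list(data)
        if not self.epochs:
            raise ValueError("no epochs supplied")
        if mode not in ("concatenated", "single_trial", "pooled"):
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.degrees = tuple(degrees)
        self.window = window
        self.scale = scale
        self.n_bins = n_bins
        self.taus = taus

    @classmethod
    def from_dataset(cls, dataset: TrialDataset, subject_id: str | None = None,
                     channel_id: str | None = None, **kwargs):
        return cls(dataset.select(subject_id, channel_id), **kwargs)

    def fit(self) -> "LangevinResults":
        result = km.reconstruct(self.epochs, mode=self.mode,
                                degrees=self.degrees, window=self.window,
                                n_bins=self.n_bins, taus=self.taus,
                                scale=self.scale)
        if self.mode == "single_trial":
            return LangevinResults(self, models=result)
        return LangevinResults(self, models=[result])


class LangevinResults:
    """Fitted Langevin equation(s) with diagnostics and downstream tools."""

    def __init__(self, model: LangevinReconstruction,
                 models: list[LangevinModel]):
        self.model = model
        self.models = models

    @property
    def langevin(self) -> LangevinModel:
        """The single fitted equation (first trial's, in single_trial mode)."""
        return self.models[0]

    @property
    def params(self) -> np.ndarray:
        """Drift then noise coefficients, highest degree first."""
        m = self.langevin
        return np.concatenate([m.drift_coeffs, m.noise_coeffs])

    @property
    def param_names(self) -> list[str]:
        G, H = self.model.degrees
        return [f"g{G - i}" for i in range(G + 1)] + \
               [f"h{H - i}" for i in range(H + 1)]

    def bse(self, n_boot: int = 200, seed: int = 0) -> np.ndarray:
        """Bootstrap-over-trials standard errors of the coefficients.

        Only meaningful for concatenated/pooled fits with several trials;
        NaN otherwise.
        """
        if self.model.mode == "single_trial" or len(self.model.epochs) < 2:
            return np.full(len(self.params), np.nan)
        rng = np.random.default_rng(seed)
        eps = self.model.epochs
        draws = []
        for _ in range(n_boot):
            idx = rng.integers(len(eps), size=len(eps))
            res = km.reconstruct([eps[i] for i in idx], mode=self.model.mode,
                                 degrees=self.model.degrees,
                                 window=self.model.window,
                                 n_bins=self.model.n_bins,
                                 taus=self.model.taus,
                                 scale=self.model.scale)
            draws.append(np.concatenate([res.drift_coeffs, res.noise_coeffs]))
        return np.std(np.asarray(draws), axis=0, ddof=1)

    def summary(self, bse: bool = False) -> str:
        m = self.langevin
        buf = io.StringIO()
        G, H = self.model.degrees
        buf.write("Langevin reconstruction results\n")
        buf.write("=" * 46 + "\n")
        buf.write(f"mode: {self.model.mode}   degrees: G={G}, H={H}\n")
        buf.write(f"trials: {len(self.model.epochs)}   "
                  f"scale: {self.model.scale:g}\n")
        if m.state_range is not None:
            buf.write(f"state range: [{m.state_range[0]:.4g}, "
                      f"{m.state_range[1]:.4g}]\n")
        buf.write("-" * 46 + "\n")
        errs = self.bse() if bse else np.full(len(self.params), np.nan)
        for name, val, err in zip(self.param_names, self.params, errs):
            line = f"  {name:>4s}  {val:12.5g}"
            if np.isfinite(err):
                line += f"  (se {err:.3g})"
            buf.write(line + "\n")
        if m.provenance.get("noise_nonpositive"):
            buf.write("warning: fitted h(z) is not positive everywhere; "
                      "simulation clamps it at the noise floor\n")
        return buf.getvalue()

    # ---- downstream -----------------------------------------------------

    def simulate(self, beta: float, config: SimConfig | None = None) -> WTSample:
        """First-passage waiting times of the fitted equation at bound β."""
        return simulate_wt_sample(self.langevin, beta, config)

    def fit_waiting_times(self, beta: float,
                          config: SimConfig | None = None):
        """Simulate at β and fit the inverse-Gaussian MLE."""
        return fit_inverse_gaussian(self.simulate(beta, config))

    def optimize_threshold(self, target: tuple[float, float],
                           beta_grid=None,
                           sim_config: SimConfig | None = None,
                           **kwargs) -> ThresholdScan:
        return optimize_threshold(self.langevin, target, beta_grid,
                                  sim_config, **kwargs)
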