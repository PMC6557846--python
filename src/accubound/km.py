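"""Drift/diffusion (Kramers–Moyal) reconstruction of a Langevin equation.

Given trial-structured time series assumed to follow a stationary Markovian
process dx/dt = g(x) + h(x)Γ(t), the drift and diffusion coefficients of
the associated Fokker–Planck equation are the τ→0 limits of the binned
conditional increment moments

    D1(x) = lim_{τ→0} <x(t+τ) − x(t)> / τ        (drift, g = D1)
    D2(x) = lim_{τ→0} <(x(t+τ) − x(t))^2> / τ    (diffusion, h = sqrt(D2))

estimated here by the standard binning procedure: the observed state range
is split into 100 bins, the conditional moments A1(x, τ) and A2(x, τ) are
averaged per bin for a ladder of lags τ = 1/fs … 10/fs, and the limit is
taken by a zero-intercept quadratic-in-τ least-squares fit whose linear
coefficient is the rate.  The zero-intercept quadratic removes the O(τ²)
finite-lag bias exactly for polynomial moments.

Three reconstruction modes mirror how trials can be combined:

``concatenated``
    all trials joined into one long series (no increment pair straddles a
    trial boundary) and a single moment field estimated;
``single_trial``
    one field and one polynomial fit per trial;
``pooled``
    per-trial fields, with all (bin, D1) and (bin, sqrt(D2)) points pooled
    into one weighted polynomial fit — the estimator used for behavioral
    models, where a single equation must describe the whole trial ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .datasets import TrialDataset, TrialEpoch
from .langevin import LangevinModel

__all__ = [
    "KMField",
    "concatenate_trials",
    "estimate_km_field",
    "extrapolate_moment",
    "fit_langevin_model",
    "reconstruct",
    "DEFAULT_N_BINS",
    "MIN_BIN_COUNT",
]

DEFAULT_N_BINS = 100
DEFAULT_N_TAUS = 10
#: a bin takes part in fitting only if it has at least this many increment
#: pairs at every lag; low-occupancy tail bins otherwise dominate the fit
MIN_BIN_COUNT = 10


@dataclass
class KMField:
    """Binned conditional moments and their τ→0 extrapolation.

    A1[b, j] and A2[b, j] are the mean increment and mean squared increment
    for state bin b at lag taus[j]; counts[b, j] the number of pairs.
    D1/D2 are per-bin drift and diffusion rates (units of x/s and x²/s);
    bins failing the occupancy rule, or whose extrapolated D2 came out
    negative (clamped to 0), are masked out of ``valid_mask``.
    """

    bin_centers: np.ndarray
    taus: np.ndarray
    A1: np.ndarray
    A2: np.ndarray
    counts: np.ndarray
    D1: np.ndarray
    D2: np.ndarray
    valid_mask: np.ndarray

    @property
    def bin_weights(self) -> np.ndarray:
        """Total pair count per bin (used as fit weights)."""
        return self.counts.sum(axis=1)


def concatenate_trials(epochs: Sequence[TrialEpoch]):
    """Join trials into one series, recording trial boundaries.

    Returns ``(y, boundaries)`` where ``boundaries[i]`` is the start index
    of trial i in ``y`` (so pairs can be restricted to single trials).
    """
    epochs = list(epochs)
    if not epochs:
        raise ValueError("no epochs to concatenate")
    fs = {e.fs for e in epochs}
    if len(fs) > 1:
        raise ValueError(f"mixed sampling rates: {sorted(fs)}")
    lengths = [e.n_samples for e in epochs]
    boundaries = np.concatenate([[0], np.cumsum(lengths)[:-1]]).astype(int)
    y = np.concatenate([e.samples for e in epochs])
    return y, boundaries


def _pair_base_mask(n_total: int, boundaries: np.ndarray, lengths: np.ndarray,
                    max_lag: int) -> np.ndarray:
    """Base indices allowed to form pairs: within each trial, every sample
    except the final ``max_lag`` ones (the "right boundary")."""
    mask = np.zeros(n_total, dtype=bool)
    for start, ln in zip(boundaries, lengths):
        if ln > max_lag:
            mask[start:start + ln - max_lag] = True
    return mask


def estimate_km_field(data, fs: float | None = None,
                      n_bins: int = DEFAULT_N_BINS,
                      taus: Sequence[float] | None = None,
                      order: int = 2) -> KMField:
    """Estimate binned conditional moments and extrapolate D1, D2.

    Parameters
    ----------
    data : array, TrialEpoch, or sequence of TrialEpoch
        A plain series (requires ``fs``) or trial epochs; with several
        epochs no increment pair straddles a trial boundary.
    taus : lags in seconds; default the 10 values 1/fs … 10/fs.
    order : polynomial order of the τ→0 extrapolation (>= 1).
    """
    if isinstance(data, TrialEpoch):
        data = [data]
    if isinstance(data, np.ndarray) or (
            hasattr(data, "__len__") and len(data) and np.isscalar(data[0])):
        if fs is None:
            raise ValueError("fs required for a bare series")
        y = np.asarray(data, dtype=float)
        boundaries = np.array([0])
        lengths = np.array([len(y)])
    else:
        epochs = list(data)
        if fs is None:
            fs = epochs[0].fs
        y, boundaries = concatenate_trials(epochs)
        lengths = np.array([e.n_samples for e in epochs])

    if taus is None:
        taus = np.arange(1, DEFAULT_N_TAUS + 1) / fs
    taus = np.asarray(taus, dtype=float)
    lags = np.round(taus * fs).astype(int)
    if np.any(lags < 1):
        raise ValueError("all lags must be at least one sample")
    max_lag = int(lags.max())
    if np.all(lengths <= max_lag):
        raise ValueError("every trial is shorter than the maximum lag")

    lo, hi = float(np.min(y)), float(np.max(y))
    if not hi > lo:
        raise ValueError("degenerate series: fewer than 2 distinct values")
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # np.digitize puts x == hi in bin n_bins; fold it into the last bin
    bin_idx = np.clip(np.digitize(y, edges) - 1, 0, n_bins - 1)

    base = _pair_base_mask(len(y), boundaries, lengths, max_lag)
    base_idx = np.nonzero(base)[0]
    b = bin_idx[base_idx]

    n_taus = len(taus)
    A1 = np.zeros((n_bins, n_taus))
    A2 = np.zeros((n_bins, n_taus))
    counts = np.zeros((n_bins, n_taus), dtype=int)
    for j, s in enumerate(lags):
        dx = y[base_idx + s] - y[base_idx]
        cnt = np.bincount(b, minlength=n_bins)
        s1 = np.bincount(b, weights=dx, minlength=n_bins)
        s2 = np.bincount(b, weights=dx * dx, minlength=n_bins)
        counts[:, j] = cnt
        occ = cnt > 0
        A1[occ, j] = s1[occ] / cnt[occ]
        A2[occ, j] = s2[occ] / cnt[occ]

    valid = np.all(counts >= MIN_BIN_COUNT, axis=1)
    D1 = np.full(n_bins, np.nan)
    D2 = np.full(n_bins, np.nan)
    for i in np.nonzero(valid)[0]:
        D1[i] = extrapolate_moment(A1[i], taus, order=order)
        D2[i] = extrapolate_moment(A2[i], taus, order=order)
    # negative diffusion is finite-sample noise: clamp and drop from fits
    neg = valid & (D2 < 0)
    D2[neg] = 0.0
    valid = valid & ~neg
    return KMField(bin_centers=centers, taus=taus, A1=A1, A2=A2,
                   counts=counts, D1=D1, D2=D2, valid_mask=valid)


def extrapolate_moment(values: Sequence[float], taus: Sequence[float],
                       order: int = 2) -> float:
    """τ→0 rate of a conditional moment.

    Least-squares fit of ``moment(τ) ≈ c1 τ + ... + c_order τ^order`` with
    zero intercept (a moment of increments vanishes identically at τ = 0);
    the linear coefficient c1 is the limit rate.
    """
    values = np.asarray(values, dtype=float)
    taus = np.asarray(taus, dtype=float)
    if order < 1:
        raise ValueError("order must be >= 1")
    if len(np.unique(taus)) < order + 1:
        raise ValueError(f"need at least {order + 1} distinct lags for order {order}")
    X = np.vander(taus, order + 1, increasing=True)[:, 1:]
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    return float(coef[0])


def fit_langevin_model(field: KMField, degree_g: int = 1, degree_h: int = 2,
                       provenance: dict | None = None) -> LangevinModel:
    """Weighted polynomial fits g ≈ D1 and h ≈ sqrt(D2) on valid bins.

    Weights are total per-bin pair counts, equalizing the influence of
    well- and poorly-sampled state regions.
    """
    m = field.valid_mask
    need = max(degree_g, degree_h) + 1
    if m.sum() < need:
        raise ValueError(f"only {int(m.sum())} valid bins; need >= {need}")
    x = field.bin_centers[m]
    w = np.sqrt(field.bin_weights[m].astype(float))  # polyfit squares its weights
    g_coef = np.polyfit(x, field.D1[m], degree_g, w=w)
    h_coef = np.polyfit(x, np.sqrt(field.D2[m]), degree_h, w=w)
    model = LangevinModel(g_coef, h_coef,
                          state_range=(float(x.min()), float(x.max())),
                          provenance=provenance or {})
    if not model.noise_is_positive():
        model.provenance["noise_nonpositive"] = True
    return model


def _pooled_fit(fields: list[KMField], degree_g: int, degree_h: int,
                provenance: dict) -> LangevinModel:
    xs, d1s, sqd2s, ws = [], [], [], []
    for f in fields:
        m = f.valid_mask
        xs.append(f.bin_centers[m])
        d1s.append(f.D1[m])
        sqd2s.append(np.sqrt(f.D2[m]))
        ws.append(f.bin_weights[m].astype(float))
    x = np.concatenate(xs)
    need = max(degree_g, degree_h) + 1
    if len(x) < need:
        raise ValueError(f"only {len(x)} pooled points; need >= {need}")
    w = np.sqrt(np.concatenate(ws))
    g_coef = np.polyfit(x, np.concatenate(d1s), degree_g, w=w)
    h_coef = np.polyfit(x, np.concatenate(sqd2s), degree_h, w=w)
    model = LangevinModel(g_coef, h_coef,
                          state_range=(float(x.min()), float(x.max())),
                          provenance=provenance)
    if not model.noise_is_positive():
        model.provenance["noise_nonpositive"] = True
    return model


def reconstruct(data, mode: str = "concatenated",
                degrees: tuple[int, int] = (1, 2),
                window: tuple[float, float] | None = None,
                n_bins: int = DEFAULT_N_BINS,
                taus: Sequence[float] | None = None,
                scale: float = 1.0):
    """Reconstruct Langevin model(s) from epochs.

    Parameters
    ----------
    data : TrialDataset or sequence of TrialEpoch
    mode : "concatenated", "single_trial" or "pooled"
    degrees : (G, H) polynomial degrees for drift and noise amplitude
    window : optional (start, end) crop in seconds relative to the event
    scale : multiplicative factor applied to samples before estimation
        (e.g. 1e13 to convert Tesla to evidence units); recorded in
        provenance.

    Returns one :class:`LangevinModel` (concatenated/pooled) or a list with
    one model per trial (single_trial).
    """
    if isinstance(data, TrialDataset):
        epochs = data.select()
    else:
        epochs = list(data)
    if not epochs:
        raise ValueError("no epochs supplied")
    if window is not None:
        epochs = [e.crop(*window) for e in epochs]
    if scale != 1.0:
        epochs = [TrialEpoch(e.subject_id, e.channel_id, e.trial_index,
                             e.samples * scale, e.fs, e.t0_index)
                  for e in epochs]
    degree_g, degree_h = degrees
    prov = {"mode": mode, "degrees": [degree_g, degree_h], "scale": scale,
            "window_s": None if window is None else list(window),
            "n_trials": len(epochs)}

    if mode == "concatenated":
        field = estimate_km_field(epochs, n_bins=n_bins, taus=taus)
        return fit_langevin_model(field, degree_g, degree_h, provenance=prov)
    if mode == "single_trial":
        out = []
        for e in epochs:
            field = estimate_km_field(e, n_bins=n_bins, taus=taus)
            p = dict(prov, subject=e.subject_id, channel=e.channel_id,
                     trial=e.trial_index)
            out.append(fit_langevin_model(field, degree_g, degree_h, provenance=p))
        return out
    if mode == "pooled":
        fields = [estimate_km_field(e, n_bins=n_bins, taus=taus) for e in epochs]
        return _pooled_fit(fields, degree_g, degree_h, provenance=prov)
    raise ValueError(f"unknown mode {mode!r}")
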