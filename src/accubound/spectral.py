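"""Power spectral density and 1/f^α exponent estimation.

The spectral exponent α of S(f) ∝ f^{-α} discriminates noise classes:
α = 0 is white noise, α = 2 Brownian noise (the output of any
constant-noise accumulator), and cortical signals typically show
1 < α < 2.  PSDs are Welch averaged periodograms (Hann taper, 256-sample
segments, 50% overlap by default) and α is the negative slope of the
log10–log10 least-squares line over the fit band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["SpectralFit", "estimate_psd", "fit_spectral_exponent"]


@dataclass
class SpectralFit:
    alpha: float
    f_range: tuple[float, float]
    r_squared: float
    frequencies: np.ndarray
    power: np.ndarray


def estimate_psd(series, fs: float, segment_length: int = 256,
                 overlap_fraction: float = 0.5):
    """Welch PSD; returns (frequencies, power)."""
    series = np.asarray(series, dtype=float)
    if len(series) < segment_length:
        raise ValueError(
            f"series of {len(series)} samples shorter than one "
            f"{segment_length}-sample segment")
    noverlap = int(round(segment_length * overlap_fraction))
    return signal.welch(series, fs=fs, window="hann", nperseg=segment_length,
                        noverlap=noverlap, detrend="constant")


def fit_spectral_exponent(frequencies, power,
                          f_range: tuple[float, float] = (0.5, 40.0)) -> SpectralFit:
    """α from the log-log linear fit of power vs frequency over f_range."""
    f = np.asarray(frequencies, dtype=float)
    p = np.asarray(power, dtype=float)
    lo, hi = f_range
    m = (f >= lo) & (f <= hi)
    if m.sum() < 5:
        raise ValueError(f"fewer than 5 frequency bins in [{lo}, {hi}] Hz")
    if np.any(p[m] <= 0):
        raise ValueError("nonpositive power inside the fit band")
    lf, lp = np.log10(f[m]), np.log10(p[m])
    slope, intercept = np.polyfit(lf, lp, 1)
    resid = lp - (slope * lf + intercept)
    ss_tot = float(np.sum((lp - lp.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return SpectralFit(alpha=float(-slope), f_range=(float(lo), float(hi)),
                       r_squared=max(0.0, min(1.0, r2)),
                       frequencies=f, power=p)
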