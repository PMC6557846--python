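"""Readiness-field channel scoring and selection.

A channel resembles a readiness field when its trial-averaged signal (the
event-related field, ERF) builds up to a maximum around the movement event.
Each channel is scored by the weight W: locate the ERF maximum within a
0.4 s window centered on the event, then average the ERF over 0.2 s around
that maximum.  The top-k channels by W feed the behavioral-model
reconstruction.

W uses the signed ERF maximum by default; magnetometer polarity depends on
source orientation, so an absolute-value variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datasets import TrialDataset, TrialEpoch

__all__ = ["ChannelWeight", "compute_erf", "readiness_weight", "select_channels"]


@dataclass
class ChannelWeight:
    channel_id: str
    W: float
    erf_peak_index: int


def compute_erf(epochs: Sequence[TrialEpoch]) -> np.ndarray:
    """Pointwise mean across trials (epochs must be aligned)."""
    epochs = list(epochs)
    if not epochs:
        raise ValueError("no epochs")
    n = {e.n_samples for e in epochs}
    t0 = {e.t0_index for e in epochs}
    if len(n) > 1 or len(t0) > 1:
        raise ValueError("misaligned epochs (length or t0 differ)")
    return np.mean([e.samples for e in epochs], axis=0)


def readiness_weight(erf: np.ndarray, fs: float, t0_index: int,
                     search_halfwidth: float = 0.2,
                     avg_halfwidth: float = 0.1,
                     absolute: bool = False,
                     channel_id: str = "") -> ChannelWeight:
    """Weight W of one ERF.

    The maximum is searched in t0 ± search_halfwidth (inclusive, centered;
    101 samples at 250 Hz); ties go to the earliest sample.  W is the mean
    of the ERF over peak ± avg_halfwidth, truncated at the epoch edges.
    """
    erf = np.asarray(erf, dtype=float)
    hs = int(round(search_halfwidth * fs))
    lo, hi = t0_index - hs, t0_index + hs + 1
    if lo < 0 or hi > len(erf):
        raise ValueError("search window exceeds the epoch")
    seg = np.abs(erf[lo:hi]) if absolute else erf[lo:hi]
    peak = lo + int(np.argmax(seg))  # argmax: first occurrence wins
    ha = int(round(avg_halfwidth * fs))
    a, b = max(0, peak - ha), min(len(erf), peak + ha + 1)
    W = float(np.mean(erf[a:b]))
    return ChannelWeight(channel_id=channel_id, W=W, erf_peak_index=peak)


def select_channels(dataset: TrialDataset, k: int = 5,
                    subject_id: str | None = None,
                    search_halfwidth: float = 0.2,
                    avg_halfwidth: float = 0.1,
                    absolute: bool = False) -> list[ChannelWeight]:
    """Top-k channels by W, sorted descending; ties broken by channel order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    chans = dataset.channels(subject_id)
    if k > len(chans):
        raise ValueError(f"k={k} exceeds {len(chans)} channels")
    weights = []
    for c in chans:
        eps = dataset.select(subject_id, c)
        erf = compute_erf(eps)
        cw = readiness_weight(erf, dataset.fs, dataset.t0_index,
                              search_halfwidth, avg_halfwidth,
                              absolute=absolute, channel_id=c)
        weights.append(cw)
    order = sorted(range(len(weights)),
                   key=lambda i: (-weights[i].W, i))  # stable tie rule
    return [weights[i] for i in order[:k]]
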