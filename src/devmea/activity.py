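"""Active-electrode filtering, firing-rate statistics and rate maps.

An electrode is *active* when its firing rate lies in [0.1, 10] Hz
(bounds inclusive); the network mean firing rate (MFR) averages over
active electrodes only.  Spike-amplitude summaries apply the
conservative negative-peak cutoff (default -250 uV, i.e. only spikes
of magnitude >= 250 uV contribute).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import SpikeTrainSet

__all__ = [
    "ACTIVE_RATE_BOUNDS_HZ",
    "ActivityResult",
    "AmplitudeSummary",
    "compute_activity",
    "rate_map",
    "summarize_amplitudes",
]

ACTIVE_RATE_BOUNDS_HZ = (0.1, 10.0)


@dataclass
class ActivityResult:
    rates_hz: np.ndarray          # per electrode, full array
    active_mask: np.ndarray       # boolean, full array
    mfr_hz: float                 # mean over active electrodes (0 if none)
    mfr_map: np.ndarray           # n_rows x n_cols, inactive cells 0
    duration: float
    n_total: int                  # electrodes in the array

    @property
    def n_active(self) -> int:
        return int(self.active_mask.sum())


@dataclass
class AmplitudeSummary:
    mean_negative_peak_uv: float  # NaN when no spike qualifies
    n_spikes_used: int
    cutoff_uv: float

    @property
    def available(self) -> bool:
        return self.n_spikes_used > 0


def compute_activity(s: SpikeTrainSet) -> ActivityResult:
    """Per-electrode rates, active mask, and network MFR."""
    rates = s.spike_counts() / s.duration
    lo, hi = ACTIVE_RATE_BOUNDS_HZ
    mask = (rates >= lo) & (rates <= hi)
    mfr = float(rates[mask].mean()) if mask.any() else 0.0
    mfr_map = np.where(mask, rates, 0.0).reshape(s.geometry.n_rows, s.geometry.n_cols)
    return ActivityResult(rates, mask, mfr, mfr_map, s.duration, s.geometry.n_electrodes)


def rate_map(s: SpikeTrainSet) -> np.ndarray:
    """64x64 (or geometry-shaped) grid of raw firing rates in Hz.

    No active filtering: grid[row, col] is simply the rate of electrode
    (row, col), so grid.sum() * duration equals the total spike count.
    """
    rates = s.spike_counts() / s.duration
    return rates.reshape(s.geometry.n_rows, s.geometry.n_cols)


def summarize_amplitudes(s: SpikeTrainSet, cutoff_uv: float = -250.0) -> AmplitudeSummary:
    """Mean negative peak over spikes at or beyond the cutoff.

    "At or beyond" means amplitude <= cutoff, i.e. magnitude >= |cutoff|.
    With no qualifying spike the mean is NaN and ``available`` is False.
    """
    if cutoff_uv >= 0:
        raise ValueError("cutoff must be negative (a negative-peak bound)")
    a = s.all_amplitudes()
    sel = a[a <= cutoff_uv]
    if sel.size == 0:
        return AmplitudeSummary(math.nan, 0, cutoff_uv)
    return AmplitudeSummary(float(sel.mean()), int(sel.size), cutoff_uv)
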