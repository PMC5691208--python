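"""Lognormal-like firing-rate distributions and condition shifts.

Firing rates of active electrodes are analysed on a log10 axis: the
occurrence histogram spans the active band [0.1, 10] Hz in 20 equal
log bins and is normalised by the total electrode count of the array
(so the histogram sums to n_active / n_total, the fraction of the array
that is active).  The Gaussian fit is the moment/MLE fit to the raw
log10 rates, not a least-squares fit to the binned histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activity import ACTIVE_RATE_BOUNDS_HZ, ActivityResult

__all__ = ["RateDistribution", "build_rate_distribution", "distribution_shift"]

N_BINS = 20
MIN_ACTIVE_FOR_FIT = 10


@dataclass
class RateDistribution:
    log10_rates: np.ndarray
    bin_edges: np.ndarray
    occurrence: np.ndarray    # counts / n_total electrodes
    fit_mu: float | None      # log10 Hz; None when the fit is unavailable
    fit_sigma: float | None
    n_active: int
    n_total: int

    @property
    def fit_available(self) -> bool:
        return self.fit_mu is not None


def build_rate_distribution(a: ActivityResult) -> RateDistribution:
    """Occurrence histogram and log-space Gaussian fit of active rates.

    With fewer than 10 active electrodes the histogram is still built
    but the fit is flagged unavailable.
    """
    log_rates = np.log10(a.rates_hz[a.active_mask])
    edges = np.linspace(np.log10(ACTIVE_RATE_BOUNDS_HZ[0]), np.log10(ACTIVE_RATE_BOUNDS_HZ[1]), N_BINS + 1)
    counts, _ = np.histogram(log_rates, bins=edges)
    occurrence = counts / a.n_total
    if log_rates.size >= MIN_ACTIVE_FOR_FIT:
        mu, sigma = float(log_rates.mean()), float(log_rates.std(ddof=0))
    else:
        mu = sigma = None
    return RateDistribution(log_rates, edges, occurrence, mu, sigma, log_rates.size, a.n_total)


def distribution_shift(d1: RateDistribution, d2: RateDistribution) -> float:
    """``d2.fit_mu - d1.fit_mu`` in log10 Hz; negative = leftward shift
    (toward lower firing frequencies)."""
    if not (d1.fit_available and d2.fit_available):
        raise ValueError("both distributions need an available Gaussian fit")
    return float(d2.fit_mu - d1.fit_mu)
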