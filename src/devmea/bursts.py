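"""Single-electrode bursts, network bursts, and inter-burst intervals.

Definitions:

* a **burst** is a maximal run of >= 5 consecutive spikes on one
  electrode with every inter-spike interval strictly below 100 ms;
* a **network burst** (NB) is a transient during which the number of
  distinct active electrodes spiking inside a 15 ms bin strictly
  exceeds 15% of the active-electrode count; supra-threshold bins
  closer than a 150 ms horizon merge into one event;
* the **IBI distribution** is a Gaussian-kernel density of log10
  inter-burst (onset-to-onset) intervals, bandwidth 5% of the log-IBI
  range, normalised to integrate to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .activity import compute_activity
from .io import SpikeTrainSet

__all__ = [
    "Burst",
    "NetworkBurst",
    "IBIDistribution",
    "detect_bursts",
    "detect_network_bursts",
    "ibi_distribution",
]

BURST_MIN_SPIKES = 5
BURST_MAX_ISI_S = 0.1


@dataclass(frozen=True)
class Burst:
    electrode: int
    start: float
    end: float
    n_spikes: int


@dataclass(frozen=True)
class NetworkBurst:
    start: float
    end: float
    peak_participation: int
    bins: tuple[int, ...]


@dataclass
class IBIDistribution:
    values_s: np.ndarray     # raw inter-onset intervals
    grid: np.ndarray         # log10 s evaluation points
    density: np.ndarray      # normalised kernel density on the grid
    bandwidth: float         # log10 units


def detect_bursts(s: SpikeTrainSet) -> tuple[list[Burst], float]:
    """All single-electrode bursts plus the mean bursting rate.

    MBR is the mean over *active* electrodes (0.1-10 Hz rule) of bursts
    per minute; electrodes outside the active band contribute neither
    bursts-per-minute terms nor bursts to the MBR, but their bursts are
    still returned.
    """
    bursts: list[Burst] = []
    per_electrode: dict[int, int] = {}
    for e in s.electrodes:
        t = s.times[e]
        n_b = 0
        if t.size >= BURST_MIN_SPIKES:
            # split at ISIs >= 100 ms; each fragment is a maximal run
            breaks = np.flatnonzero(np.diff(t) >= BURST_MAX_ISI_S)
            for run in np.split(t, breaks + 1):
                if run.size >= BURST_MIN_SPIKES:
                    bursts.append(Burst(e, float(run[0]), float(run[-1]), int(run.size)))
                    n_b += 1
        per_electrode[e] = n_b
    act = compute_activity(s)
    active = np.flatnonzero(act.active_mask)
    if active.size == 0:
        return bursts, 0.0
    counts = np.array([per_electrode.get(int(e), 0) for e in active], dtype=float)
    mbr = float((counts / s.duration * 60.0).mean())
    return bursts, mbr


def detect_network_bursts(
    s: SpikeTrainSet,
    bin_ms: float = 15.0,
    window_ms: float = 150.0,
    threshold_frac: float = 0.15,
) -> list[NetworkBurst]:
    """Network bursts from binned multi-electrode participation.

    Time is partitioned into contiguous ``bin_ms`` bins aligned to t=0;
    a bin is an event bin when the count of distinct active electrodes
    with at least one spike in it strictly exceeds
    ``threshold_frac * n_active``.  Event bins separated by less than
    ``window_ms`` belong to the same NB.  NB start/end are the outer
    edges of its first/last event bin.
    """
    act = compute_activity(s)
    active = set(int(e) for e in np.flatnonzero(act.active_mask))
    if not active:
        raise ValueError("network-burst detection needs at least one active electrode")
    bin_s = bin_ms * 1e-3
    n_bins = int(np.ceil(s.duration / bin_s))
    participation = np.zeros(n_bins, dtype=np.int64)
    for e in s.electrodes:
        if e not in active:
            continue
        b = np.unique(np.minimum((s.times[e] / bin_s).astype(int), n_bins - 1))
        participation[b] += 1
    threshold = threshold_frac * len(active)
    event_bins = np.flatnonzero(participation > threshold)
    if event_bins.size == 0:
        return []
    merge_gap = window_ms * 1e-3
    groups: list[list[int]] = [[int(event_bins[0])]]
    for b in event_bins[1:]:
        # gap between end of previous event bin and start of this one
        gap = (b - groups[-1][-1] - 1) * bin_s
        if gap < merge_gap:
            groups[-1].append(int(b))
        else:
            groups.append([int(b)])
    out = []
    for grp in groups:
        out.append(
            NetworkBurst(
                start=grp[0] * bin_s,
                end=(grp[-1] + 1) * bin_s,
                peak_participation=int(participation[grp].max()),
                bins=tuple(grp),
            )
        )
    return out


def ibi_distribution(events: Sequence, n_grid: int = 256) -> IBIDistribution:
    """Smoothed distribution of log10 inter-onset intervals.

    ``events`` may be Burst/NetworkBurst objects (their ``start`` is
    used) or plain onset times in seconds.  The kernel bandwidth is 5%
    of the log10-IBI range (floored at 0.01 log units for degenerate
    all-equal inputs); the density is renormalised to integrate to 1 on
    its grid by the trapezoid rule.
    """
    starts = np.asarray(
        [getattr(ev, "start", ev) for ev in events], dtype=float
    )
    if starts.size < 2:
        raise ValueError("need at least two events for an IBI distribution")
    starts = np.sort(starts)
    ibis = np.diff(starts)
    if np.any(ibis <= 0):
        raise ValueError("duplicate event onsets")
    x = np.log10(ibis)
    bw = max(0.05 * (x.max() - x.min()), 0.01)
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, n_grid)
    density = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / bw) ** 2).sum(axis=1)
    density /= np.trapezoid(density, grid)
    return IBIDistribution(ibis, grid, density, bw)
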