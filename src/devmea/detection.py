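"""Extracellular spike detection with a differential threshold.

A spike is a negative-going local minimum whose peak-to-peak excursion,
measured against the largest local maximum within +/- one peak lifetime,
exceeds ``threshold_multiplier`` times the per-electrode noise SD.  This
is the classic differential (peak-to-peak) criterion of precise-timing
spike detectors, rather than a plain level crossing: small wobbles on a
slow drift do not fire it, while a fast biphasic transient does.

The noise SD defaults to the MAD estimate (median absolute deviation
scaled by 1/0.6745) because a plain sample SD is inflated by the spikes
themselves on active electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.signal import argrelextrema

from .io import RawRecording, SpikeTrainSet

__all__ = ["DetectionParams", "estimate_noise_sd", "detect_spikes"]

MAD_TO_SD = 0.6745  # Phi^-1(0.75): MAD of a Gaussian = 0.6745 sigma


@dataclass(frozen=True)
class DetectionParams:
    threshold_multiplier: float = 9.0
    peak_lifetime_ms: float = 2.0
    refractory_ms: float = 1.0
    noise_estimator: str = "mad"

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be positive")
        if self.peak_lifetime_ms <= 0:
            raise ValueError("peak_lifetime_ms must be positive")
        if self.refractory_ms < 0:
            raise ValueError("refractory_ms must be >= 0")
        if self.noise_estimator not in ("mad", "sd"):
            raise ValueError("noise_estimator must be 'mad' or 'sd'")


def estimate_noise_sd(trace: np.ndarray, estimator: str = "mad") -> float:
    """Noise SD of a voltage trace in uV.

    ``mad``: median(|x - median(x)|) / 0.6745 (robust to spikes);
    ``sd``: plain sample standard deviation.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 1000:
        raise ValueError("need at least 1000 samples for a noise estimate")
    if estimator == "mad":
        return float(np.median(np.abs(trace - np.median(trace))) / MAD_TO_SD)
    if estimator == "sd":
        return float(np.std(trace, ddof=1))
    raise ValueError("estimator must be 'mad' or 'sd'")


def _detect_trace(trace: np.ndarray, fs: float, params: DetectionParams) -> tuple[np.ndarray, np.ndarray]:
    """Spike (times, amplitudes) for one trace."""
    threshold = params.threshold_multiplier * estimate_noise_sd(trace, params.noise_estimator)
    w = max(int(round(params.peak_lifetime_ms * 1e-3 * fs)), 1)
    # windowed maximum over +/- w samples; the max of the trace in the
    # window dominates every local maximum in it
    win_max = maximum_filter1d(trace, size=2 * w + 1, mode="nearest")
    win_min = -maximum_filter1d(-trace, size=2 * w + 1, mode="nearest")
    minima = argrelextrema(trace, np.less_equal, order=1)[0]
    # strict negative-going troughs that are also the deepest point
    # within one peak lifetime (suppresses flank troughs of a spike)
    minima = minima[(trace[minima] < 0) & (trace[minima] <= win_min[minima])]
    excursion = win_max[minima] - trace[minima]
    cand = minima[excursion > threshold]
    if cand.size == 0:
        return np.empty(0), np.empty(0)
    # refractory suppression: of detections closer than the refractory
    # period, keep the larger-magnitude trough
    refr = params.refractory_ms * 1e-3 * fs
    kept_idx: list[int] = []
    for i in cand:
        if kept_idx and i - kept_idx[-1] < refr:
            if trace[i] < trace[kept_idx[-1]]:
                kept_idx[-1] = i
        else:
            kept_idx.append(i)
    idx = np.asarray(kept_idx, dtype=int)
    return idx / fs, trace[idx]


def detect_spikes(rec: RawRecording, params: DetectionParams = DetectionParams()) -> SpikeTrainSet:
    """Detect spikes on every trace of a recording.

    Timestamps are the negative-peak samples; amplitudes the trace value
    there.  Output satisfies all SpikeTrainSet invariants (sorted,
    strictly increasing, non-positive amplitudes).
    """
    times: dict[int, np.ndarray] = {}
    amps: dict[int, np.ndarray] = {}
    for row, e in enumerate(rec.electrode_ids):
        t, a = _detect_trace(rec.traces[row], rec.sampling_rate, params)
        if t.size:
            times[int(e)] = t
            amps[int(e)] = a
    return SpikeTrainSet(rec.geometry, rec.duration, times, amps,
                         metadata={"detector": "differential", **params.__dict__})
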