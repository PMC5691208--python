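"""Synthetic developing-network data with known ground truth.

Every downstream stage (spike detection, burst/network-burst detection,
rate-distribution fits, the expression-crossing estimator) is exercised
against data from this module, so its generative assumptions are the
reference conditions of the whole test suite:

* tonic firing is a homogeneous Poisson process per electrode with a
  2 ms dead time, electrode rates lognormal across the array
  (``log10 r ~ Normal(mu, sigma)``, clipped to [0.01, 20] Hz);
* network bursts (NBs) are point events recruiting a binomial subset of
  the active electrodes, each recruited electrode contributing a Poisson
  number of spikes jittered normally around the event time;
* cotransporter expression follows opposed logistic curves in DIV whose
  noiseless intersection is placed exactly at a requested crossing day.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ArrayGeometry, ExpressionSeries, RawRecording, SpikeTrainSet

__all__ = [
    "NetworkPreset",
    "ExpressionCurveSpec",
    "SpikeTemplate",
    "GroundTruth",
    "simulate_network",
    "simulate_raw",
    "simulate_expression",
]

logger = logging.getLogger(__name__)

RATE_CLIP_HZ = (0.01, 20.0)
TONIC_DEAD_TIME_S = 0.002
#: minimum separation enforced between generated NB events, so each
#: planted event maps to exactly one detected event under the 150 ms
#: merge horizon of the NB detector
NB_MIN_SEPARATION_S = 0.3


@dataclass(frozen=True)
class NetworkPreset:
    """Statistical description of one culture condition.

    ``burst_trains_fraction`` of the active electrodes additionally emit
    intrinsic single-electrode bursts (>= 5 spikes, ISIs < 100 ms) as a
    Poisson event process at ``burst_rate_per_min``.
    """

    n_active: int = 500
    rate_mu_log10: float = -0.5
    rate_sigma_log10: float = 0.3
    nb_rate_per_min: float = 6.0
    nb_participation: float = 0.6
    nb_spikes_per_electrode: float = 3.0
    nb_jitter_s: float = 0.005
    burst_trains_fraction: float = 0.0
    burst_rate_per_min: float = 20.0
    amplitude_mean_uv: float = -60.0
    amplitude_sd_uv: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active < 0:
            raise ValueError("n_active must be >= 0")
        for name in ("nb_participation", "burst_trains_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("nb_rate_per_min", "nb_spikes_per_electrode", "burst_rate_per_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ExpressionCurveSpec:
    """Opposed logistic NKCC1/KCC2 curves with a known crossing DIV."""

    crossing_div: float = 18.0
    nkcc1_start_pct: float = 140.0
    nkcc1_end_pct: float = 80.0
    kcc2_start_pct: float = 85.0
    kcc2_end_pct: float = 215.0
    steepness: float = 0.35
    sample_divs: tuple[float, ...] = (8.0, 16.0, 26.0)
    sem_pct: float = 3.0
    n_per_point: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")
        if self.nkcc1_start_pct <= self.nkcc1_end_pct:
            raise ValueError("NKCC1 must decrease (start > end)")
        if self.kcc2_start_pct >= self.kcc2_end_pct:
            raise ValueError("KCC2 must increase (start < end)")
        if not min(self.sample_divs) <= self.crossing_div <= max(self.sample_divs):
            raise ValueError("crossing_div must lie within the sampled DIV range")
        mid = 0.5 * (self.nkcc1_start_pct + self.nkcc1_end_pct)
        if not self.kcc2_start_pct < mid < self.kcc2_end_pct:
            raise ValueError(
                "KCC2 range must bracket the NKCC1 midpoint for a crossing to exist"
            )


@dataclass(frozen=True)
class SpikeTemplate:
    """Biphasic extracellular spike shape, dominant negative phase."""

    peak_uv: float = -90.0
    width_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.peak_uv >= 0:
            raise ValueError("peak amplitude must be negative")
        if self.width_ms <= 0:
            raise ValueError("width must be positive")

    def waveform(self, sampling_rate: float) -> np.ndarray:
        """Unit shape sampled at ``sampling_rate``; min exactly -1,
        zero at both ends."""
        n = max(int(round(self.width_ms * 1e-3 * sampling_rate)), 5)
        x = np.linspace(0.0, 1.0, n)
        w = -np.exp(-(((x - 0.35) / 0.12) ** 2)) + 0.3 * np.exp(-(((x - 0.70) / 0.18) ** 2))
        w -= np.linspace(w[0], w[-1], n)  # pin both ends to exactly 0
        return w / -w.min()


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    nb_times: np.ndarray
    nb_recruited: list[np.ndarray]
    rates_hz: np.ndarray
    active_electrodes: np.ndarray
    preset: NetworkPreset


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream: same (seed, key) always yields the same
    stream, independent of how many other streams are drawn."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _thin_dead_time(t: np.ndarray, dead: float) -> np.ndarray:
    """Greedy enforcement of a minimum inter-event separation."""
    if t.size == 0:
        return t
    keep = [t[0]]
    for x in t[1:]:
        if x - keep[-1] > dead:
            keep.append(x)
    return np.asarray(keep)


def simulate_network(
    preset: NetworkPreset,
    duration: float,
    geometry: ArrayGeometry = ArrayGeometry(),
    seed: int | None = None,
) -> tuple[SpikeTrainSet, GroundTruth]:
    """Generate a spike-train set plus its ground truth.

    Parameters
    ----------
    preset
        Statistical condition to emulate; ``preset.seed`` is used unless
        ``seed`` overrides it.
    duration
        Recording length in seconds.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if preset.n_active > geometry.n_electrodes:
        raise ValueError("more active electrodes than the array holds")
    if preset.n_active == 0 and preset.nb_rate_per_min > 0:
        raise ValueError("network bursts require at least one active electrode")
    seed = preset.seed if seed is None else seed

    g = _rng(seed, 0)  # global stream: layout, rates, NB schedule
    active = np.sort(g.choice(geometry.n_electrodes, size=preset.n_active, replace=False))
    rates = np.zeros(geometry.n_electrodes)
    if preset.n_active:
        r = 10.0 ** g.normal(preset.rate_mu_log10, preset.rate_sigma_log10, preset.n_active)
        rates[active] = np.clip(r, *RATE_CLIP_HZ)
    amp_mean = np.minimum(
        g.normal(preset.amplitude_mean_uv, preset.amplitude_sd_uv, geometry.n_electrodes),
        -20.0,
    )

    # network-burst schedule
    nb_times = np.empty(0)
    nb_recruited: list[np.ndarray] = []
    extra: dict[int, list[np.ndarray]] = {}
    if preset.nb_rate_per_min > 0 and preset.n_active > 0:
        lam = preset.nb_rate_per_min / 60.0 * duration
        n_events = g.poisson(lam)
        nb_times = _thin_dead_time(np.sort(g.uniform(0, duration, n_events)), NB_MIN_SEPARATION_S)
        for t0 in nb_times:
            k = g.binomial(preset.n_active, preset.nb_participation)
            rec = g.choice(active, size=k, replace=False)
            nb_recruited.append(np.sort(rec))
            counts = g.poisson(preset.nb_spikes_per_electrode, size=k)
            for e, c in zip(rec, counts):
                if c == 0:
                    continue
                t = t0 + g.normal(0.0, preset.nb_jitter_s, c)
                extra.setdefault(int(e), []).append(t)

    burst_electrodes = set()
    if preset.burst_trains_fraction > 0 and preset.n_active:
        n_b = int(round(preset.burst_trains_fraction * preset.n_active))
        burst_electrodes = set(int(e) for e in g.choice(active, size=n_b, replace=False))

    times: dict[int, np.ndarray] = {}
    amps: dict[int, np.ndarray] = {}
    for e in active:
        e = int(e)
        rng_e = _rng(seed, 1, e)
        n = rng_e.poisson(rates[e] * duration)
        t = np.sort(rng_e.uniform(0, duration, n))
        t = _thin_dead_time(t, TONIC_DEAD_TIME_S)
        parts = [t]
        if e in burst_electrodes:
            n_bursts = rng_e.poisson(preset.burst_rate_per_min / 60.0 * duration)
            for t0 in rng_e.uniform(0, duration, n_bursts):
                n_sp = 5 + rng_e.poisson(1.0)
                isis = rng_e.uniform(0.02, 0.08, n_sp - 1)
                parts.append(t0 + np.concatenate([[0.0], np.cumsum(isis)]))
        if e in extra:
            parts.extend(extra[e])
        t = np.concatenate(parts)
        t = np.unique(t[(t >= 0) & (t <= duration)])
        if t.size == 0:
            continue
        a = np.minimum(amp_mean[e] + rng_e.normal(0.0, 5.0, t.size), -5.0)
        times[e] = t
        amps[e] = a

    spikes = SpikeTrainSet(geometry, duration, times, amps,
                           metadata={"seed": seed, "source": "simulate_network"})
    truth = GroundTruth(nb_times=nb_times, nb_recruited=nb_recruited,
                        rates_hz=rates, active_electrodes=active, preset=preset)
    return spikes, truth


def simulate_raw(
    spikes: SpikeTrainSet,
    template: SpikeTemplate = SpikeTemplate(),
    noise_sd: float = 5.0,
    sampling_rate: float = 7800.0,
    seed: int = 0,
) -> RawRecording:
    """Render spike trains to voltage traces.

    Each spike inserts the template scaled so the waveform minimum
    equals the spike's amplitude; overlaps sum linearly; additive white
    Gaussian noise with SD ``noise_sd`` (0 allowed for noiseless
    traces).  Spikes whose template would extend past the trace end are
    truncated with a warning.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    shape = template.waveform(sampling_rate)
    peak_off = int(np.argmin(shape))
    n_samples = int(round(spikes.duration * sampling_rate))
    electrodes = np.arange(spikes.geometry.n_electrodes)
    rng = _rng(seed, 2)
    if noise_sd > 0:
        traces = rng.normal(0.0, noise_sd, (electrodes.size, n_samples))
    else:
        traces = np.zeros((electrodes.size, n_samples))
    for row, e in enumerate(electrodes):
        if e not in spikes.times:
            continue
        idx = np.round(spikes.times[e] * sampling_rate).astype(int)
        for i, a in zip(idx, spikes.amplitudes[e]):
            start = i - peak_off
            stop = start + shape.size
            w = shape * (-a)
            if start < 0 or stop > n_samples:
                logger.warning("spike at sample %d on electrode %d truncated at trace edge", i, e)
                lo, hi = max(start, 0), min(stop, n_samples)
                traces[row, lo:hi] += w[lo - start : hi - start]
            else:
                traces[row, start:stop] += w
    return RawRecording(spikes.geometry, sampling_rate, traces, electrodes)


def _logistic(t: np.ndarray, lo: float, hi: float, k: float, t0: float, increasing: bool) -> np.ndarray:
    s = 1.0 if increasing else -1.0
    return lo + (hi - lo) / (1.0 + np.exp(-s * k * (t - t0)))


def expression_curves(spec: ExpressionCurveSpec, divs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless (nkcc1, kcc2) curve values at ``divs``.

    NKCC1 is a falling logistic with midpoint at the crossing day; the
    KCC2 midpoint is solved so that the rising KCC2 logistic passes
    through the same value there, making the crossing exact by
    construction.
    """
    divs = np.asarray(divs, dtype=float)
    k = spec.steepness
    mid = 0.5 * (spec.nkcc1_start_pct + spec.nkcc1_end_pct)
    nkcc1 = _logistic(divs, spec.nkcc1_end_pct, spec.nkcc1_start_pct, k, spec.crossing_div, increasing=False)
    # solve KCC2 midpoint: kcc2(crossing) == mid
    span = spec.kcc2_end_pct - spec.kcc2_start_pct
    t0_k = spec.crossing_div + np.log(span / (mid - spec.kcc2_start_pct) - 1.0) / k
    kcc2 = _logistic(divs, spec.kcc2_start_pct, spec.kcc2_end_pct, k, t0_k, increasing=True)
    return nkcc1, kcc2


def simulate_expression(
    spec: ExpressionCurveSpec, seed: int | None = None
) -> tuple[list[ExpressionSeries], float]:
    """Sample NKCC1/KCC2 expression series; returns (series, true crossing).

    Sampled means are the noiseless curves perturbed by
    ``Normal(0, sem_pct)``; the per-point SEM recorded in the series is
    ``sem_pct`` itself.
    """
    seed = spec.seed if seed is None else seed
    divs = np.asarray(spec.sample_divs, dtype=float)
    nkcc1, kcc2 = expression_curves(spec, divs)
    # Calibrate the sampled KCC2 values by a constant offset so the
    # piecewise-linear interpolation of the noiseless *samples* crosses
    # exactly at crossing_div: the sampled trajectories are what any
    # downstream estimator sees, so the ground truth must be exact for
    # them, not just for the underlying smooth curves.
    d = kcc2 - nkcc1  # monotone increasing (KCC2 rises, NKCC1 falls)
    i = int(np.searchsorted(divs, spec.crossing_div, side="right")) - 1
    i = min(max(i, 0), divs.size - 2)
    alpha = (spec.crossing_div - divs[i]) / (divs[i + 1] - divs[i])
    kcc2 = kcc2 + (-alpha * (d[i + 1] - d[i]) - d[i])
    rng = _rng(seed, 3)
    if spec.sem_pct > 0:
        nkcc1 = nkcc1 + rng.normal(0.0, spec.sem_pct, divs.size)
        kcc2 = kcc2 + rng.normal(0.0, spec.sem_pct, divs.size)
    nkcc1 = np.maximum(nkcc1, 1e-3)
    kcc2 = np.maximum(kcc2, 1e-3)
    sem = np.full(divs.size, float(spec.sem_pct))
    n = np.full(divs.size, spec.n_per_point, dtype=int)
    series = [
        ExpressionSeries("synthetic", "NKCC1", divs, nkcc1, sem, n),
        ExpressionSeries("synthetic", "KCC2", divs, kcc2, sem, n),
    ]
    return series, float(spec.crossing_div)
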