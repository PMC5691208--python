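"""GABA-polarity-switch estimation from NKCC1/KCC2 expression curves.

The developmental switch of GABA-A signalling from depolarising to
hyperpolarising is located at the day in vitro (DIV) where the falling
NKCC1 expression trajectory is first overtaken by the rising KCC2
trajectory.  With only a handful of sampled DIVs, the trajectories are
interpolated piecewise-linearly between sampled means - any smoother
model would be under-determined by three points - and the crossing is
the smallest t in the sampled range where KCC2(t) >= NKCC1(t).

Uncertainty comes from a parametric bootstrap: each point mean is
redrawn from Normal(mean, SEM) and the crossing recomputed; the CI is
the 2.5/97.5 percentile band of the defined crossings (replicates where
the curves never cross are counted separately).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionSeries

__all__ = ["SwitchEstimate", "estimate_switch", "bootstrap_switch"]


@dataclass
class SwitchEstimate:
    crossing_div: float | None    # None = no crossing within the sampled range
    method: str = "linear"
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    seed: int | None = None
    no_crossing_fraction: float = 0.0

    @property
    def defined(self) -> bool:
        return self.crossing_div is not None


def _crossing(divs: np.ndarray, nkcc1: np.ndarray, kcc2: np.ndarray) -> float | None:
    """Smallest t with kcc2(t) - nkcc1(t) >= 0 under linear interpolation."""
    d = kcc2 - nkcc1
    if d[0] >= 0:
        return float(divs[0])
    for i in range(1, d.size):
        if d[i] >= 0:
            # linear root of d on [divs[i-1], divs[i]]
            t0, t1 = divs[i - 1], divs[i]
            return float(t0 + (t1 - t0) * (-d[i - 1]) / (d[i] - d[i - 1]))
    return None


def _check_grids(nkcc1: ExpressionSeries, kcc2: ExpressionSeries) -> np.ndarray:
    if len(nkcc1) < 2 or len(kcc2) < 2:
        raise ValueError("need at least two sampled DIVs per series")
    if not np.array_equal(nkcc1.divs, kcc2.divs):
        raise ValueError("NKCC1 and KCC2 series must share the same DIV grid")
    return nkcc1.divs


def estimate_switch(nkcc1: ExpressionSeries, kcc2: ExpressionSeries) -> SwitchEstimate:
    """Point estimate of the switch DIV from the two mean trajectories."""
    divs = _check_grids(nkcc1, kcc2)
    return SwitchEstimate(_crossing(divs, nkcc1.mean_pct, kcc2.mean_pct))


def bootstrap_switch(
    nkcc1: ExpressionSeries,
    kcc2: ExpressionSeries,
    n_boot: int = 2000,
    seed: int = 0,
) -> SwitchEstimate:
    """Point estimate plus a percentile bootstrap confidence interval.

    Raw per-culture intensities are not available, so each replicate
    perturbs the point means with Normal(0, SEM) noise (a parametric
    bootstrap of the mean).  Requires SEMs on every point and
    ``n_boot >= 100``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    divs = _check_grids(nkcc1, kcc2)
    point = _crossing(divs, nkcc1.mean_pct, kcc2.mean_pct)
    rng = np.random.default_rng(seed)
    crossings = []
    n_undefined = 0
    for _ in range(n_boot):
        nk = nkcc1.mean_pct + rng.normal(0.0, nkcc1.sem_pct)
        kc = kcc2.mean_pct + rng.normal(0.0, kcc2.sem_pct)
        c = _crossing(divs, nk, kc)
        if c is None:
            n_undefined += 1
        else:
            crossings.append(c)
    if crossings:
        lo, hi = np.percentile(crossings, [2.5, 97.5])
    else:
        lo = hi = None
    return SwitchEstimate(
        crossing_div=point,
        ci_low=None if lo is None else float(lo),
        ci_high=None if hi is None else float(hi),
        n_boot=n_boot,
        seed=seed,
        no_crossing_fraction=n_undefined / n_boot,
    )
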