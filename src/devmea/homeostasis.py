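"""Homeostatic-plasticity quantification on baseline-normalised MFR.

The perturbation protocol: record a baseline at 16 DIV, apply 20 uM
bicuculline, then follow the network mean firing rate at 2 h and 48 h,
each expressed as a percentage of baseline (100 = baseline).  A healthy
network responds (here: WT increases) and then *restores* - returns to
within a tolerance band of baseline by 48 h.  A network with impaired
homeostasis drifts away and stays away.

The restoration tolerance defaults to 12% of baseline: wide enough that
a return to ~89% still counts as restored, narrow enough that ~64%
clearly does not.  The response direction at 2 h uses a +/-5% dead-band
so measurement noise is not classified as a response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import TimelineTable

__all__ = [
    "Timeline",
    "HomeostasisVerdict",
    "normalize_to_baseline",
    "fold_change",
    "classify_homeostasis",
    "timeline_from_table",
]

DEFAULT_RESTORE_TOLERANCE_PCT = 12.0
DIRECTION_DEADBAND_PCT = 5.0
RESPONSE_LABEL = "2h"
RECOVERY_LABEL = "48h"


@dataclass
class Timeline:
    """Ordered (label, mfr_pct, sem_pct) points; baseline at 100%."""

    points: list[tuple[str, float, float]]
    baseline_label: str = "baseline"
    genotype: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        labels = [p[0] for p in self.points]
        if self.baseline_label not in labels:
            raise ValueError(f"timeline lacks a {self.baseline_label!r} point")
        if abs(self.mfr_pct(self.baseline_label) - 100.0) > 1e-9:
            raise ValueError("baseline point must be at 100%")

    def mfr_pct(self, label: str) -> float:
        for lab, mfr, _ in self.points:
            if lab == label:
                return mfr
        raise KeyError(f"no timepoint {label!r}")


@dataclass(frozen=True)
class HomeostasisVerdict:
    response_direction: str   # "increase" | "decrease" | "none"
    restored: bool
    tolerance_pct: float


def normalize_to_baseline(
    raw_mfrs: Sequence[tuple[str, float]],
    baseline_label: str = "baseline",
    sems: Sequence[float] | None = None,
    **labels: str,
) -> Timeline:
    """Convert raw MFRs in Hz to a percent-of-baseline timeline."""
    base = dict(raw_mfrs).get(baseline_label)
    if base is None:
        raise ValueError(f"no {baseline_label!r} entry")
    if base <= 0:
        raise ValueError("baseline MFR must be positive")
    sems = sems if sems is not None else [0.0] * len(raw_mfrs)
    points = [
        (lab, 100.0 * mfr / base, sem) for (lab, mfr), sem in zip(raw_mfrs, sems)
    ]
    return Timeline(points, baseline_label=baseline_label, **labels)


def fold_change(a_pct: float, b_pct: float) -> float:
    """Ratio a/b of two percent-of-baseline MFRs (units cancel)."""
    if b_pct == 0:
        raise ZeroDivisionError("fold change against a zero MFR")
    return a_pct / b_pct


def classify_homeostasis(
    t: Timeline,
    tolerance_pct: float = DEFAULT_RESTORE_TOLERANCE_PCT,
    response_label: str = RESPONSE_LABEL,
    recovery_label: str = RECOVERY_LABEL,
) -> HomeostasisVerdict:
    """Direction of the acute response and restoration at the endpoint."""
    resp = t.mfr_pct(response_label) - 100.0
    if resp > DIRECTION_DEADBAND_PCT:
        direction = "increase"
    elif resp < -DIRECTION_DEADBAND_PCT:
        direction = "decrease"
    else:
        direction = "none"
    restored = abs(t.mfr_pct(recovery_label) - 100.0) <= tolerance_pct
    return HomeostasisVerdict(direction, restored, tolerance_pct)


def timeline_from_table(table: TimelineTable, genotype: str, condition: str) -> Timeline:
    """Extract one (genotype, condition) trajectory as a Timeline."""
    df = table.trajectory(genotype, condition)
    points = [
        (str(r.timepoint), float(r.mfr_pct), float(r.sem_pct)) for r in df.itertuples()
    ]
    return Timeline(points, baseline_label=table.baseline_label,
                    genotype=genotype, condition=condition)
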