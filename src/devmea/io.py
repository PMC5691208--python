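"""Shared data model and file readers/writers.

Conventions used throughout the package:

* spike times are seconds from the start of the recording;
* spike amplitudes are the negative extracellular peak in microvolts and
  are stored with their sign (i.e. ``<= 0``);
* electrodes on the 64x64 grid are addressed by a single 0-based,
  row-major index ``e = row * n_cols + col``;
* percentage quantities (expression intensities, baseline-normalised
  firing rates) are kept on the printed scale where 100 = baseline.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ArrayGeometry",
    "RawRecording",
    "SpikeTrainSet",
    "ExpressionSeries",
    "TimelineTable",
    "read_spike_table",
    "write_spike_table",
    "read_spike_h5",
    "write_spike_h5",
    "read_expression_csv",
    "write_expression_csv",
    "read_timeline_csv",
]

SPIKE_TABLE_COLUMNS = ["electrode", "time_s", "amplitude_uV"]
EXPRESSION_COLUMNS = ["genotype", "transporter", "div", "mean_pct", "sem_pct", "n"]
TIMELINE_COLUMNS = ["genotype", "condition", "timepoint", "mfr_pct", "sem_pct"]


@dataclass(frozen=True)
class ArrayGeometry:
    """Electrode-grid geometry of a CMOS multielectrode array.

    Defaults describe a 4096-electrode chip: 64x64 grid of 21 um
    electrodes at 42 um pitch.
    """

    n_rows: int = 64
    n_cols: int = 64
    pitch_um: float = 42.0
    electrode_size_um: float = 21.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    def index(self, row: int, col: int) -> int:
        """Row-major 0-based electrode index of grid position (row, col)."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"position ({row}, {col}) outside grid")
        return row * self.n_cols + col

    def rowcol(self, electrode: int) -> tuple[int, int]:
        """Inverse of :meth:`index`."""
        if not 0 <= electrode < self.n_electrodes:
            raise IndexError(f"electrode {electrode} outside array")
        return divmod(electrode, self.n_cols)


class SpikeTrainSet:
    """Per-electrode sorted spike times and negative-peak amplitudes.

    The central object of the pipeline.  Spikes live in two parallel
    dicts keyed by electrode index; electrodes without spikes are simply
    absent.  ``metadata`` carries free-form labels (genotype, DIV,
    condition).
    """

    def __init__(
        self,
        geometry: ArrayGeometry,
        duration: float,
        times: Mapping[int, np.ndarray] | None = None,
        amplitudes: Mapping[int, np.ndarray] | None = None,
        metadata: dict | None = None,
    ) -> None:
        if duration <= 0:
            raise ValueError("duration must be positive")
        self.geometry = geometry
        self.duration = float(duration)
        self.times: dict[int, np.ndarray] = {}
        self.amplitudes: dict[int, np.ndarray] = {}
        self.metadata = dict(metadata or {})
        times = times or {}
        amplitudes = amplitudes or {}
        for e, t in times.items():
            t = np.asarray(t, dtype=float)
            a = np.asarray(
                amplitudes.get(e, np.zeros_like(t)), dtype=float
            )
            self._set_electrode(int(e), t, a)

    def _set_electrode(self, e: int, t: np.ndarray, a: np.ndarray) -> None:
        if not 0 <= e < self.geometry.n_electrodes:
            raise ValueError(f"electrode {e} outside the array")
        if t.shape != a.shape:
            raise ValueError("times and amplitudes must have equal length")
        if t.size == 0:
            return
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"spike times on electrode {e} not strictly increasing")
        if t[0] < 0 or t[-1] > self.duration:
            raise ValueError(f"spike time outside [0, duration] on electrode {e}")
        if np.any(a > 0):
            raise ValueError(f"positive spike amplitude on electrode {e}")
        self.times[e] = t
        self.amplitudes[e] = a

    @property
    def electrodes(self) -> list[int]:
        """Electrodes carrying at least one spike, ascending."""
        return sorted(self.times)

    @property
    def n_spikes(self) -> int:
        return sum(t.size for t in self.times.values())

    def spike_counts(self) -> np.ndarray:
        """Spike count per electrode over the full array (length n_electrodes)."""
        counts = np.zeros(self.geometry.n_electrodes, dtype=np.int64)
        for e, t in self.times.items():
            counts[e] = t.size
        return counts

    def all_amplitudes(self) -> np.ndarray:
        if not self.amplitudes:
            return np.empty(0)
        return np.concatenate([self.amplitudes[e] for e in self.electrodes])

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.electrodes:
            rows.append(
                pd.DataFrame(
                    {
                        "electrode": e,
                        "time_s": self.times[e],
                        "amplitude_uV": self.amplitudes[e],
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=SPIKE_TABLE_COLUMNS)
        return pd.concat(rows, ignore_index=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTrainSet):
            return NotImplemented
        if self.geometry != other.geometry or self.duration != other.duration:
            return False
        if self.electrodes != other.electrodes:
            return False
        return all(
            np.array_equal(self.times[e], other.times[e])
            and np.array_equal(self.amplitudes[e], other.amplitudes[e])
            for e in self.electrodes
        )


@dataclass
class RawRecording:
    """Per-electrode extracellular voltage traces (uV).

    ``traces`` is ``(n_traces, n_samples)``; ``electrode_ids`` maps each
    trace row to its electrode index, so a recording may cover any
    subset of the array (a full 64x64 10-minute recording at 7.8 kHz is
    rarely wanted in memory at once).
    """

    geometry: ArrayGeometry
    sampling_rate: float = 7800.0
    traces: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    electrode_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.electrode_ids is None:
            self.electrode_ids = np.arange(self.traces.shape[0])
        else:
            self.electrode_ids = np.asarray(self.electrode_ids, dtype=int)
        if self.electrode_ids.shape[0] != self.traces.shape[0]:
            raise ValueError("one electrode id per trace row required")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class ExpressionSeries:
    """Chloride-cotransporter expression over culture age.

    One series per (genotype, transporter); ``mean_pct``/``sem_pct`` are
    fluorescence intensities on the printed percent scale, ``n`` the
    number of cultures behind each point.
    """

    genotype: str
    transporter: str
    divs: np.ndarray
    mean_pct: np.ndarray
    sem_pct: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.divs = np.asarray(self.divs, dtype=float)
        self.mean_pct = np.asarray(self.mean_pct, dtype=float)
        self.sem_pct = np.asarray(self.sem_pct, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if not (self.divs.shape == self.mean_pct.shape == self.sem_pct.shape == self.n.shape):
            raise ValueError("all point arrays must share one length")
        if self.divs.size and np.any(np.diff(self.divs) <= 0):
            raise ValueError("DIVs must be strictly increasing")
        if np.any(self.mean_pct <= 0):
            raise ValueError("mean_pct must be positive")
        if np.any(self.n < 1):
            raise ValueError("n must be >= 1")

    def __len__(self) -> int:
        return self.divs.size


@dataclass
class TimelineTable:
    """Baseline-normalised MFR trajectories, one row per timepoint.

    Wraps a validated DataFrame with columns
    ``genotype,condition,timepoint,mfr_pct,sem_pct``; every
    (genotype, condition) group must contain a ``baseline`` row at 100%.
    """

    frame: pd.DataFrame
    baseline_label: str = "baseline"

    def __post_init__(self) -> None:
        missing = [c for c in TIMELINE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"timeline table missing columns {missing}")
        for (g, c), grp in self.frame.groupby(["genotype", "condition"]):
            base = grp[grp["timepoint"] == self.baseline_label]
            if len(base) != 1 or not np.isclose(base["mfr_pct"].iloc[0], 100.0):
                raise ValueError(
                    f"({g}, {c}) lacks a single {self.baseline_label!r} row at 100%"
                )

    def conditions(self) -> list[tuple[str, str]]:
        return sorted(set(zip(self.frame["genotype"], self.frame["condition"])))

    def trajectory(self, genotype: str, condition: str) -> pd.DataFrame:
        sel = self.frame[
            (self.frame["genotype"] == genotype) & (self.frame["condition"] == condition)
        ]
        if sel.empty:
            raise KeyError(f"no rows for ({genotype}, {condition})")
        return sel.reset_index(drop=True)


# ---------------------------------------------------------------------------
# spike tables (CSV and HDF5 container)
# ---------------------------------------------------------------------------

def read_spike_table(path: str | os.PathLike, geometry: ArrayGeometry, duration: float) -> SpikeTrainSet:
    """Read a ``electrode,time_s,amplitude_uV`` CSV into a SpikeTrainSet.

    Rows are sorted per electrode; out-of-array electrodes, times outside
    [0, duration], positive amplitudes and duplicate times on one
    electrode are rejected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SPIKE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spike table missing columns {missing}")
    times: dict[int, np.ndarray] = {}
    amps: dict[int, np.ndarray] = {}
    for e, grp in df.groupby("electrode"):
        e = int(e)
        order = np.argsort(grp["time_s"].to_numpy(), kind="stable")
        t = grp["time_s"].to_numpy(dtype=float)[order]
        a = grp["amplitude_uV"].to_numpy(dtype=float)[order]
        if np.any(np.diff(t) == 0):
            raise ValueError(f"duplicate spike time on electrode {e}")
        times[e] = t
        amps[e] = a
    return SpikeTrainSet(geometry, duration, times, amps)


def write_spike_table(s: SpikeTrainSet, path: str | os.PathLike) -> None:
    """Write the CSV spike-table dialect.

    Floats are written in shortest round-trip notation, so
    ``read_spike_table(write_spike_table(s))`` reproduces ``s`` exactly.
    """
    df = s.to_dataframe()
    df.to_csv(path, index=False)


def write_spike_h5(s: SpikeTrainSet, path: str | os.PathLike, sampling_rate: float | None = None) -> None:
    """Hierarchical container: ``/spikes/<electrode>`` groups with
    ``times``/``amplitudes`` datasets; geometry and duration as root
    attributes."""
    with h5py.File(path, "w") as f:
        f.attrs["duration"] = s.duration
        if sampling_rate is not None:
            f.attrs["sampling_rate"] = sampling_rate
        f.attrs["geometry"] = (s.geometry.n_rows, s.geometry.n_cols,
                               s.geometry.pitch_um, s.geometry.electrode_size_um)
        g = f.create_group("spikes")
        for e in s.electrodes:
            ge = g.create_group(str(e))
            ge.create_dataset("times", data=s.times[e])
            ge.create_dataset("amplitudes", data=s.amplitudes[e])


def read_spike_h5(path: str | os.PathLike) -> SpikeTrainSet:
    with h5py.File(path, "r") as f:
        rows, cols, pitch, size = f.attrs["geometry"]
        geometry = ArrayGeometry(int(rows), int(cols), float(pitch), float(size))
        duration = float(f.attrs["duration"])
        times, amps = {}, {}
        for key, ge in f["spikes"].items():
            e = int(key)
            times[e] = ge["times"][...]
            amps[e] = ge["amplitudes"][...]
    return SpikeTrainSet(geometry, duration, times, amps)


# ---------------------------------------------------------------------------
# expression and timeline tables
# ---------------------------------------------------------------------------

def read_expression_csv(path: str | os.PathLike) -> list[ExpressionSeries]:
    """Read ``genotype,transporter,div,mean_pct,sem_pct,n`` into one
    ExpressionSeries per (genotype, transporter), points sorted by DIV."""
    df = pd.read_csv(path)
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"expression table missing columns {missing}")
    if df.duplicated(subset=["genotype", "transporter", "div"]).any():
        raise ValueError("duplicate (genotype, transporter, div) row")
    out = []
    for (g, tr), grp in df.groupby(["genotype", "transporter"], sort=True):
        grp = grp.sort_values("div")
        out.append(
            ExpressionSeries(
                genotype=str(g),
                transporter=str(tr),
                divs=grp["div"].to_numpy(dtype=float),
                mean_pct=grp["mean_pct"].to_numpy(dtype=float),
                sem_pct=grp["sem_pct"].to_numpy(dtype=float),
                n=grp["n"].to_numpy(dtype=int),
            )
        )
    return out


def write_expression_csv(series: Iterable[ExpressionSeries], path: str | os.PathLike) -> None:
    rows = []
    for s in series:
        for i in range(len(s)):
            rows.append(
                (s.genotype, s.transporter, s.divs[i], s.mean_pct[i], s.sem_pct[i], s.n[i])
            )
    pd.DataFrame(rows, columns=EXPRESSION_COLUMNS).to_csv(path, index=False)


def read_timeline_csv(path: str | os.PathLike, baseline_label: str = "baseline") -> TimelineTable:
    """Read ``genotype,condition,timepoint,mfr_pct,sem_pct`` rows."""
    return TimelineTable(pd.read_csv(path), baseline_label=baseline_label)
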