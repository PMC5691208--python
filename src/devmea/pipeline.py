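"""End-to-end orchestration: simulate -> detect -> metrics -> bursts ->
distributions -> homeostasis -> switch, with a machine-readable summary.

``PipelineConfig`` round-trips through plain dict/YAML; every stage
parameter defaults to the value documented in its own module, and the
summary echoes every parameter and seed actually used so a run is fully
reproducible from its summary alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import datasets
from .activity import compute_activity, summarize_amplitudes
from .bursts import detect_bursts, detect_network_bursts, ibi_distribution
from .homeostasis import classify_homeostasis, timeline_from_table
from .io import ArrayGeometry, read_expression_csv, read_spike_table, read_timeline_csv, write_spike_table
from .ratedist import build_rate_distribution
from .switch import bootstrap_switch
from .synth import NetworkPreset, simulate_network

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "activity", "bursts", "ratedist", "homeostasis", "switch")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "devmea_out"
    stages: tuple[str, ...] = STAGES
    # simulate
    preset: str = "WT-16div"
    duration_s: float = 300.0
    # spike input used instead of simulation when given
    spikes_csv: str | None = None
    spikes_duration_s: float | None = None
    # burst analysis
    nb_bin_ms: float = 15.0
    nb_window_ms: float = 150.0
    nb_threshold_frac: float = 0.15
    # amplitude summary
    amplitude_cutoff_uv: float = -250.0
    # homeostasis
    timeline_csv: str | None = None
    restore_tolerance_pct: float = 12.0
    # switch
    expression_csv: str | None = None
    switch_genotype: str = "Lgdel"
    n_boot: int = 2000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _check_dependencies(cfg: PipelineConfig) -> None:
    needs_spikes = {"activity", "bursts", "ratedist"} & set(cfg.stages)
    if needs_spikes and "simulate" not in cfg.stages and cfg.spikes_csv is None:
        raise ValueError(
            f"stages {sorted(needs_spikes)} need spikes: enable 'simulate' or set spikes_csv"
        )


def run_pipeline(cfg: PipelineConfig, geometry: ArrayGeometry = ArrayGeometry()) -> dict:
    """Execute the enabled stages in dependency order.

    Writes per-stage outputs plus ``summary.json`` under ``cfg.out_dir``
    and returns the summary dict.  Identical configs yield identical
    summaries.
    """
    _check_dependencies(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, val in sorted(cfg.to_dict().items()):
        logger.info("config %s = %r", key, val)
    summary: dict = {"config": cfg.to_dict()}

    spikes = None
    if "simulate" in cfg.stages:
        preset = datasets.load_presets()[cfg.preset]
        spikes, truth = simulate_network(preset, cfg.duration_s, geometry, seed=cfg.seed)
        write_spike_table(spikes, out / "spikes.csv")
        summary["simulate"] = {
            "preset": cfg.preset,
            "n_spikes": spikes.n_spikes,
            "n_planted_nb": int(truth.nb_times.size),
        }
    elif cfg.spikes_csv is not None:
        if cfg.spikes_duration_s is None:
            raise ValueError("spikes_duration_s required with spikes_csv")
        spikes = read_spike_table(cfg.spikes_csv, geometry, cfg.spikes_duration_s)

    activity = None
    if "activity" in cfg.stages:
        activity = compute_activity(spikes)
        amp = summarize_amplitudes(spikes, cfg.amplitude_cutoff_uv)
        summary["activity"] = {
            "mfr_hz": activity.mfr_hz,
            "n_active": activity.n_active,
            "mean_negative_peak_uv": None if not amp.available else amp.mean_negative_peak_uv,
            "n_spikes_at_cutoff": amp.n_spikes_used,
        }
        np.savetxt(out / "rate_map.csv", activity.mfr_map, delimiter=",", fmt="%.6g")

    if "bursts" in cfg.stages:
        burst_list, mbr = detect_bursts(spikes)
        nbs = detect_network_bursts(
            spikes, cfg.nb_bin_ms, cfg.nb_window_ms, cfg.nb_threshold_frac
        )
        entry = {"n_bursts": len(burst_list), "mbr_per_min": mbr, "n_network_bursts": len(nbs)}
        if len(nbs) >= 2:
            ibi = ibi_distribution(nbs)
            entry["nb_ibi_median_s"] = float(np.median(ibi.values_s))
        summary["bursts"] = entry
        with open(out / "bursts.json", "w") as f:
            json.dump(entry, f, indent=2)

    if "ratedist" in cfg.stages:
        if activity is None:
            activity = compute_activity(spikes)
        dist = build_rate_distribution(activity)
        summary["ratedist"] = {
            "fit_mu_log10hz": dist.fit_mu,
            "fit_sigma_log10hz": dist.fit_sigma,
            "n_active": dist.n_active,
        }
        centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
        np.savetxt(
            out / "rate_distribution.csv",
            np.column_stack([centers, dist.occurrence]),
            delimiter=",",
            header="bin_center_log10hz,occurrence",
            comments="",
        )

    if "homeostasis" in cfg.stages:
        table = (
            read_timeline_csv(cfg.timeline_csv)
            if cfg.timeline_csv
            else datasets.load_timeline_fixture()
        )
        verdicts = {}
        for genotype, condition in table.conditions():
            tl = timeline_from_table(table, genotype, condition)
            try:
                v = classify_homeostasis(tl, cfg.restore_tolerance_pct)
            except KeyError:
                continue  # trajectory without the 2h/48h protocol points
            verdicts[f"{genotype}/{condition}"] = {
                "response_direction": v.response_direction,
                "restored": v.restored,
            }
        summary["homeostasis"] = verdicts
        with open(out / "homeostasis.json", "w") as f:
            json.dump(verdicts, f, indent=2)

    if "switch" in cfg.stages:
        if cfg.expression_csv:
            series = read_expression_csv(cfg.expression_csv)
            pick = lambda tr: next(
                s for s in series if s.genotype == cfg.switch_genotype and s.transporter == tr
            )
            nkcc1, kcc2 = pick("NKCC1"), pick("KCC2")
        else:
            nkcc1 = datasets.expression_series(cfg.switch_genotype, "NKCC1")
            kcc2 = datasets.expression_series(cfg.switch_genotype, "KCC2")
        est = bootstrap_switch(nkcc1, kcc2, n_boot=cfg.n_boot, seed=cfg.seed)
        summary["switch"] = {
            "genotype": cfg.switch_genotype,
            "crossing_div": est.crossing_div,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
            "no_crossing_fraction": est.no_crossing_fraction,
        }
        with open(out / "switch.json", "w") as f:
            json.dump(summary["switch"], f, indent=2)

    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=2)
    return summary
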