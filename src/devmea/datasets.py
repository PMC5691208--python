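"""Packaged reference tables and named presets.

``load_expression_fixture`` / ``load_timeline_fixture`` return the
published summary tables (expression intensities and percent-of-baseline
MFR trajectories) that the switch estimator and homeostasis classifier
operate on; ``load_presets`` returns the named synthetic-network
conditions used throughout the tests.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .io import ExpressionSeries, TimelineTable, read_expression_csv, read_timeline_csv
from .synth import NetworkPreset

__all__ = [
    "load_expression_fixture",
    "load_timeline_fixture",
    "load_presets",
    "expression_series",
]


def _data_path(name: str):
    return resources.files("devmea.data").joinpath(name)


def load_expression_fixture() -> list[ExpressionSeries]:
    """All published NKCC1/KCC2 expression series (WT, Lgdel, Dgcr8 at
    DIVs 8/16/26; the 8-DIV WT reference is normalised to 100%)."""
    with resources.as_file(_data_path("expression_fixture.csv")) as p:
        return read_expression_csv(p)


def expression_series(genotype: str, transporter: str) -> ExpressionSeries:
    """Convenience selector over :func:`load_expression_fixture`."""
    for s in load_expression_fixture():
        if s.genotype == genotype and s.transporter == transporter:
            return s
    raise KeyError(f"no fixture series for ({genotype}, {transporter})")


def load_timeline_fixture() -> TimelineTable:
    """Published percent-of-baseline MFR trajectories for the
    bicuculline homeostasis protocol and the bumetanide rescue
    experiments.

    Note: the 83.76 +/- 8.05% value appears twice in the source (18-DIV
    bumetanide-treated and 26-DIV bumetanide-untreated Lgdel), an
    apparent typographic duplication there; both rows are kept as
    printed.
    """
    with resources.as_file(_data_path("timeline_fixture.csv")) as p:
        return read_timeline_csv(p)


def load_presets() -> dict[str, NetworkPreset]:
    """Named NetworkPreset fixtures (e.g. 'WT-8div', 'Lgdel-16div')."""
    with resources.as_file(_data_path("presets.yaml")) as p:
        raw = yaml.safe_load(p.read_text())
    return {name: NetworkPreset(**params) for name, params in raw.items()}
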