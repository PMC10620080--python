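"""Plain-text readers/writers and run manifests shared by all stages.

TSV is the universal interchange: pupation records, count tables, gene
annotations and trajectory/sweep exports all travel as tab-separated text.
Scenario configuration is YAML.  Every CLI invocation writes a
``manifest.yaml`` next to its outputs recording the subcommand, resolved
configuration, seeds and package version, so a run can be reproduced from
its manifest alone.
"""

from __future__ import annotations

import datetime
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .selection import EventSchedule, FitnessScheme

__all__ = [
    "RunManifest",
    "read_records",
    "write_records",
    "read_counts",
    "write_counts",
    "read_annotation",
    "write_annotation",
    "write_table",
    "load_config",
    "parse_scheme",
    "parse_events",
]


@dataclass
class RunManifest:
    subcommand: str
    config: dict = field(default_factory=dict)
    seed: int | None = None
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    package_version: str = ""
    timestamp: str = ""

    def write(self, directory: Path) -> Path:
        from . import __version__

        self.package_version = self.package_version or __version__
        self.timestamp = self.timestamp or datetime.datetime.now().isoformat(timespec="seconds")
        path = Path(directory) / "manifest.yaml"
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
        return path


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "observed" in df.columns:
        df["observed"] = df["observed"].astype(bool)
    return df


def write_records(records: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    """Genes x samples count table; first column is the gene id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    counts.to_csv(path, sep="\t", index_label="gene")


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cluster": str})
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    annotation.to_csv(path, sep="\t", index=False)


def write_table(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def parse_scheme(config: dict) -> FitnessScheme:
    """Build a FitnessScheme from a config mapping with keys s_m, s_f, h_m, h_f."""
    scheme_cfg = config.get("scheme", config)
    return FitnessScheme(
        s_m=float(scheme_cfg.get("s_m", 0.0177)),
        s_f=float(scheme_cfg.get("s_f", 0.0)),
        h_m=float(scheme_cfg.get("h_m", 1.0)),
        h_f=float(scheme_cfg.get("h_f", 0.0)),
    )


def parse_events(config: dict) -> EventSchedule:
    """Events as a list of [generation, parameter, value] triples."""
    return EventSchedule.from_triples(config.get("events", []))
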