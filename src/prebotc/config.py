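"""Experiment configuration schema with lossless YAML round-tripping.

A single :class:`ExperimentConfig` captures everything needed to reproduce a
run of either model: parameter blocks (defaults equal the published constant
tables), seeds, integration settings, and a label.  Every numeric field can
be overridden; unknown keys are rejected with a field-level diagnostic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import SimulationConfig
from .network import ConnectivitySpec, PopulationSpec

__all__ = ["ReducedConfig", "ExperimentConfig", "load_config", "save_config"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ReducedConfig:
    """Settings for a reduced-model run."""

    w: float = 2.0
    duration: float = 300_000.0  # ms
    discard: float = 50_000.0  # ms
    dt: float = 0.5  # ms
    record_dt: float = 5.0  # ms
    el_perturbation: tuple[float, float, float] | None = None  # (t0, t1, factor)


@dataclass
class ExperimentConfig:
    """Complete, serializable description of one experiment."""

    model: str = "large_scale"  # or "reduced"
    label: str = "experiment"
    population: PopulationSpec = field(default_factory=PopulationSpec)
    connectivity: ConnectivitySpec = field(default_factory=ConnectivitySpec)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    reduced: ReducedConfig = field(default_factory=ReducedConfig)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.model not in ("large_scale", "reduced"):
            raise ValueError(f"model must be 'large_scale' or 'reduced', got {self.model!r}")


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config field(s) at {path}: {sorted(unknown)}")
    return cls(**data)


def config_to_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    rv = d["simulation"]["record_voltage_ids"]
    d["simulation"]["record_voltage_ids"] = list(rv)
    if d["reduced"]["el_perturbation"] is not None:
        d["reduced"]["el_perturbation"] = list(d["reduced"]["el_perturbation"])
    return d


def config_from_dict(data: dict) -> ExperimentConfig:
    data = dict(data)
    version = data.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version}")
    blocks = {}
    if "population" in data:
        blocks["population"] = _build(PopulationSpec, data.pop("population"), "population")
    if "connectivity" in data:
        blocks["connectivity"] = _build(ConnectivitySpec, data.pop("connectivity"), "connectivity")
    if "simulation" in data:
        sim = dict(data.pop("simulation"))
        if "record_voltage_ids" in sim:
            sim["record_voltage_ids"] = tuple(sim["record_voltage_ids"])
        blocks["simulation"] = _build(SimulationConfig, sim, "simulation")
    if "reduced" in data:
        red = dict(data.pop("reduced"))
        if red.get("el_perturbation") is not None:
            red["el_perturbation"] = tuple(red["el_perturbation"])
        blocks["reduced"] = _build(ReducedConfig, red, "reduced")
    return _build(ExperimentConfig, {**data, **blocks, "schema_version": SCHEMA_VERSION}, "<root>")


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def load_config(path: str | Path) -> ExperimentConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
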