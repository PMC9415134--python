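"""YAML run configuration: one validated document aggregating all defaults.

The defaults equal the reference settings: Z1=10, Z2=18 parallel hidden
neurons, 64 ELM baseline nodes, 2:6:2 partition ratio, chunk size 40,
C_Hth = 2 × mean contribution degree and C_Lth = min{0.05, 1/(Z1+Z2)}.
Unknown keys anywhere in the document are rejected, and every section is
validated through its dataclass's own invariants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .adapt import AdaptationConfig
from .exceptions import ConfigurationError
from .network import NetworkConfig
from .preprocessing import FeatureGrouping
from .rf import AttenuationModel, DriftSpec, RFLinkParams, ScenarioRanges

__all__ = ["SimulationConfig", "TrainingConfig", "RunConfig", "load_config"]


def _build(cls, doc: dict, path: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: expected a mapping, got {type(doc).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(doc) - names
    if unknown:
        raise ConfigurationError(f"{path}: unknown key(s) {sorted(unknown)}")
    converted = {}
    for f in dataclasses.fields(cls):
        if f.name not in doc:
            continue
        v = doc[f.name]
        if isinstance(v, list):
            v = tuple(v)
        converted[f.name] = v
    return cls(**converted)


@dataclass(frozen=True)
class SimulationConfig:
    """Synthetic-dataset settings: acquisition protocol plus scenario ranges."""

    n: int = 1000
    n_reads: int = 100
    noise_halfwidth: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1 or self.n_reads < 1:
            raise ConfigurationError("n and n_reads must be >= 1")
        if self.noise_halfwidth < 0:
            raise ConfigurationError("noise_halfwidth must be >= 0")


@dataclass(frozen=True)
class TrainingConfig:
    """Streaming-training settings."""

    chunk_size: int = 40
    ratio: tuple[float, float, float] = (2.0, 6.0, 2.0)
    mu: float = 1.0
    elm_hidden: int = 64
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.chunk_size < 1:
            raise ConfigurationError("chunk_size must be >= 1")
        if len(self.ratio) != 3 or any(r <= 0 for r in self.ratio):
            raise ConfigurationError("ratio must be three positive numbers")
        if not (0 < self.mu <= 1):
            raise ConfigurationError("mu must be in (0, 1]")


@dataclass(frozen=True)
class RunConfig:
    """Full validated run configuration (see module docstring for defaults)."""

    link: RFLinkParams = field(default_factory=RFLinkParams)
    attenuation: AttenuationModel = field(default_factory=AttenuationModel)
    ranges: ScenarioRanges = field(default_factory=ScenarioRanges)
    drift: DriftSpec = field(default_factory=DriftSpec)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    adaptation: AdaptationConfig = field(default_factory=AdaptationConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)


_SECTIONS = {
    "link": RFLinkParams,
    "attenuation": AttenuationModel,
    "ranges": ScenarioRanges,
    "drift": DriftSpec,
    "network": NetworkConfig,
    "adaptation": AdaptationConfig,
    "simulation": SimulationConfig,
    "training": TrainingConfig,
}


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if doc is None:
        return RunConfig()
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    unknown = set(doc) - set(_SECTIONS)
    if unknown:
        raise ConfigurationError(f"{path}: unknown section(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in doc:
            section = doc[name]
            if name == "network" and isinstance(section, dict) and "grouping" in section:
                section = dict(section)
                section["grouping"] = _build(FeatureGrouping, section["grouping"], f"{name}.grouping")
            kwargs[name] = _build(cls, section, name)
    return RunConfig(**kwargs)
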