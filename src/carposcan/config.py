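"""Run configuration: YAML-backed, strict, defaulting to the pipeline constants.

Defaults reproduce the analysis constants throughout: ring boundaries at
30/55/75/100 % of the radius, carpel cut at 30 %, 10 a* bins on [0, 60],
a mean-a* filter threshold of 10, and alpha = 0.05.  Unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .color_features import RingSpec
from .segmentation import SegmentationConfig
from .synthetic_data import FadingProfile, GeneticScenario

__all__ = ["RunConfig", "TraitsConfig", "StatsConfig", "load_config"]


@dataclass
class TraitsConfig:
    k: int = 10
    mean_a_threshold: float = 10.0


@dataclass
class StatsConfig:
    alpha: float = 0.05


@dataclass
class RunConfig:
    seg: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: RingSpec = field(default_factory=RingSpec)
    traits: TraitsConfig = field(default_factory=TraitsConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    simulate: GeneticScenario = field(default_factory=GeneticScenario)
    seed: int = 0


_SECTION_TYPES = {
    "seg": SegmentationConfig,
    "features": RingSpec,
    "traits": TraitsConfig,
    "stats": StatsConfig,
    "simulate": GeneticScenario,
}


def _build_section(cls, mapping: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown key(s) in config section {section!r}: {sorted(unknown)}")
    kwargs = dict(mapping)
    if isinstance(kwargs.get("base_profile"), dict):
        kwargs["base_profile"] = FadingProfile(**kwargs["base_profile"])
    # tuples serialize as lists in YAML
    for f in fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(
                tuple(v) if isinstance(v, list) else v for v in kwargs[f.name]
            )
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a RunConfig from a YAML document; ``None`` gives pure defaults."""
    if path is None:
        return RunConfig()
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(doc) - set(_SECTION_TYPES) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name in doc:
            kwargs[name] = _build_section(cls, doc[name] or {}, name)
    if "seed" in doc:
        kwargs["seed"] = int(doc["seed"])
    return RunConfig(**kwargs)


def config_to_dict(cfg: RunConfig) -> dict:
    """Plain-dict view of a RunConfig (for run-summary JSON)."""
    return dataclasses.asdict(cfg)
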