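"""YAML configuration mapping onto the package's parameter dataclasses.

A config file may contain any of the top-level sections ``wave``, ``rhythm``,
``noise``, ``filter``, ``iat``, ``position``; each section's keys are the
corresponding dataclass fields. Missing sections fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .iat import IATConfig
from .position import PositionNetConfig
from .preprocess import FilterSpec
from .synth import NoiseModel, RhythmModel, WaveParams

SECTIONS = {
    "wave": WaveParams,
    "rhythm": RhythmModel,
    "noise": NoiseModel,
    "filter": FilterSpec,
    "iat": IATConfig,
    "position": PositionNetConfig,
}


def load_config(path) -> dict:
    """Parse a YAML file into a dict of constructed config objects."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for name, cls in SECTIONS.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            raise ValueError(f"config section {name!r} must be a mapping")
        out[name] = cls(**section)
    return out


def default_config() -> dict:
    return {name: cls() for name, cls in SECTIONS.items()}


def dump_config(config: dict, path) -> None:
    """Write the dataclass sections back to YAML."""
    raw = {}
    for name, obj in config.items():
        raw[name] = dataclasses.asdict(obj)
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))
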