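"""YAML/JSON round-tripping for scenario configurations."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .experiments import ScenarioConfig

__all__ = ["load_config", "save_config", "config_hash"]


def load_config(path: str | Path) -> ScenarioConfig:
    """Read a scenario configuration from a YAML (or JSON) file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return ScenarioConfig.from_dict(data)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config: ScenarioConfig) -> str:
    """Short stable digest of a configuration, for run logs."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
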