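"""YAML configuration loading for the generator, spectral front end and models."""

from __future__ import annotations

from pathlib import Path

import yaml

from .bandpower import SpectralConfig
from .models import ModelSpec
from .synthetic import GeneratorConfig


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def generator_config(path: str | Path | None, **overrides) -> GeneratorConfig:
    """GeneratorConfig from a YAML file's ``cohort`` section (or defaults)."""
    data = load_yaml(path).get("cohort", {}) if path else {}
    data.update(overrides)
    return GeneratorConfig(**data)


def spectral_config(path: str | Path | None, **overrides) -> SpectralConfig:
    data = load_yaml(path).get("spectral", {}) if path else {}
    data.update(overrides)
    if "bands" in data:
        data["bands"] = {k: tuple(v) for k, v in data["bands"].items()}
    return SpectralConfig(**data)


def model_spec(path: str | Path | None, **overrides) -> ModelSpec:
    data = load_yaml(path).get("model", {}) if path else {}
    data.update(overrides)
    if "space" in data and data["space"] is not None:
        data["space"] = {k: tuple(v) for k, v in data["space"].items()}
    return ModelSpec(**data)
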