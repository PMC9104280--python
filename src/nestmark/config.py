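"""Structured pipeline configuration with strict key validation.

A single YAML file holds per-stage sections; command-line flags
override it. Unknown keys are rejected by name so a typo can never
silently fall back to a default tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping, Union

import yaml

from .align import MatchParams
from .confirm import ConfirmParams
from .markers import SelectionCriteria

__all__ = ["PipelineConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class ClassifierConfig:
    white_markers: tuple[str, ...] = ("W2",)
    ebn_markers: tuple[str, ...] = ("E7",)
    grass_markers: tuple[str, ...] = ("G1",)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    alignment: MatchParams = field(default_factory=MatchParams)
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)
    confirmation: ConfirmParams = field(default_factory=ConfirmParams)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    extra_adulterants: tuple[str, ...] = ()


_SECTIONS = {
    "alignment": MatchParams,
    "selection": SelectionCriteria,
    "confirmation": ConfirmParams,
    "classifier": ClassifierConfig,
}


def _build(cls: type, data: Mapping[str, Any], section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}; "
            f"allowed: {sorted(allowed)}"
        )
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    return cls(**coerced)


def load_config(path: Union[str, Path, None]) -> PipelineConfig:
    """Load and validate a pipeline configuration; None gives the defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    top_allowed = set(_SECTIONS) | {"seed", "extra_adulterants"}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}; allowed: {sorted(top_allowed)}")
    kwargs: dict[str, Any] = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "extra_adulterants" in raw:
        kwargs["extra_adulterants"] = tuple(raw["extra_adulterants"])
    for name, cls in _SECTIONS.items():
        if name in raw:
            section = raw[name]
            if not isinstance(section, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            try:
                kwargs[name] = _build(cls, section, name)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"section {name!r}: {exc}") from exc
    return PipelineConfig(**kwargs)
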