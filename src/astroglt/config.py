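"""Run configuration: YAML loading, validation and resolved-config dumps.

Defaults equal the published model parameters; a config file only lists
overrides.  Unknown keys are rejected by name so garbled configs fail loudly,
and every run can write its fully resolved configuration next to its outputs
for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .glt1 import GLT1Params, IonState
from .hotspot import StimulusField
from .membrane import MembraneParams
from .morphology import MorphologyConfig
from .synth import SynthConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_resolved"]


class ConfigError(ValueError):
    pass


_SECTIONS = {
    "glt1": GLT1Params,
    "membrane": MembraneParams,
    "ions": IonState,
    "morphology": MorphologyConfig,
    "stimulus": StimulusField,
    "synth": SynthConfig,
}


@dataclass(frozen=True)
class RunConfig:
    glt1: GLT1Params = field(default_factory=GLT1Params)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    ions: IonState = field(default_factory=IonState)
    morphology: MorphologyConfig = field(default_factory=MorphologyConfig)
    stimulus: StimulusField = field(default_factory=StimulusField)
    synth: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0
    out_dir: str = "results"


def _build_section(cls, data: dict, section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section '{section}': {', '.join(sorted(unknown))}"
        )
    coerced = {k: (tuple(v) if isinstance(v, list) else v) for k, v in data.items()}
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section '{section}': {exc}") from exc


def load_config(path=None) -> RunConfig:
    """Load a YAML config; an empty/missing file yields the full defaults."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
    top_extra = set(raw) - set(_SECTIONS) - {"seed", "out_dir"}
    if top_extra:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(top_extra))}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        sec = raw.get(name, {}) or {}
        if not isinstance(sec, dict):
            raise ConfigError(f"section '{name}' must be a mapping")
        kwargs[name] = _build_section(cls, sec, name)
    return RunConfig(seed=int(raw.get("seed", 0)),
                     out_dir=str(raw.get("out_dir", "results")), **kwargs)


def dump_resolved(config: RunConfig, path) -> None:
    """Write the fully resolved configuration as JSON next to run outputs."""
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    doc = {name: enc(getattr(config, name)) for name in _SECTIONS}
    doc["seed"] = config.seed
    doc["out_dir"] = config.out_dir
    Path(path).write_text(json.dumps(doc, indent=1))
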