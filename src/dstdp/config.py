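"""YAML round-trip for the full simulation configuration.

A config file has four named sections (``window``, ``neuron``, ``inputs``,
``run``), each a flat key-value mapping onto the corresponding dataclass;
missing keys take the dataclass defaults, unknown keys are an error.
"""

from __future__ import annotations

from dataclasses import fields

import yaml

from .exceptions import ParameterError
from .inputs import InputConfig
from .neuron import NeuronParams
from .simulator import RunConfig, SimConfig
from .window import WindowParams

_SECTIONS = {"window": WindowParams, "neuron": NeuronParams,
             "inputs": InputConfig, "run": RunConfig}


def _build(cls, mapping: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ParameterError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if cls is RunConfig and isinstance(mapping.get("signal_window_s"), list):
        mapping = dict(mapping, signal_window_s=tuple(mapping["signal_window_s"]))
    return cls(**mapping)


def config_from_dict(data: dict) -> SimConfig:
    extra = set(data) - set(_SECTIONS)
    if extra:
        raise ParameterError(f"unknown config sections: {sorted(extra)}")
    parts = {name: _build(cls, dict(data.get(name) or {}))
             for name, cls in _SECTIONS.items()}
    return SimConfig(**parts)


def load_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
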