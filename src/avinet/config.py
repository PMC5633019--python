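"""Plain-text ``key = value`` configuration files.

A config bundles the environment, network, learning and schedule
parameters under dotted keys, e.g.::

    env.sigma0_v_deg = 4.0
    net.tau_ms = 3.0
    learn.gamma_rf = 0.02
    schedule.epochs = 100

Unknown keys are rejected; omitted keys keep their defaults.  ``#``
starts a comment.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields

from .learning import LearningParams, TrainingSchedule
from .network import NetworkParams
from .stimuli import EnvironmentParams

__all__ = ["ModelConfig", "load_config", "save_config", "config_hash"]

_SECTIONS = {
    "env": EnvironmentParams,
    "net": NetworkParams,
    "learn": LearningParams,
    "schedule": TrainingSchedule,
}


@dataclass
class ModelConfig:
    env: EnvironmentParams = field(default_factory=EnvironmentParams)
    net: NetworkParams = field(default_factory=NetworkParams)
    learn: LearningParams = field(default_factory=LearningParams)
    schedule: TrainingSchedule = field(default_factory=TrainingSchedule)


def _parse_value(raw: str, target_type):
    raw = raw.strip()
    if target_type is bool:
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"not a boolean: {raw!r}")
    return target_type(raw)


def load_config(path) -> ModelConfig:
    """Read a ``key = value`` file into a :class:`ModelConfig`."""
    raw: dict[str, dict[str, str]] = {name: {} for name in _SECTIONS}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if "." not in key:
                raise ValueError(f"{path}:{lineno}: key must be '<section>.<name>'")
            section, name = key.split(".", 1)
            if section not in _SECTIONS:
                raise ValueError(f"{path}:{lineno}: unknown section {section!r}")
            raw[section][name] = value

    kwargs = {}
    for section, cls in _SECTIONS.items():
        known = {f.name: f for f in fields(cls)}
        params = {}
        for name, value in raw[section].items():
            if name not in known:
                raise ValueError(f"unknown key {section}.{name}")
            params[name] = _parse_value(value, type(known[name].default))
        kwargs[section] = cls(**params)
    return ModelConfig(**kwargs)


def save_config(config: ModelConfig, path) -> None:
    """Write every parameter of a config as ``section.name = value``."""
    with open(path, "w") as fh:
        for section, cls in _SECTIONS.items():
            obj = getattr(config, section)
            for f in fields(cls):
                fh.write(f"{section}.{f.name} = {getattr(obj, f.name)}\n")


def config_hash(config: ModelConfig) -> str:
    """Short stable hash of every parameter value, for provenance
    columns in result tables."""
    parts = []
    for section, cls in _SECTIONS.items():
        obj = getattr(config, section)
        for f in fields(cls):
            parts.append(f"{section}.{f.name}={getattr(obj, f.name)!r}")
    return hashlib.sha256(";".join(parts).encode()).hexdigest()[:12]
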