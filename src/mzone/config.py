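"""Run configuration: one human-editable YAML file covering neuron
parameters, network geometry and simulation settings.

An empty (or absent-section) file yields the standard defaults.  Unknown
keys are rejected with a message naming the offending key, so typos cannot
silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from .network import NetworkConfig
from .neuron import CellClass, NeuronParams, DEFAULT_PARAMS, DT_MS, ParameterError

__all__ = ["RunConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    """Malformed run-configuration file."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run, minus the experiment choice."""

    neuron_params: Dict[CellClass, NeuronParams] = field(
        default_factory=lambda: dict(DEFAULT_PARAMS)
    )
    network: NetworkConfig = field(default_factory=NetworkConfig)
    duration_ms: float = 300_000.0
    dt: float = DT_MS
    sim_seed: int = 0
    out_dir: str = "mzone_out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "neuron_params": {
                cls.value: p.to_dict() for cls, p in self.neuron_params.items()
            },
            "network": self.network.to_dict(),
            "duration_ms": self.duration_ms,
            "dt": self.dt,
            "sim_seed": self.sim_seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }


_TOP_KEYS = {
    "neuron_params", "network", "duration_ms", "dt", "sim_seed", "out_dir", "log_level",
}


def _check_keys(given: dict, allowed: set, context: str) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {', '.join(sorted(unknown))}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Every field is either taken from the file or from the documented
    defaults; partial neuron-parameter overrides are merged onto the default
    cell-class profiles.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration file must contain a mapping")
    _check_keys(raw, _TOP_KEYS, "configuration")

    cfg = RunConfig()
    if "neuron_params" in raw:
        np_raw = raw["neuron_params"]
        _check_keys(np_raw, {c.value for c in CellClass}, "neuron_params")
        param_fields = {f.name for f in dataclasses.fields(NeuronParams)}
        for cls_name, overrides in np_raw.items():
            cls = CellClass(cls_name)
            _check_keys(overrides, param_fields, f"neuron_params.{cls_name}")
            overrides = dict(overrides)
            # a redundant cell_class entry (as written by save_config) is
            # accepted as long as it matches its section
            if overrides.pop("cell_class", cls_name) != cls_name:
                raise ConfigError(
                    f"neuron_params.{cls_name}: cell_class does not match section"
                )
            try:
                cfg.neuron_params[cls] = cfg.neuron_params[cls].with_updates(**overrides)
            except ParameterError as e:
                raise ConfigError(f"neuron_params.{cls_name}: {e}") from e
    if "network" in raw:
        net_fields = {f.name for f in dataclasses.fields(NetworkConfig)}
        _check_keys(raw["network"], net_fields, "network")
        merged = cfg.network.to_dict() | raw["network"]
        try:
            cfg.network = NetworkConfig.from_dict(merged)
        except ParameterError as e:
            raise ConfigError(f"network: {e}") from e
    for key in ("duration_ms", "dt", "sim_seed", "out_dir", "log_level"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if cfg.dt <= 0 or cfg.duration_ms < cfg.dt:
        raise ConfigError("duration_ms must be at least one positive dt")
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
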