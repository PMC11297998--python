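"""Reading model parameters from TOML or JSON config files.

A config file carries exactly the seven society parameters::

    omega = 0.4
    epsilon = 0.3
    n_group = 100
    v_total = 1.0
    c_total = 2.0
    d_v = 0.55
    d_c = 0.55

Unknown keys are rejected outright so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Any, Dict, Optional

from .errors import ConfigError
from .payoffs import ModelConfig

__all__ = ["load_model_config", "read_config_mapping"]

_ALLOWED = {f.name for f in dc_fields(ModelConfig)}


def read_config_mapping(path) -> Dict[str, Any]:
    """Parse a TOML (``.toml``) or JSON config file into a plain dict."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config file must contain a table/object at top level")
    unknown = sorted(set(data) - _ALLOWED)
    if unknown:
        raise ConfigError(
            f"{path}: unknown config keys {unknown}; allowed keys are {sorted(_ALLOWED)}"
        )
    return data


def load_model_config(path, overrides: Optional[Dict[str, Any]] = None) -> ModelConfig:
    """Build a :class:`ModelConfig` from a file, with optional overrides.

    ``overrides`` (typically CLI flags) take precedence over file values;
    ``None`` values in it are ignored.
    """
    data = read_config_mapping(path)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    missing = sorted(_ALLOWED - set(data) - {"v_total", "c_total", "d_v", "d_c"})
    if missing:
        raise ConfigError(f"{path}: missing required config keys {missing}")
    return ModelConfig(**data)
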