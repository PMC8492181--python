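"""Run-configuration parsing for the command-line interface.

A config file is a flat YAML/JSON mapping: the ``model`` tag and its
rate parameters, plus optional run options.  Unknown keys are rejected
so typos fail loudly; defaults are filled for omitted options and the
file's SHA-256 is logged for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .models import MechanisticParams, RefractoryParams, TwoStateParams, params_from_dict

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "save_config"]

_OPTION_DEFAULTS = {
    "samples": 10_000,
    "seed": 1,
    "horizon": None,
    "n_max": None,
    "deficit_tol": 1e-9,
}


@dataclass
class RunConfig:
    """Validated parameters plus run options with defaults applied."""

    params: MechanisticParams | TwoStateParams | RefractoryParams
    samples: int = 10_000
    seed: int = 1
    horizon: float | None = None
    n_max: int | None = None
    deficit_tol: float = 1e-9
    source_hash: str | None = None


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML or JSON run configuration."""
    path = Path(path)
    raw = path.read_bytes()
    data = yaml.safe_load(raw)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(data).__name__}")
    options = {}
    for key in list(data):
        if key in _OPTION_DEFAULTS:
            options[key] = data.pop(key)
    params = params_from_dict(data)  # rejects unknown/invalid parameter keys
    merged = {**_OPTION_DEFAULTS, **options}
    digest = hashlib.sha256(raw).hexdigest()[:16]
    log.info("loaded config %s (sha256:%s): %s", path, digest, merged)
    return RunConfig(params=params, source_hash=digest, **merged)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config back out; ``save -> load`` is the identity on content."""
    from .models import params_to_dict

    data = params_to_dict(config.params)
    for f in fields(config):
        if f.name in _OPTION_DEFAULTS:
            value = getattr(config, f.name)
            if value is not None:
                data[f.name] = value
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
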