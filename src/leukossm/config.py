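"""Configuration handling.

All fixed model constants and default optimiser initial values live in a
YAML file (``data/defaults.yaml`` inside the package) so that nothing is
hard-coded; :func:`load_config` merges a user file over those defaults.
"""
from __future__ import annotations

import copy
from importlib import resources
from typing import Any

import yaml

_DEFAULTS: dict[str, Any] | None = None


def default_config() -> dict[str, Any]:
    """Return a deep copy of the packaged default configuration."""
    global _DEFAULTS
    if _DEFAULTS is None:
        text = resources.files("leukossm").joinpath("data/defaults.yaml").read_text()
        _DEFAULTS = yaml.safe_load(text)
    return copy.deepcopy(_DEFAULTS)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | None = None) -> dict[str, Any]:
    """Load configuration, overlaying ``path`` (YAML) on the packaged defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    return cfg
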