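"""Hierarchical parameter configuration.

All model parameters live in one YAML document with sections
``physiology``, ``transport``, ``metabolism``, ``signaling``, ``genes``,
``protocol`` and ``solver``.  The shipped ``data/defaults.yaml`` is the
frozen calibrated default set; user files are deep-merged over it, so a
config file only needs the keys it overrides.
"""

from __future__ import annotations

import copy
import hashlib
import importlib.resources
import json
from typing import Any, Mapping

import yaml

__all__ = ["load_defaults", "load_config", "deep_merge", "config_hash"]


def deep_merge(base: dict, override: Mapping | None) -> dict:
    """Recursively merge ``override`` into a copy of ``base``; mappings merge
    key-wise, every other type replaces."""
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_defaults() -> dict:
    """The frozen calibrated default configuration."""
    text = (
        importlib.resources.files("musclesim") / "data" / "defaults.yaml"
    ).read_text()
    return yaml.safe_load(text)


def load_config(path=None, overrides: Mapping | None = None) -> dict:
    """Defaults, optionally overlaid with a YAML/JSON file and a dict."""
    cfg = load_defaults()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh)
        cfg = deep_merge(cfg, user or {})
    if overrides:
        cfg = deep_merge(cfg, overrides)
    return cfg


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Stable short hash identifying a configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
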