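"""Configuration loading.

A single YAML document governs every pipeline stage (echo-code accept list,
anchor keywords, section headings, pattern knobs, qualitative map,
classification thresholds).  :func:`load_config` returns the shipped defaults,
optionally deep-merged with a user override file.
"""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["default_config", "load_config", "config_hash"]


def default_config() -> dict:
    """The shipped default configuration as a fresh dict."""
    text = (resources.files("efparse") / "data" / "default_config.yaml").read_text(
        encoding="utf-8"
    )
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load configuration, deep-merging ``path`` (if given) over the defaults."""
    cfg = default_config()
    if path is not None:
        with Path(path).open(encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a YAML mapping")
        cfg = _deep_merge(cfg, user)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable sha256 over the canonical JSON form of a config dict."""
    canon = json.dumps(cfg, sort_keys=True, ensure_ascii=True)
    return hashlib.sha256(canon.encode()).hexdigest()
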