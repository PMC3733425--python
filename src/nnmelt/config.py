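"""Packaged configuration: default bindings and tunable thresholds."""

from __future__ import annotations

from pathlib import Path

import yaml

_DEFAULTS_PATH = Path(__file__).parent / "data" / "defaults.yaml"
_cache: dict | None = None


def defaults() -> dict:
    """The packaged defaults, loaded once."""
    global _cache
    if _cache is None:
        with open(_DEFAULTS_PATH) as fh:
            _cache = yaml.safe_load(fh)
    return _cache


def get(name: str, override=None):
    """One configuration value; a non-None override wins."""
    if override is not None:
        return override
    return defaults()[name]
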