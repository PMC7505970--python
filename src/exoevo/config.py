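"""Configuration loading.

A config file is a flat YAML mapping whose keys are exactly the
:class:`~exoevo.params.ParameterSet` field names (values at unit volume,
k = 1, as in the packaged default file).  The loaded set is rescaled to its
own ``k`` and validated; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .params import (ParameterSet, ParameterError, UNIT_VOLUME_DEFAULTS,
                     rescale_for_system_size, validate)

__all__ = ["load_config", "default_config_path", "apply_overrides"]

_FIELD_NAMES = {f.name for f in dataclasses.fields(ParameterSet)}
_INT_FIELDS = {"L"}


def default_config_path() -> Path:
    """Path of the packaged default configuration."""
    return Path(str(resources.files("exoevo") / "data" / "defaults.yaml"))


def _coerce(name: str, value):
    if value is None:
        return None
    if name in _INT_FIELDS:
        return int(value)
    return float(value)


def load_config(path: Optional[Union[str, Path]] = None,
                overrides: Optional[dict[str, object]] = None
                ) -> ParameterSet:
    """Load a parameter set from ``path`` (packaged defaults when None).

    Keys absent from the file fall back to the defaults; unknown keys raise
    ParameterError.  File values are interpreted at unit volume and rescaled
    to the file's ``k``; ``overrides`` (e.g. from ``--set name=value``) are
    applied to the unit-volume values before rescaling.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ParameterError([f"config {path}: expected a flat mapping"])
    if overrides:
        raw = {**raw, **overrides}
    unknown = sorted(set(raw) - _FIELD_NAMES)
    if unknown:
        raise ParameterError([f"unknown config key: {k}" for k in unknown])
    vals = dict(UNIT_VOLUME_DEFAULTS)
    for key, value in raw.items():
        vals[key] = _coerce(key, value)
    k_target = vals["k"] if "k" in raw else 10.0   # standard system size
    vals["k"] = 1.0
    base = ParameterSet(**vals)
    return validate(rescale_for_system_size(base, k_target))


def apply_overrides(pairs) -> dict[str, object]:
    """Parse ``name=value`` strings (CLI ``--set``) into an override dict."""
    out: dict[str, object] = {}
    for pair in pairs:
        if "=" not in pair:
            raise ParameterError([f"--set expects name=value, got {pair!r}"])
        name, value = pair.split("=", 1)
        name = name.strip()
        if name not in _FIELD_NAMES:
            raise ParameterError([f"unknown config key: {name}"])
        out[name] = _coerce(name, yaml.safe_load(value))
    return out
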