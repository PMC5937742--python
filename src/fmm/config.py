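"""Flat key-value run configuration shared by all pipeline stages.

The on-disk format is TOML restricted to scalar keys (a flat namespace).
Nested tables are flattened with dots, so ``[segmentation]\nsnr_threshold=3``
becomes ``segmentation.snr_threshold``; plain top-level keys are used as-is.
Every stage-level dataclass exposes ``from_mapping`` which picks out its own
keys (with or without a stage prefix) and ignores the rest.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path
from typing import Any, Mapping

from .errors import ConfigurationError

__all__ = ["load_config", "dump_config", "pick_fields"]


def _flatten(d: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, Mapping):
            out.update(_flatten(v, prefix=f"{key}."))
        else:
            out[key] = v
    return out


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a flat TOML config file into a flat ``{key: value}`` dict."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return _flatten(data)


def _toml_scalar(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def dump_config(cfg: Mapping[str, Any], path: str | Path) -> None:
    """Write a flat mapping back out as one-key-per-line TOML."""
    lines = []
    for k, v in cfg.items():
        if v is None:
            continue
        key = f'"{k}"' if "." in k else k
        lines.append(f"{key} = {_toml_scalar(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def pick_fields(cls: type, cfg: Mapping[str, Any], prefix: str = "") -> dict[str, Any]:
    """Extract constructor kwargs for dataclass ``cls`` from a flat mapping.

    A key matches either bare (``snr_threshold``) or prefixed
    (``segmentation.snr_threshold``); the prefixed form wins.
    """
    if not dataclasses.is_dataclass(cls):
        raise ConfigurationError(f"{cls!r} is not a dataclass")
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(cls):
        for key in (f"{prefix}{f.name}", f.name):
            if key in cfg:
                kwargs[f.name] = cfg[key]
                break
    return kwargs
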