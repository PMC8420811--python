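"""Configuration loading and tidy CSV / JSON output helpers."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

__all__ = ["load_config", "write_csv", "write_json"]


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a flat YAML config (keys mirror the CLI flags)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of option names to values")
    return cfg


def write_csv(frame: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy table: comma-delimited, '.' decimal, header row, no index."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def write_json(summary: Mapping[str, Any], path: str | Path) -> Path:
    """Write a machine-readable summary of headline numbers."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        try:
            return o.item()
        except AttributeError:
            return str(o)

    path.write_text(json.dumps(dict(summary), indent=2, default=_default) + "\n")
    return path
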