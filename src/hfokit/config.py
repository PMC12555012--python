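"""YAML configuration files for filter and detector settings.

YAML is the repo-wide config dialect.  A config file mirrors the dataclass
fields, e.g.::

    filter:
      band_low: 80
      band_high: 500
      powerline_hz: 60
      powerline_enabled: true
    detector:
      name: hilbert
      sd_thres: 5
      min_window: 0.010
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from hfokit.detect import DETECTORS
from hfokit.eeg_io import FilterSpec

__all__ = ["load_config", "save_config", "filter_spec_from", "detector_config_from"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def save_config(path: str | Path, filter_spec: FilterSpec | None = None,
                detector_name: str | None = None, detector_cfg=None) -> Path:
    doc: dict = {}
    if filter_spec is not None:
        doc["filter"] = dataclasses.asdict(filter_spec)
    if detector_cfg is not None:
        entry = dataclasses.asdict(detector_cfg)
        entry = {k: list(v) if isinstance(v, tuple) else v for k, v in entry.items()}
        entry["name"] = detector_name
        doc["detector"] = entry
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def filter_spec_from(config: dict) -> FilterSpec:
    section = config.get("filter", config)
    known = {f.name for f in dataclasses.fields(FilterSpec)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown filter config keys: {sorted(unknown)}")
    return FilterSpec(**section)


def detector_config_from(config: dict, name: str | None = None):
    """Build a detector config from the 'detector' section; returns (name, cfg)."""
    section = dict(config.get("detector", config))
    name = name or section.pop("name", None)
    if name not in DETECTORS:
        raise ValueError(f"detector name must be one of {sorted(DETECTORS)}, got {name!r}")
    cls = DETECTORS[name]
    known = {f.name for f in dataclasses.fields(cls)}
    section.pop("name", None)
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")
    if "filter_freq" in section:
        section["filter_freq"] = tuple(section["filter_freq"])
    return name, cls(**section)
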