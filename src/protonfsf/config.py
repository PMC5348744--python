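"""YAML configuration for beamline geometry and fit settings.

Example::

    geometry:
      vsad_x_mm: 2000
      vsad_y_mm: 2000       # or `parallel: true` instead of the VSADs
      spot_spacing_mm: 5
      plane_offsets_cm: [-20, -10, 0, 10, 20]   # *_cm keys accepted too
    fit:
      sigma1_bounds_mm: [0.5, 30]
      w2_grid_range: [0.0, 0.3]
      refine: true
"""

from __future__ import annotations

import math
from dataclasses import fields
from pathlib import Path

import yaml

from .fit import FitSettings
from .geometry import BeamGeometry


def _length_mm(block: dict, stem: str, default=None):
    """Read `<stem>_mm` or `<stem>_cm` (converted) from a config block."""
    if f"{stem}_mm" in block and f"{stem}_cm" in block:
        raise ValueError(f"give {stem} in mm or cm, not both")
    if f"{stem}_mm" in block:
        return block[f"{stem}_mm"]
    if f"{stem}_cm" in block:
        v = block[f"{stem}_cm"]
        return [10.0 * x for x in v] if isinstance(v, (list, tuple)) else 10.0 * v
    return default


def geometry_from_dict(block: dict) -> BeamGeometry:
    kwargs = {}
    if block.get("parallel", False):
        kwargs["vsad_x_mm"] = math.inf
        kwargs["vsad_y_mm"] = math.inf
    else:
        for axis in ("x", "y"):
            v = _length_mm(block, f"vsad_{axis}")
            if v is not None:
                kwargs[f"vsad_{axis}_mm"] = float(v)
    ss = _length_mm(block, "spot_spacing")
    if ss is not None:
        kwargs["spot_spacing_mm"] = float(ss)
    offsets = _length_mm(block, "plane_offsets")
    if offsets is not None:
        kwargs["plane_offsets_mm"] = tuple(float(z) for z in offsets)
    return BeamGeometry(**kwargs)


def fit_settings_from_dict(block: dict) -> FitSettings:
    valid = {f.name for f in fields(FitSettings)}
    unknown = set(block) - valid
    if unknown:
        raise ValueError(f"unknown fit settings: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in block.items()
    }
    return FitSettings(**kwargs)


def load_config(path: str | Path) -> tuple[BeamGeometry, FitSettings]:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    geom = geometry_from_dict(doc.get("geometry", {}))
    settings = fit_settings_from_dict(doc.get("fit", {}))
    return geom, settings
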