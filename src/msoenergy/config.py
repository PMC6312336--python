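"""YAML configuration for cell, stimulus and simulation settings.

A config file has up to three sections, with keys matching the
dataclass field names (units as in the dataclasses)::

    cell:
      soma_area: 1256.0
      dendrite_length: 150.0
      g_L: 0.86
      g_KLT_bar: 13.6
    stimulus:
      frequency: 500.0
      epsg_peak: 20.0
      seed: 1
    sim:
      duration_ms: 5000.0
      dt_ms: 0.01

Omitted keys take the default (experimentally constrained) values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .input_gen import StimulusSpec
from .model_core import CellSpec

__all__ = ["SimSettings", "load_config", "dump_config"]


@dataclass(frozen=True)
class SimSettings:
    duration_ms: float = 5000.0
    dt_ms: float = 0.01


def _build(cls, section: dict, rename: dict | None = None):
    rename = rename or {}
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in (section or {}).items():
        key = rename.get(key, key)
        if key not in names:
            raise KeyError(f"unknown {cls.__name__} key {key!r}")
        kwargs[key] = val
    return cls(**kwargs)


def load_config(path) -> tuple[CellSpec, StimulusSpec, SimSettings]:
    """Read a config file; missing sections fall back to defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cell = _build(CellSpec, raw.get("cell"))
    stim = _build(StimulusSpec, raw.get("stimulus"))
    sim = _build(SimSettings, raw.get("sim"))
    if "duration" not in (raw.get("stimulus") or {}):
        stim = dataclasses.replace(stim, duration=sim.duration_ms)
    return cell, stim, sim


def dump_config(path, cell: CellSpec, stim: StimulusSpec,
                sim: SimSettings = SimSettings()) -> None:
    obj = {"cell": dataclasses.asdict(cell),
           "stimulus": dataclasses.asdict(stim),
           "sim": dataclasses.asdict(sim)}
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
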