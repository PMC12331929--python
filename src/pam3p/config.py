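"""YAML configuration handling.

A config file holds up to five sections — ``optics``, ``chromophore``,
``transducer``, ``phantom`` and ``scan`` — plus top-level ``seed`` and
``noise`` entries. Missing sections fall back to the instrument defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .acoustics import TransducerModel
from .errors import InvalidArgumentError
from .optics import Chromophore, OpticsConfig
from .recon import ScanConfig

__all__ = ["Config", "load_config", "dump_config"]


@dataclass
class Config:
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    chromophore: Chromophore = field(default_factory=Chromophore)
    transducer: TransducerModel = field(default_factory=TransducerModel)
    scan: ScanConfig = field(default_factory=ScanConfig)
    phantom: dict = field(default_factory=lambda: {
        "kind": "gel_cylinder", "concentration_mm": 10.0,
        "diameter_mm": 3.0, "height_mm": 1.58, "pitch_um": 20.0})
    seed: int = 0
    fs_ghz: float = 2.0


_SECTIONS = {
    "optics": OpticsConfig,
    "chromophore": Chromophore,
    "scan": ScanConfig,
}


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise InvalidArgumentError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    # YAML lists -> tuples where the dataclass expects tuples
    for key in ("pixels", "passband_mhz"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path=None, overrides: dict | None = None) -> Config:
    """Load a YAML config file (all sections optional) with dict overrides."""
    raw: dict = {}
    if path is not None:
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
    if overrides:
        for k, v in overrides.items():
            if isinstance(v, dict):
                raw.setdefault(k, {}).update(v)
            else:
                raw[k] = v
    cfg = Config()
    for name, cls in _SECTIONS.items():
        if name in raw:
            setattr(cfg, name, _build(cls, raw[name]))
    if "transducer" in raw:
        tdata = dict(raw["transducer"])
        preset = tdata.pop("preset", None)
        if "passband_mhz" in tdata and isinstance(tdata["passband_mhz"], list):
            tdata["passband_mhz"] = tuple(tdata["passband_mhz"])
        if preset:
            cfg.transducer = TransducerModel.preset(preset, **tdata)
        else:
            cfg.transducer = _build(TransducerModel, tdata)
    if "phantom" in raw:
        cfg.phantom = {**cfg.phantom, **raw["phantom"]}
    cfg.seed = int(raw.get("seed", cfg.seed))
    cfg.fs_ghz = float(raw.get("fs_ghz", cfg.fs_ghz))
    return cfg


def dump_config(cfg: Config) -> str:
    """Resolved configuration as a YAML string (for --show-config)."""
    out = {
        "seed": cfg.seed,
        "fs_ghz": cfg.fs_ghz,
        "optics": dataclasses.asdict(cfg.optics),
        "chromophore": dataclasses.asdict(cfg.chromophore),
        "transducer": dataclasses.asdict(cfg.transducer),
        "scan": dataclasses.asdict(cfg.scan),
        "phantom": dict(cfg.phantom),
    }
    for section in ("transducer", "scan"):
        for k, v in out[section].items():
            if isinstance(v, tuple):
                out[section][k] = list(v)
    return yaml.safe_dump(out, sort_keys=False)
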