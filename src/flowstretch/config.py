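"""Run configuration: analysis constants, presets and geometries as YAML.

Zero-configuration defaults reproduce the standard analysis constants
(200 bp resolution floor, 3 s / 6-point minimum pause, threshold divisor 10);
everything is overridable from a human-editable YAML file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from .calibration import GEOMETRIES, SubstrateGeometry
from .errors import ValidationError
from .simulate import PRESETS, KineticPreset, RateModel


@dataclass
class RunConfig:
    resolution_floor_bp: float = 200.0
    min_pause_s: float = 3.0
    min_pause_samples: int = 6
    threshold_divisor: float = 10.0
    fft_display_cutoff_hz: float = 0.1
    acquisition_hz: float = 2.0
    master_seed: int = 0
    presets: dict = field(default_factory=lambda: dict(PRESETS))
    geometries: dict = field(default_factory=lambda: dict(GEOMETRIES))

    def preset(self, name: str) -> KineticPreset:
        try:
            return self.presets[name]
        except KeyError:
            raise ValidationError(
                f"unknown preset {name!r}; known: {sorted(self.presets)}"
            ) from None

    def geometry(self, name: str) -> SubstrateGeometry:
        try:
            return self.geometries[name]
        except KeyError:
            raise ValidationError(
                f"unknown geometry {name!r}; known: {sorted(self.geometries)}"
            ) from None


def _preset_from_dict(name: str, d: dict) -> KineticPreset:
    rm = d.pop("rate_model")
    if isinstance(rm, dict):
        rm = RateModel(**rm)
    return KineticPreset(name=name, rate_model=rm, **d)


def load_config(path=None) -> RunConfig:
    """Default configuration, optionally overridden from a YAML file."""
    cfg = RunConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    scalars = {
        k: v
        for k, v in raw.items()
        if k not in ("presets", "geometries") and hasattr(cfg, k)
    }
    cfg = replace(cfg, **scalars)
    for name, d in (raw.get("presets") or {}).items():
        cfg.presets[name] = _preset_from_dict(name, dict(d))
    for name, d in (raw.get("geometries") or {}).items():
        cfg.geometries[name] = SubstrateGeometry(name=name, **d)
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    """Write the full configuration (including presets) as editable YAML."""
    data = {
        k: getattr(cfg, k)
        for k in (
            "resolution_floor_bp",
            "min_pause_s",
            "min_pause_samples",
            "threshold_divisor",
            "fft_display_cutoff_hz",
            "acquisition_hz",
            "master_seed",
        )
    }
    data["presets"] = {}
    for name, p in cfg.presets.items():
        d = asdict(p)
        d.pop("name")
        data["presets"][name] = d
    data["geometries"] = {}
    for name, g in cfg.geometries.items():
        d = asdict(g)
        d.pop("name")
        data["geometries"][name] = d
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
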