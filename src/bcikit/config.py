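"""Run configuration: one YAML file with per-stage sections.

Recognized top-level keys are ``seed``, ``log_level``, ``out_dir`` and the
stage sections ``features``, ``spatial``, ``classify``, ``p300``, ``fsm``
and ``simulate``.  Unknown keys are rejected so typos fail loudly, and
every CLI run writes the resolved configuration next to its outputs for
reproducibility.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .mi_features import FeatureConfig

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    pass


_SECTIONS = {"features", "spatial", "classify", "p300", "fsm", "simulate"}
_SCALARS = {"seed", "log_level", "out_dir"}

_SPATIAL_DEFAULTS = {"car": True, "laplacian": "small", "weighted": False}
_CLASSIFY_DEFAULTS = {"algorithm": "LR", "train_fraction": 0.8}
_P300_DEFAULTS = {
    "window_ms": 667.0,
    "band": [0.1, 10.0],
    "order": 8,
    "ripple": 0.5,
    "repetitions": 15,
    "algorithm": "RF",
}


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "."
    features: FeatureConfig = field(default_factory=FeatureConfig)
    spatial: dict = field(default_factory=lambda: dict(_SPATIAL_DEFAULTS))
    classify: dict = field(default_factory=lambda: dict(_CLASSIFY_DEFAULTS))
    p300: dict = field(default_factory=lambda: dict(_P300_DEFAULTS))
    fsm: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)

    def resolved(self) -> dict:
        out = {
            "seed": self.seed,
            "log_level": self.log_level,
            "out_dir": self.out_dir,
            "features": asdict(self.features),
            "spatial": self.spatial,
            "classify": self.classify,
            "p300": self.p300,
            "fsm": self.fsm,
            "simulate": self.simulate,
        }
        return out

    def write_resolved(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.resolved(), fh, sort_keys=True)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig, rejecting unknown keys by name."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _SECTIONS - _SCALARS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig()
    for key in _SCALARS & set(raw):
        setattr(cfg, key, raw[key])
    if "features" in raw:
        feats = raw["features"] or {}
        known = set(FeatureConfig.__dataclass_fields__)
        bad = set(feats) - known
        if bad:
            raise ConfigError(f"unknown features keys: {sorted(bad)}")
        for k in ("mu_band", "beta_band"):
            if k in feats:
                feats[k] = tuple(feats[k])
        cfg.features = FeatureConfig(**feats)
    for section, defaults in (
        ("spatial", _SPATIAL_DEFAULTS),
        ("classify", _CLASSIFY_DEFAULTS),
        ("p300", _P300_DEFAULTS),
    ):
        if section in raw:
            given = raw[section] or {}
            bad = set(given) - set(defaults)
            if bad:
                raise ConfigError(f"unknown {section} keys: {sorted(bad)}")
            merged = dict(defaults)
            merged.update(given)
            setattr(cfg, section, merged)
    for section in ("fsm", "simulate"):
        if section in raw:
            setattr(cfg, section, raw[section] or {})
    return cfg
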