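"""Layered run configuration: documented defaults < YAML file < overrides.

The configuration tree mirrors the pipeline sections (model, loss, train,
augment, postprocess, synth, metrics) plus a global seed.  Unknown keys are
rejected with the nearest valid key named, and every artifact the CLI
writes embeds the configuration hash and seed that produced it.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional

import yaml

from .augment import AugmentConfig
from .losses import LossConfig
from .network import ModelConfig
from .postprocess import PostprocessOptions
from .training import TrainConfig
from .types import ConfigError


def _defaults() -> dict[str, dict[str, Any]]:
    return {
        "seed": 0,
        "model": ModelConfig().to_dict(),
        "loss": {"gamma": 1.0, "alpha": 1.0, "log_floor": 1e-7},
        "train": {"lr_init": 1e-3, "epochs": 50, "batch_size": 32,
                  "crop_margin_s": 2.0},
        "augment": {
            "delta_f_hz": 0.01, "mains_hz": 50.0, "n_blw_harmonics": 50,
            "n_pln_harmonics": 3, "gaussian_sd_mv": 0.01,
            "resize_log_range": [math.log(0.5), math.log(2.0)],
            "baseline_shift_sd_mv": 0.1, "powerline_amp_scale": 0.02,
            "baseline_wander_amp_scale": 0.05,
            "powerline_independent_phases": False,
            "p_baseline_wander": 0.5, "p_powerline": 0.5, "p_resize": 0.5,
            "p_gaussian": 0.5, "p_baseline_shift": 0.5,
        },
        "postprocess": {"min_wave_ms": 40.0, "include_edge_waves": False,
                        "suppression_threshold": 0.5},
        "synth": {"n_records": 50, "duration_s": 10.0, "fs": 500.0,
                  "class_mix": {"NSR": 0.25, "ST": 0.15, "BBB": 0.15,
                                "AVB1": 0.15, "AFIB": 0.15, "AFL": 0.1,
                                "VT": 0.05}},
        "metrics": {"tol_ms": 150.0, "mode": "full", "beat_window_ms": 400.0},
    }


def _merge(base: dict, update: Mapping, path: str = "") -> None:
    for key, value in update.items():
        full = f"{path}.{key}" if path else str(key)
        if key not in base:
            candidates = difflib.get_close_matches(str(key), [str(k) for k in base], n=1)
            hint = f"; did you mean {path + '.' if path else ''}{candidates[0]!r}?" if candidates else ""
            raise ConfigError(f"unknown config key {full!r}{hint}")
        if isinstance(base[key], dict) and not _is_leaf_dict(full):
            if not isinstance(value, Mapping):
                raise ConfigError(f"config section {full!r} must be a mapping")
            _merge(base[key], value, full)
        else:
            base[key] = value


def _is_leaf_dict(path: str) -> bool:
    # class_mix values are free-form rhythm -> proportion maps
    return path.endswith("class_mix")


@dataclass
class RunConfig:
    """A fully merged configuration tree."""

    tree: dict[str, Any] = field(default_factory=_defaults)

    def __getitem__(self, key: str) -> Any:
        return self.tree[key]

    def model_config(self) -> ModelConfig:
        return ModelConfig.from_dict(self.tree["model"])

    def loss_config(self) -> LossConfig:
        return LossConfig(**self.tree["loss"])

    def train_config(self) -> TrainConfig:
        t = dict(self.tree["train"])
        t["augment"] = self.augment_config()
        t["seed"] = self.tree["seed"]
        return TrainConfig(**t)

    def augment_config(self) -> AugmentConfig:
        a = dict(self.tree["augment"])
        a["resize_log_range"] = tuple(a["resize_log_range"])
        return AugmentConfig(**a)

    def postprocess_options(self) -> PostprocessOptions:
        return PostprocessOptions(**self.tree["postprocess"])

    @property
    def seed(self) -> int:
        return int(self.tree["seed"])

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.tree, sort_keys=True)

    def hash(self) -> str:
        canon = json.dumps(self.tree, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def provenance(self) -> dict[str, Any]:
        return {"config_hash": self.hash(), "seed": self.seed}


def _parse_override_value(raw: str) -> Any:
    return yaml.safe_load(raw)


def load_config(path: Optional[str] = None,
                overrides: Optional[Mapping[str, Any]] = None) -> RunConfig:
    """Build a RunConfig from defaults, an optional YAML file and overrides.

    Override keys are dotted paths (``augment.gaussian_sd_mv``); string
    values are parsed as YAML scalars.
    """
    tree = _defaults()
    if path is not None:
        with open(path) as fh:
            file_tree = yaml.safe_load(fh) or {}
        if not isinstance(file_tree, Mapping):
            raise ConfigError(f"config file {path} must hold a mapping")
        _merge(tree, file_tree)
    for dotted, value in (overrides or {}).items():
        parts = str(dotted).split(".")
        node: Any = {"": tree}
        update: dict[str, Any] = {}
        cursor = update
        for part in parts[:-1]:
            cursor[part] = {}
            cursor = cursor[part]
        cursor[parts[-1]] = _parse_override_value(value) if isinstance(value, str) else value
        _merge(tree, update)
    cfg = RunConfig(tree)
    # eager validation: constructing the typed configs checks invariants
    cfg.model_config()
    cfg.loss_config()
    cfg.augment_config()
    cfg.postprocess_options()
    return cfg
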