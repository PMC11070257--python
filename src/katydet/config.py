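"""Declarative pipeline configuration (YAML).

Every pipeline constant — class map (with merges, reject class, per-class
focal segment advance and centralization-penalty flags), augmentation
probabilities and parameter ranges, architecture and training schedule, and
the detection-threshold sweep — is a configurable default, not a hard-coded
literal. ``load_config`` deep-merges a user YAML over the defaults;
``class_map_from_config`` / ``architecture_from_config`` /
``schedule_from_config`` build the typed objects.
"""

from __future__ import annotations

import copy
from dataclasses import asdict

import yaml

from katydet.annotations import ClassMap
from katydet.augment import FOCAL_PARAMS, NONFOCAL_PARAMS
from katydet.network import ArchitectureConfig, TrainingSchedule

__all__ = [
    "default_config",
    "load_config",
    "save_config",
    "class_map_from_config",
    "architecture_from_config",
    "schedule_from_config",
]


def default_config() -> dict:
    """The built-in defaults (deployed configuration values)."""
    return {
        "classes": {
            "names": [],  # project-specific; see the example config
            "merges": {},
            "background_tag": "background",
            "reject_class": None,
            "penalty_classes": [],
            "focal_advance": {},
            "default_focal_advance": 0.2,
        },
        "signal": {
            "target_rate": 96_000,
            "highpass_cutoff_hz": 6_900.0,
            "highpass_order": 12,
            "segment_length_s": 0.8,
            "inference_advance_s": 0.2,
        },
        "augment": {
            "focal": copy.deepcopy(FOCAL_PARAMS),
            "non-focal": copy.deepcopy(NONFOCAL_PARAMS),
        },
        "architecture": asdict(ArchitectureConfig()),
        "schedule": asdict(TrainingSchedule()),
        "detection": {"threshold": 0.5, "sweep_step": 0.05},
    }


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None) -> dict:
    """Defaults, optionally overlaid with a user YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def class_map_from_config(cfg: dict) -> ClassMap:
    c = cfg["classes"]
    if not c["names"]:
        raise ValueError("config lists no class names")
    return ClassMap(
        class_names=list(c["names"]),
        merges=dict(c.get("merges") or {}),
        background_tag=c.get("background_tag", "background"),
        reject_class=c.get("reject_class"),
        penalty_classes=frozenset(c.get("penalty_classes") or []),
        focal_advance=dict(c.get("focal_advance") or {}),
        default_focal_advance=float(c.get("default_focal_advance", 0.2)),
    )


def architecture_from_config(cfg: dict) -> ArchitectureConfig:
    a = dict(cfg["architecture"])
    a["input_shape"] = tuple(a["input_shape"])
    return ArchitectureConfig(**a)


def schedule_from_config(cfg: dict, seed: int | None = None) -> TrainingSchedule:
    s = dict(cfg["schedule"])
    s["lr_drop_epochs"] = tuple(s["lr_drop_epochs"])
    if seed is not None:
        s["seed"] = seed
    return TrainingSchedule(**s)
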