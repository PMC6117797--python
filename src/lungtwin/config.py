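"""Flat key-value configuration files for the twin.

One file configures geometry, breathing, motor and camera with flat keys
(YAML syntax, no nesting), e.g.::

    r_mm: 20
    d1_mm: 5
    d2_mm: 20
    l_mm: 20
    period_s: 3.75        # or: bpm: 16
    full_step_deg: 1.8
    microstep_divisor: 32
    px_per_mm: 8
    fps: 30

Unknown keys are rejected so typos surface immediately.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .breathing import BreathingSpec, GeometryConfig, period_from_bpm
from .mechanism import MotorSpec
from .tracking import CameraConfig

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "geometry_from_config",
    "breathing_from_config",
    "motor_from_config",
    "camera_from_config",
]

DEFAULT_CONFIG: dict = {
    "r_mm": 20.0,
    "d1_mm": 5.0,
    "d2_mm": 20.0,
    "l_mm": 20.0,
    "mirror": False,
    "period_s": 3.75,
    "full_step_deg": 1.8,
    "microstep_divisor": 32,
    "width_px": 640,
    "height_px": 480,
    "px_per_mm": 8.0,
    "fps": 30.0,
    "sticker_radius_mm": 2.5,
    "noise_sigma": 3.0,
}

_KNOWN_KEYS = set(DEFAULT_CONFIG) | {"bpm", "seed"}


def load_config(path=None) -> dict:
    """Read a flat key-value config file, filling defaults for absent keys."""
    cfg = dict(DEFAULT_CONFIG)
    if path is None:
        return cfg
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain flat key: value pairs")
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "bpm" in data and "period_s" in data:
        raise ValueError("give either period_s or bpm, not both")
    if "bpm" in data:
        data["period_s"] = period_from_bpm(data.pop("bpm"))
    cfg.update(data)
    return cfg


def geometry_from_config(cfg: dict) -> GeometryConfig:
    return GeometryConfig(
        r=cfg["r_mm"], d1=cfg["d1_mm"], d2=cfg["d2_mm"], l=cfg["l_mm"],
        mirror=bool(cfg.get("mirror", False)),
    )


def breathing_from_config(cfg: dict) -> BreathingSpec:
    return BreathingSpec(period_s=cfg["period_s"])


def motor_from_config(cfg: dict) -> MotorSpec:
    return MotorSpec(
        full_step_deg=cfg["full_step_deg"],
        microstep_divisor=int(cfg["microstep_divisor"]),
    )


def camera_from_config(cfg: dict, seed: int = 0) -> CameraConfig:
    return CameraConfig(
        width_px=int(cfg["width_px"]), height_px=int(cfg["height_px"]),
        px_per_mm=cfg["px_per_mm"], fps=cfg["fps"],
        sticker_radius_mm=cfg["sticker_radius_mm"],
        noise_sigma=cfg["noise_sigma"], seed=seed,
    )
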