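"""Run configuration: defaults, validation, and YAML round-tripping.

A :class:`RunConfig` gathers every tunable of the pipeline with defaults
equal to the study conditions (25 Hz stroke, 10 rad/s rotation, beta = 0.2,
lambda = 0.9, m = 3, k = 10, 15 ms refractory, 90/10 split, ...).  Configs
round-trip losslessly through YAML; unknown keys and out-of-range values are
rejected with the offending field named.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .selection import SSPOCParams
from .wing import Axis, FlappingKinematics, RotationCondition, SensorGrid, WingParams
from .encoding import EncoderParams

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    wing: WingParams = field(default_factory=WingParams)
    kinematics: FlappingKinematics = field(default_factory=FlappingKinematics)
    rotation: RotationCondition = field(default_factory=RotationCondition)
    encoder: EncoderParams = field(default_factory=EncoderParams)
    sspoc: SSPOCParams = field(default_factory=SSPOCParams)
    grid: SensorGrid = field(default_factory=SensorGrid)
    duration: float = 3.0
    n_spike_repeats: int = 10
    train_frac: float = 0.9
    n_replicates: int = 20
    direction: str = "spanwise"
    seed: int = 0
    output_dir: str = "results"
    allow_beta_outside_sweep: bool = False

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration: must be positive")
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac: must lie in (0, 1)")
        if self.n_spike_repeats < 1:
            raise ValueError("n_spike_repeats: must be at least 1")
        if self.direction not in ("spanwise", "chordwise"):
            raise ValueError("direction: must be 'spanwise' or 'chordwise'")
        if not self.allow_beta_outside_sweep and not \
                0.05 - 1e-12 <= self.encoder.beta <= 0.7 + 1e-12:
            raise ValueError(
                "encoder.beta: outside the studied range [0.05, 0.7] "
                "(set allow_beta_outside_sweep to override)")


_SECTIONS = {
    "wing": WingParams,
    "kinematics": FlappingKinematics,
    "rotation": RotationCondition,
    "encoder": EncoderParams,
    "sspoc": SSPOCParams,
    "grid": SensorGrid,
}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, Axis):
        return obj.value
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_config(cfg: RunConfig, path) -> None:
    """Write the config as YAML (scalars and nested sections only)."""
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))


def _build_section(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{section}: unknown key(s) {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{section}: {err}") from err


def load_config(path) -> RunConfig:
    """Load and validate a YAML config; missing keys take the defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    scalar_names = {f.name for f in dataclasses.fields(RunConfig)
                    if f.name not in _SECTIONS}
    unknown = set(raw) - set(_SECTIONS) - scalar_names
    if unknown:
        raise ValueError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build_section(cls, raw[name] or {}, name)
    for name in scalar_names:
        if name in raw:
            kwargs[name] = raw[name]
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as err:
        raise ValueError(str(err)) from err
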