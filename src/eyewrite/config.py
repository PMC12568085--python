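"""YAML run-configuration loading.

A run config is a YAML file with optional blocks ``preprocess``,
``augment``, ``model``, ``train`` and ``generate``; every key defaults to
the package's standard recipe so an empty file is a valid config.

Example::

    preprocess:
      target_length: 64
      initial_point: true
      filters:
        enabled: false
    train:
      epochs: 50
      batch_size: 64
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augmentation import DistortionConfig, WarpConfig
from .filtering import FilterConfig
from .nn import CNNBranchConfig, ModelConfig, TCNBranchConfig
from .normalization import NormalizationConfig
from .synthetic import GeneratorConfig
from .training import AugmentationConfig, TrainConfig

__all__ = ["RunConfig", "load_run_config"]


@dataclass
class RunConfig:
    """All pipeline settings for one run."""

    filters: FilterConfig = field(default_factory=FilterConfig.disabled)
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    generate: GeneratorConfig = field(default_factory=GeneratorConfig)


def _filters(d: dict) -> FilterConfig:
    enabled = d.pop("enabled", None)
    flags = {}
    if enabled is not None:
        flags = {"median_enabled": enabled, "lowpass_enabled": enabled,
                 "dc_block_enabled": enabled}
    return FilterConfig(**{**flags, **d})


def _normalization(d: dict) -> NormalizationConfig:
    mapping = {"target_length": "target_length",
               "amplitude_mode": "amplitude_mode",
               "baseline_pad_length": "baseline_pad_length",
               "initial_point": "apply_initial_point",
               "truncation_convention": "truncation_convention"}
    return NormalizationConfig(**{mapping[k]: v for k, v in d.items()})


def _augmentation(d: dict) -> AugmentationConfig:
    kwargs: dict = {"seed": d.get("seed", 0), "enabled": d.get("enabled", True)}
    if "distortion1" in d:
        kwargs["distortion1"] = DistortionConfig(**d["distortion1"])
    if "distortion2" in d:
        kwargs["distortion2"] = DistortionConfig(**d["distortion2"])
    if "window_warp" in d:
        w = d["window_warp"]
        kwargs["warp"] = WarpConfig(
            window_ratio=w.get("ratio", 0.3),
            scale_choices=tuple(w.get("scales", (0.25, 4.0))))
    return AugmentationConfig(**kwargs)


def _model(d: dict) -> ModelConfig:
    kwargs = dict(d)
    if "cnn" in kwargs:
        c = dict(kwargs["cnn"])
        if "channels" in c:
            c["channels"] = tuple(c["channels"])
        kwargs["cnn"] = CNNBranchConfig(**c)
    if "tcn" in kwargs:
        t = dict(kwargs["tcn"])
        if "dilations" in t:
            t["dilations"] = tuple(t["dilations"])
        kwargs["tcn"] = TCNBranchConfig(**t)
    return ModelConfig(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config, filling defaults for missing keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    pre = dict(raw.get("preprocess", {}))
    filt = _filters(dict(pre.pop("filters", {}) or {}))
    cfg = RunConfig(
        filters=filt,
        normalization=_normalization(pre),
        augmentation=_augmentation(dict(raw.get("augment", {}) or {})),
        model=_model(dict(raw.get("model", {}) or {})),
        train=TrainConfig(**(raw.get("train", {}) or {})),
        generate=GeneratorConfig(
            **{k: tuple(v) if k == "duration_range_s" else v
               for k, v in (raw.get("generate", {}) or {}).items()}),
    )
    return cfg
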