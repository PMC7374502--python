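"""Structured run configuration: one YAML file drives every pipeline stage.

Unknown keys are rejected (typos must not silently fall back to defaults)
and the full effective configuration is echoed into run logs and manifests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from typing import Any

import yaml

from .losses import DiscriminativeConfig
from .postprocess import ClusteringConfig
from .synthetic import SceneConfig

__all__ = ["LabelConfig", "TrainSection", "NetworkSection", "PostprocessConfig", "RunConfig"]


@dataclass(frozen=True)
class LabelConfig:
    core_scale: float = 0.5  # axis scale of the inner-core class
    head_fraction: float = 0.4  # major-axis share of the head cap


@dataclass(frozen=True)
class NetworkSection:
    stages: int = 4
    base_width: int = 16
    embedding_dim: int = 8
    coord_features: bool = True


@dataclass(frozen=True)
class TrainSection:
    learning_rate: float = 1e-5
    epochs: int = 10
    batch_size: int = 4
    seed: int = 0
    augment: bool = True
    cosine_decay: bool = True


@dataclass(frozen=True)
class PostprocessConfig:
    tau: float = 0.5  # foreground probability threshold
    min_pixels: int = 20  # smallest blob/cluster an ellipse is fitted to
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)


@dataclass(frozen=True)
class RunConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    labels: LabelConfig = field(default_factory=LabelConfig)
    loss: DiscriminativeConfig = field(default_factory=DiscriminativeConfig)
    network: NetworkSection = field(default_factory=NetworkSection)
    train: TrainSection = field(default_factory=TrainSection)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "RunConfig":
        """The small-everything setup used for CPU-scale experiments.

        128x128 scenes, a 4-stage / 8-channel backbone, flip/rotation/
        grayscale augmentation, and a learning rate suited to training this
        small network from scratch (the 1e-5 default fits fine-tuning a
        large pretrained backbone, not a fresh ~50k-parameter model).
        """
        return cls(
            scene=SceneConfig(seed=seed),
            network=NetworkSection(stages=4, base_width=8),
            train=TrainSection(
                learning_rate=3e-3, epochs=50, batch_size=2, seed=seed, augment=True
            ),
        )

    def as_dict(self) -> dict[str, Any]:
        return asdict(self)


_SECTION_TYPES = {
    "scene": SceneConfig,
    "labels": LabelConfig,
    "loss": DiscriminativeConfig,
    "network": NetworkSection,
    "train": TrainSection,
    "postprocess": PostprocessConfig,
}


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path!r} must be a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) under {path!r}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key == "clustering":
            value = _build(ClusteringConfig, value, f"{path}.{key}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_run_config(path) -> RunConfig:
    """Load a RunConfig from YAML, rejecting unknown keys at any level."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping of sections")
    unknown = set(data) - set(_SECTION_TYPES)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    sections = {
        name: _build(cls, data[name], name) for name, cls in _SECTION_TYPES.items() if name in data
    }
    return replace(RunConfig(), **sections)
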