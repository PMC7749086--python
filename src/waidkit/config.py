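"""Configuration objects and YAML loading.

Defaults follow the operating point used throughout the package: 256
histogram bins, linear histogram kernel, 50x50 patches, 25 patches per
bag, 15 random-noise negative bags, eta = 0.9, and an RBF kernel with
gamma = 0.00025 for the final classifiers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "DescriptorConfig",
    "MILConfig",
    "EvalConfig",
    "ExperimentConfig",
    "load_config",
    "config_hash",
]


@dataclass(frozen=True)
class DescriptorConfig:
    """Settings for CKD construction."""

    bins: int = 256
    eps_scale: float = 1e-6
    kernel: str = "linear"
    kernel_params: dict | None = None
    gradient_operator: str = "sobel"


@dataclass(frozen=True)
class MILConfig:
    """Settings for bag construction and the eta-constrained SVM."""

    patch_size: int = 50          # n: side of sampled square patches (px)
    patches_per_bag: int = 25     # m: instances per bag
    n_neg_bags: int = 15
    neg_strategy: str = "noise"   # noise | texture | healthy
    eta: float = 0.9              # required fraction of positives in the bag
    C0: float = 0.01
    growth: float = 2.0
    C_max: float = 1e6
    order: int = 1                # feature-map approximation order r
    period: float = 0.6           # spectral sampling period of the JS map


@dataclass(frozen=True)
class EvalConfig:
    """Settings for classifier evaluation."""

    measure: str = "lerm"         # lerm | jbld (patch-level kernels)
    gamma: float = 2.5e-4         # RBF bandwidth
    svm_C: float = 100.0
    patch_folds: int = 10
    image_folds: int = 5


@dataclass(frozen=True)
class ExperimentConfig:
    """Full synthetic experiment: generation + descriptors + MIL + eval."""

    n_images_per_class: int = 20
    image_size: int = 150
    seed: int = 0
    descriptors: DescriptorConfig = field(default_factory=DescriptorConfig)
    mil: MILConfig = field(default_factory=MILConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)


def _dataclass_from(cls, data: dict):
    fields = {f for f in cls.__dataclass_fields__}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML file.

    Recognized top-level keys: ``n_images_per_class``, ``image_size``,
    ``seed`` and the nested sections ``descriptors``, ``mil``, ``eval``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sections = {}
    for key, cls in (("descriptors", DescriptorConfig), ("mil", MILConfig),
                     ("eval", EvalConfig)):
        sections[key] = _dataclass_from(cls, raw.pop(key, {}) or {})
    return _dataclass_from(ExperimentConfig, raw | sections)


def config_hash(config) -> str:
    """Short stable hash of a config dataclass, for manifests/reports."""
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
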