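"""Pipeline configuration: feature, model, training and evaluation knobs.

A single dataclass carries every tunable of the segmentation pipeline and
round-trips through YAML; unknown keys in a config file are rejected so
typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .crf import WeightVector
from .features import DEFAULT_SCALES
from .training import TrainingConfig

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline settings with their defaults.

    Feature settings control the filter bank; ``normalize_lstar`` toggles
    exposure compensation.  CRF training settings mirror TrainingConfig.
    ``positive_index`` is the label-set index treated as "lesion" in
    metrics and masks.
    """

    scales: tuple = DEFAULT_SCALES
    normalize_lstar: bool = True
    log_scale_normalized: bool = False
    padding_mode: str = "reflect"

    w0_node: float = 1.0
    w0_edge: float = 0.1
    sigma2: float = 10.0
    gamma: float = 1e-3
    epsilon: float = 1e-4
    n_itr: int = 200
    gradient: str = "spa"

    k_folds: int = 10
    cv_seed: int = 0
    n_thresholds: int = 256
    positive_index: int = 1

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(
            w0=WeightVector(np.array([self.w0_node, self.w0_edge]), (1,)),
            sigma2=self.sigma2,
            gamma=self.gamma,
            epsilon=self.epsilon,
            n_itr=self.n_itr,
            gradient=self.gradient,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "scales" in d:
            d["scales"] = tuple(d["scales"])
        if "sigma2" in d and d["sigma2"] in ("inf", ".inf", None):
            d["sigma2"] = math.inf
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scales"] = list(self.scales)
        if math.isinf(self.sigma2):
            d["sigma2"] = "inf"
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
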