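"""Configuration records for the network, its head, the auxiliary branch
and a full training run, with YAML round-tripping.

`default_*` constructors mirror the published architecture scale
(cardinality-32 backbone with a ResNeXt-50-style stage layout);
`miniature_*` constructors give the small footprint used by the test
suite and the scaled-down experiments (cardinality 4, two stages,
64×64 inputs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigurationError


@dataclass
class AResNetConfig:
    """Backbone hyperparameters.

    ``cardinality`` is the number of parallel residual branches per
    block; every branch also carries a deepwise optimization path
    (avg-pool + conv + BN + ReLU) whose depth is ``optimization_depth``.
    The stem downsamples by 4; ``stage_strides`` multiply onto that.
    """

    input_channels: int = 1
    stem_channels: int = 64
    cardinality: int = 32
    branch_width: int = 4
    optimization_depth: int = 1
    pool_size: int = 3
    stage_channels: tuple = (256, 512, 1024, 2048)
    block_counts: tuple = (3, 4, 6, 3)
    stage_strides: tuple = (1, 2, 2, 1)
    norm: str = "bn"

    def __post_init__(self):
        if self.cardinality < 1:
            raise ConfigurationError("cardinality must be >= 1")
        if self.optimization_depth < 1:
            raise ConfigurationError("optimization_depth must be >= 1")
        if self.pool_size % 2 != 1 or self.pool_size < 1:
            raise ConfigurationError(
                "pool_size must be odd so the pooling path preserves shape"
            )
        if not (
            len(self.stage_channels) == len(self.block_counts) == len(self.stage_strides)
        ):
            raise ConfigurationError("stage lists must have equal length")

    @property
    def total_stride(self) -> int:
        s = 4
        for st in self.stage_strides:
            s *= st
        return s

    @property
    def low_level_stride(self) -> int:
        return 4  # the stem output feeds the decoder skip and BINet

    @property
    def low_level_channels(self) -> int:
        return self.stem_channels

    @property
    def high_level_channels(self) -> int:
        return self.stage_channels[-1]


@dataclass
class DASPPConfig:
    """Decode-head hyperparameters (DASPP pyramid + BICECA attention)."""

    atrous_rates: tuple = (1, 6, 12, 18)
    branch_channels: int = 256
    include_image_pool: bool = True
    lcci_kernel_size: int = 3
    lcci_adaptive: bool = False
    attention_transform: str = "identity"  # or "affine"
    low_level_proj_channels: int = 48
    refine_channels: int = 256
    n_classes: int = 2

    def __post_init__(self):
        rates = tuple(self.atrous_rates)
        if not rates or any(r < 1 for r in rates):
            raise ConfigurationError("atrous_rates must be nonempty positive ints")
        if list(rates) != sorted(set(rates)):
            raise ConfigurationError("atrous_rates must be strictly increasing")
        if self.lcci_kernel_size % 2 != 1 or self.lcci_kernel_size < 1:
            raise ConfigurationError("lcci_kernel_size must be odd and positive")


@dataclass
class BINetConfig:
    """Auxiliary-branch hyperparameters (reflect conv stack + bilinear
    upsampling); ``aux_weight`` is the λ of the joint loss."""

    enabled: bool = True
    n_layers: int = 2
    kernel_size: int = 3
    aux_weight: float = 0.4
    apply_avg: bool = True

    def __post_init__(self):
        if self.aux_weight < 0:
            raise ConfigurationError("aux_weight must be nonnegative")
        if self.kernel_size % 2 != 1:
            raise ConfigurationError("kernel_size must be odd")
        if self.n_layers < 1:
            raise ConfigurationError("n_layers must be >= 1")


@dataclass
class OptimizerConfig:
    name: str = "adam"
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    cosine_decay: bool = True


@dataclass
class RunConfig:
    """Complete, serializable description of one training run."""

    backbone: AResNetConfig = field(default_factory=AResNetConfig)
    head: DASPPConfig = field(default_factory=DASPPConfig)
    binet: BINetConfig = field(default_factory=BINetConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    batch_size: int = 8
    epochs: int = 30
    seed: int = 0
    n_classes: int = 2
    normalize: str = "minmax"
    augment: bool = False
    class_weighting: bool = False
    device: str = "cpu"

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("backbone", "head"):
            for k, v in d[key].items():
                if isinstance(v, tuple):
                    d[key][k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {
            "backbone": AResNetConfig,
            "head": DASPPConfig,
            "binet": BINetConfig,
            "optimizer": OptimizerConfig,
        }
        kwargs = {}
        for key, klass in sub.items():
            if key in d:
                val = d.pop(key)
                if isinstance(val, dict):
                    val = {
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in val.items()
                    }
                    val = klass(**val)
                kwargs[key] = val
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def miniature_backbone() -> AResNetConfig:
    """Two-stage cardinality-4 backbone for 64×64 inputs (output stride 8)."""
    return AResNetConfig(
        input_channels=1,
        stem_channels=8,
        cardinality=4,
        branch_width=2,
        stage_channels=(16, 16),
        block_counts=(1, 1),
        stage_strides=(1, 2),
    )


def miniature_head() -> DASPPConfig:
    return DASPPConfig(
        atrous_rates=(1, 2, 4),
        branch_channels=16,
        lcci_kernel_size=3,
        low_level_proj_channels=8,
        refine_channels=16,
    )


def miniature_run_config(**overrides) -> RunConfig:
    cfg = RunConfig(
        backbone=miniature_backbone(),
        head=miniature_head(),
        binet=BINetConfig(),
        batch_size=8,
        epochs=30,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg
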