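"""AResNet — the multi-path parallel residual backbone.

Every block holds C (the cardinality) parallel residual branches.  A
branch contributes two terms: the grouped-convolution feature-extraction
result G_i(x) and a deepwise residual optimization term H_i(x) computed
from the same block input, where H_i is an average-pooling path and a
convolution path summed, then batch-normalized and rectified.  The block
output is the plain sum

    Y(x) = Σ_{i=1..C} (G_i(x) + H_i(x)) + x,

with the identity skip replaced by a 1×1 projection when the block
changes channel count or stride.  No activation follows the sum, so a
block whose branch parameters are all zero is exactly the identity map.

For speed the C branches are evaluated as grouped convolutions; the
grouping is mathematically identical to looping over branches and
summing (the tests assert this against an explicit branch loop).
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .config import AResNetConfig
from .exceptions import ConfigurationError, ShapeError
from .nn import Conv2d, Identity, Module, ReLU, Sequential, make_norm

__all__ = [
    "DeepwiseOptimizationBranches",
    "ParallelResidualBranches",
    "AResNetBlock",
    "AResNetBackbone",
]


class DeepwiseOptimizationBranches(Module):
    """The C deepwise residual optimization paths H_i of one block.

    Each path stacks ``depth`` units of (convolution + average-pooling)
    on the same input, sums the two per unit, then applies the norm and
    ReLU once at the end; all C paths are evaluated jointly on a
    C-times-wider channel axis and summed afterwards.
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int,
                 cardinality: int, depth: int = 1, pool_size: int = 3,
                 norm: str = "bn", rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cardinality = cardinality
        self.out_channels = out_channels
        self.depth = depth
        self.pool_size = pool_size
        wide = cardinality * out_channels
        for d in range(depth):
            cin = in_channels if d == 0 else wide
            s = stride if d == 0 else 1
            conv = Conv2d(cin, wide, 3, stride=s, rng=rng,
                          groups=1 if d == 0 else cardinality)
            self.add_module(f"conv{d}", conv)
            # pooling path: identity channels when they already match,
            # else a 1×1 projection so the two paths can be summed
            if d == 0 and (in_channels != out_channels or stride != 1):
                self.add_module(
                    f"pool_proj{d}",
                    Conv2d(in_channels, wide, 1, stride=s, bias=False, rng=rng),
                )
            elif d == 0:
                self.add_module(f"pool_proj{d}", Identity())
            else:
                self.add_module(f"pool_proj{d}", Identity())
        self.norm = make_norm(norm, wide)

    def _pool_path(self, z: Tensor, d: int) -> Tensor:
        pooled = ag.avg_pool2d(z, self.pool_size)
        proj = self._modules[f"pool_proj{d}"]
        if isinstance(proj, Identity):
            if d == 0:
                # same pooled map feeds every branch
                pooled = ag.concat([pooled] * self.cardinality, axis=1)
            return pooled
        return proj(pooled)

    def forward(self, x: Tensor) -> Tensor:
        z = x
        for d in range(self.depth):
            conv_out = self._modules[f"conv{d}"](z)
            z = ag.add(conv_out, self._pool_path(z if d > 0 else x, d))
        z = ag.relu(self.norm(z))
        n, _, h, w = z.data.shape
        z = ag.reshape(z, (n, self.cardinality, self.out_channels, h, w))
        return ag.tensor_sum(z, axis=1)


class ParallelResidualBranches(Module):
    """The C grouped-convolution branches G_i of one block
    (1×1 reduce → 3×3 grouped spatial → 1×1 expand), summed.

    The final 1×1 expansion carries no norm, so the block output stays a
    plain sum over branch outputs.
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int,
                 cardinality: int, branch_width: int, norm: str = "bn",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        wide = cardinality * branch_width
        self.reduce = Conv2d(in_channels, wide, 1, bias=False, rng=rng)
        self.norm1 = make_norm(norm, wide)
        self.spatial = Conv2d(wide, wide, 3, stride=stride, groups=cardinality,
                              bias=False, rng=rng)
        self.norm2 = make_norm(norm, wide)
        self.expand = Conv2d(wide, out_channels, 1, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        z = ag.relu(self.norm1(self.reduce(x)))
        z = ag.relu(self.norm2(self.spatial(z)))
        return self.expand(z)


class AResNetBlock(Module):
    """One deepwise parallel residual optimization block."""

    def __init__(self, in_channels: int, out_channels: int, stride: int,
                 config: AResNetConfig, rng: np.random.Generator | None = None):
        super().__init__()
        if config.cardinality < 1:
            raise ConfigurationError("cardinality must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.g_branches = ParallelResidualBranches(
            in_channels, out_channels, stride, config.cardinality,
            config.branch_width, config.norm, rng,
        )
        self.h_branches = DeepwiseOptimizationBranches(
            in_channels, out_channels, stride, config.cardinality,
            config.optimization_depth, config.pool_size, config.norm, rng,
        )
        if in_channels != out_channels or stride != 1:
            self.skip = Conv2d(in_channels, out_channels, 1, stride=stride,
                               bias=False, rng=rng)
        else:
            self.skip = Identity()

    def forward(self, x: Tensor) -> Tensor:
        return ag.add(ag.add(self.g_branches(x), self.h_branches(x)), self.skip(x))


class AResNetBackbone(Module):
    """Stem (stride 4) plus the configured block stages.

    ``forward`` returns the stem feature map (the stride-4 skip consumed
    by the decoder and the auxiliary branch) and the final-stage map.
    """

    def __init__(self, config: AResNetConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        c0 = config.stem_channels
        self.stem = Sequential(
            Conv2d(config.input_channels, c0, 3, stride=2, rng=rng),
            make_norm(config.norm, c0), ReLU(),
            Conv2d(c0, c0, 3, stride=2, rng=rng),
            make_norm(config.norm, c0), ReLU(),
        )
        in_ch = c0
        blocks = []
        for stage, (ch, n_blocks, stride) in enumerate(
            zip(config.stage_channels, config.block_counts, config.stage_strides)
        ):
            for b in range(n_blocks):
                blocks.append(
                    AResNetBlock(in_ch, ch, stride if b == 0 else 1, config, rng)
                )
                in_ch = ch
        self.blocks = Sequential(*blocks)

    def forward(self, image: Tensor) -> tuple[Tensor, Tensor]:
        _, _, h, w = image.data.shape
        stride = self.config.total_stride
        if h % stride or w % stride:
            pad_h = (stride - h % stride) % stride
            pad_w = (stride - w % stride) % stride
            raise ShapeError(
                f"input {h}×{w} not divisible by total stride {stride}; "
                f"pad to {h + pad_h}×{w + pad_w}"
            )
        low = self.stem(image)
        high = self.blocks(low)
        return low, high
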