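"""DASPP-BICECA decode head.

DASPP runs parallel atrous depthwise-separable branches at several
dilation rates (plus an optional global-pool branch), concatenates them
and fuses with a 1×1 projection.  BICECA gates the fused channels with
efficient channel attention: a global average descriptor is passed
through a circular 1D convolution over the channel axis (local
cross-channel interaction, LCCI), squashed to (0,1) by a sigmoid, and
broadcast-multiplied back onto the features, with a residual add and
ReLU.  Bicubic interpolation carries the result back to the skip and
input resolutions.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .config import DASPPConfig
from .core_ops import bicubic_resize_to
from .exceptions import ConfigurationError
from .nn import BatchNorm2d, Conv2d, Module, ReLU, Sequential, make_norm, parameter

__all__ = ["DASPP", "BICECA", "DecodeHead", "adaptive_lcci_kernel_size"]


def adaptive_lcci_kernel_size(channels: int) -> int:
    """Nearest odd integer to |log2(C)/2 + 1/2| (the ECA convention)."""
    k = int(abs(np.log2(channels) / 2 + 0.5))
    return max(k if k % 2 == 1 else k + 1, 1)


class DASPPBranch(Module):
    """One pyramid branch: atrous depthwise 3×3 then pointwise 1×1."""

    def __init__(self, in_channels: int, out_channels: int, rate: int,
                 norm: str = "bn", rng=None):
        super().__init__()
        self.depthwise = Conv2d(in_channels, in_channels, 3, dilation=rate,
                                groups=in_channels, bias=False, rng=rng)
        self.pointwise = Conv2d(in_channels, out_channels, 1, bias=False, rng=rng)
        self.norm = make_norm(norm, out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(self.norm(self.pointwise(self.depthwise(x))))


class DASPP(Module):
    """Depthwise atrous spatial pyramid pooling."""

    def __init__(self, in_channels: int, config: DASPPConfig, norm: str = "bn",
                 rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.rates = tuple(config.atrous_rates)
        out = config.branch_channels
        for r in self.rates:
            self.add_module(f"branch_r{r}",
                            DASPPBranch(in_channels, out, r, norm, rng))
        self.include_image_pool = config.include_image_pool
        if self.include_image_pool:
            self.pool_proj = Conv2d(in_channels, out, 1, rng=rng)
        n_branches = len(self.rates) + int(self.include_image_pool)
        self.fuse = Conv2d(n_branches * out, out, 1, bias=False, rng=rng)
        self.fuse_norm = make_norm(norm, out)

    def forward(self, x: Tensor) -> Tensor:
        outs = [self._modules[f"branch_r{r}"](x) for r in self.rates]
        if self.include_image_pool:
            pooled = ag.relu(self.pool_proj(ag.global_avg_pool(x)))
            ones = Tensor(np.ones((1, 1) + x.data.shape[2:]))
            outs.append(ag.mul(pooled, ones))
        z = ag.concat(outs, axis=1)
        return ag.relu(self.fuse_norm(self.fuse(z)))


class BICECA(Module):
    """Bicubic efficient channel attention block.

    With s = DSConv(Q) computed once and shared:
      descriptor  q_avg = transform(ReLU(GAP(s)))          (one value/channel)
      gates       φ = sigmoid(LCCI(q_avg))                 (strictly in (0,1))
      attended    η = φ ⊗ s                                 (broadcast multiply)
      output      ReLU(η ⊕ s)                               (residual add)
    """

    def __init__(self, channels: int, kernel_size: int = 3,
                 transform: str = "identity", norm: str = "bn", rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if channels < kernel_size:
            raise ConfigurationError(
                f"channel count {channels} must be >= LCCI kernel {kernel_size}"
            )
        self.dsconv_depthwise = Conv2d(channels, channels, 3, groups=channels,
                                       bias=False, rng=rng)
        self.dsconv_pointwise = Conv2d(channels, channels, 1, bias=False, rng=rng)
        self.transform = transform
        if transform == "affine":
            self.t_scale = parameter(np.ones(channels))
            self.t_shift = parameter(np.zeros(channels))
        elif transform != "identity":
            raise ConfigurationError(f"unknown transform {transform!r}")
        # LCCI: circular 1D conv across channels, deliberately bias-free so
        # a zero descriptor maps to gates of exactly 0.5
        self.lcci_weight = parameter(
            rng.normal(0.0, np.sqrt(1.0 / kernel_size), size=kernel_size)
        )

    def attention_factors(self, s: Tensor) -> Tensor:
        """The per-channel gates φ for a shared feature map s, shape (N, C)."""
        q = ag.relu(ag.global_avg_pool(s))
        q = ag.reshape(q, q.data.shape[:2])
        if self.transform == "affine":
            q = ag.add(ag.mul(q, self.t_scale.reshape(1, -1)),
                       self.t_shift.reshape(1, -1))
        return ag.sigmoid(ag.circular_conv1d(q, self.lcci_weight))

    def forward(self, x: Tensor) -> Tensor:
        s = self.dsconv_pointwise(self.dsconv_depthwise(x))
        phi = self.attention_factors(s)
        phi4 = ag.reshape(phi, phi.data.shape + (1, 1))
        eta = ag.mul(phi4, s)
        return ag.relu(ag.add(eta, s))


class DecodeHead(Module):
    """DASPP → BICECA → bicubic upsample → skip fusion → logits.

    The high-level map is decoded, bicubically upsampled to the stride-4
    skip resolution, concatenated with a 1×1-projected skip, refined by a
    3×3 convolution and classified; class logits are bicubically
    upsampled to the input resolution.
    """

    def __init__(self, low_channels: int, high_channels: int,
                 config: DASPPConfig, norm: str = "bn", rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        k = (adaptive_lcci_kernel_size(config.branch_channels)
             if config.lcci_adaptive else config.lcci_kernel_size)
        self.daspp = DASPP(high_channels, config, norm, rng)
        self.biceca = BICECA(config.branch_channels, k,
                             config.attention_transform, norm, rng)
        self.low_proj = Conv2d(low_channels, config.low_level_proj_channels, 1,
                               bias=False, rng=rng)
        self.low_norm = make_norm(norm, config.low_level_proj_channels)
        self.refine = Sequential(
            Conv2d(config.branch_channels + config.low_level_proj_channels,
                   config.refine_channels, 3, rng=rng),
            make_norm(norm, config.refine_channels), ReLU(),
        )
        self.classifier = Conv2d(config.refine_channels, config.n_classes, 1,
                                 rng=rng)

    def forward(self, low: Tensor, high: Tensor,
                out_size: tuple[int, int]) -> Tensor:
        z = self.biceca(self.daspp(high))
        z = bicubic_resize_to(z, *low.data.shape[2:])
        skip = ag.relu(self.low_norm(self.low_proj(low)))
        z = self.refine(ag.concat([z, skip], axis=1))
        logits = self.classifier(z)
        return bicubic_resize_to(logits, *out_size)
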