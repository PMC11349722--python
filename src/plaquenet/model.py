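"""PlaqueNet: backbone + decode head + optional auxiliary branch."""

from __future__ import annotations

import numpy as np

from .aresnet import AResNetBackbone
from .autograd import Tensor
from .binet import BINetBranch
from .config import RunConfig
from .daspp_biceca import DecodeHead
from .nn import Module

__all__ = ["PlaqueNet", "build_model"]


class PlaqueNet(Module):
    """End-to-end segmentation network.

    ``forward_logits`` returns ``(main_logits, aux_logits)`` where the
    auxiliary logits are ``None`` unless requested and enabled; the
    auxiliary branch taps the backbone's stride-4 features and never
    feeds back into the main path.
    """

    def __init__(self, config: RunConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(config.seed)
        self.config = config
        bb = config.backbone
        self.backbone = AResNetBackbone(bb, rng)
        self.head = DecodeHead(bb.low_level_channels, bb.high_level_channels,
                               config.head, bb.norm, rng)
        if config.binet.enabled:
            self.binet = BINetBranch(bb.low_level_channels, config.binet,
                                     bb.low_level_stride,
                                     config.head.n_classes, bb.norm, rng)

    def forward_logits(self, image, with_aux: bool = False):
        x = image if isinstance(image, Tensor) else Tensor(image)
        low, high = self.backbone(x)
        main = self.head(low, high, x.data.shape[2:])
        aux = None
        if with_aux and self.config.binet.enabled:
            aux = self.binet(low)
        return main, aux

    forward = forward_logits

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Argmax segmentation masks for a batch of images (inference
        mode; the auxiliary branch is skipped entirely)."""
        was_training = self.training
        self.eval()
        try:
            main, _ = self.forward_logits(np.asarray(images, dtype=np.float64),
                                          with_aux=False)
        finally:
            self.train(was_training)
        return main.data.argmax(axis=1).astype(np.uint8)


def build_model(config: RunConfig, seed: int | None = None) -> PlaqueNet:
    """Construct a model with seeded parameter initialization."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return PlaqueNet(config, rng)
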