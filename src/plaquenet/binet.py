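"""BINet auxiliary branch and the joint cross-entropy loss.

BINet reads the backbone's stride-4 features, passes them through N
reflection-padded K×K convolutions and a bilinear upsampling step (with
the F_Avg smoothing pass), and classifies per pixel.  Its prediction is
scored against the ground-truth mask and the resulting auxiliary loss is
added to the main loss with weight λ:

    L_total = L_CE(main) + λ · L_CE(aux).

The branch reads backbone features but writes nothing back into the
main path, so enabling or disabling it cannot change inference output —
:func:`inference_equivalence_guard` asserts exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .config import BINetConfig
from .core_ops import avg2x2_matrix, resample_matrix
from .exceptions import DataError, InvariantViolation, ShapeError, UsageError
from .nn import Conv2d, Module, Sequential

__all__ = ["BINetBranch", "LossBundle", "cross_entropy", "joint_loss",
           "inference_equivalence_guard"]


class BINetBranch(Module):
    """Reflect-padded convolution stack + bilinear upsampling + classifier.

    The stack is N plain K×K convolutions (reflection padding, biases,
    no interleaved normalization or activation), matching the defining
    form of the branch; the stride-4 features it reads are already
    rectified by the backbone.
    """

    def __init__(self, in_channels: int, config: BINetConfig, upsample: int,
                 n_classes: int = 2, norm: str = "bn", rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        self.upsample = upsample
        self.stack = Sequential(*[
            Conv2d(in_channels, in_channels, config.kernel_size,
                   padding_mode="reflect", rng=rng)
            for _ in range(config.n_layers)
        ])
        self.classifier = Conv2d(in_channels, n_classes, 1, rng=rng)

    def forward(self, low: Tensor) -> Tensor:
        if not self.config.enabled:
            raise UsageError("BINet branch invoked while disabled")
        z = self.stack(low)
        _, _, h, w = z.data.shape
        Rm = resample_matrix(h, self.upsample, "bilinear")
        Cm = resample_matrix(w, self.upsample, "bilinear")
        if self.config.apply_avg:
            Rm = avg2x2_matrix(Rm.shape[0]) @ Rm
            Cm = avg2x2_matrix(Cm.shape[0]) @ Cm
        z = ag.resize2d(z, Rm, Cm)
        return self.classifier(z)


# ---------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------

@dataclass
class LossBundle:
    """Main, auxiliary and combined loss of one step/epoch."""

    main_loss: float
    aux_loss: float
    aux_weight: float
    total_loss: float
    graph: object = field(default=None, repr=False, compare=False)

    def as_dict(self) -> dict:
        return {
            "main_loss": self.main_loss,
            "aux_loss": self.aux_loss,
            "aux_weight": self.aux_weight,
            "total_loss": self.total_loss,
        }


def _check_target(logits: Tensor, target: np.ndarray) -> np.ndarray:
    target = np.asarray(target)
    n_classes = logits.data.shape[1]
    if target.shape != (logits.data.shape[0],) + logits.data.shape[2:]:
        raise ShapeError(
            f"target shape {target.shape} does not match logits "
            f"{logits.data.shape}"
        )
    bad = (target < 0) | (target >= n_classes)
    if bad.any():
        offending = np.unique(target[bad])
        raise DataError(
            f"target contains labels {offending.tolist()} outside "
            f"[0, {n_classes})"
        )
    return target.astype(int)


def cross_entropy(logits: Tensor, target, class_weights=None) -> Tensor:
    """Mean per-pixel softmax cross-entropy.

    ``class_weights`` (optional, one per class) reweights pixel terms and
    renormalizes by the total weight, so uniform weights equal the plain
    mean.
    """
    logits = logits if isinstance(logits, Tensor) else Tensor(logits)
    target = _check_target(logits, target)
    n_classes = logits.data.shape[1]
    logp = ag.log_softmax(logits, axis=1)
    onehot = np.moveaxis(np.eye(n_classes)[target], -1, 1)
    if class_weights is None:
        picked = ag.tensor_sum(ag.mul(logp, Tensor(onehot)))
        return ag.mul(picked, Tensor(-1.0 / target.size))
    w = np.asarray(class_weights, dtype=np.float64)[target]
    weighted = ag.mul(logp, Tensor(onehot * w[:, None]))
    return ag.mul(ag.tensor_sum(weighted), Tensor(-1.0 / w.sum()))


def joint_loss(main_logits, aux_logits, target, aux_weight: float,
               class_weights=None) -> LossBundle:
    """Combine main and auxiliary cross-entropies: total = main + λ·aux.

    ``aux_logits`` may be ``None`` (auxiliary branch absent/disabled), in
    which case the auxiliary loss is zero and total equals main.
    """
    if aux_weight < 0:
        raise DataError(f"aux_weight must be nonnegative, got {aux_weight}")
    main = cross_entropy(main_logits, target, class_weights)
    if aux_logits is None:
        total = main
        aux_val = 0.0
    else:
        aux = cross_entropy(aux_logits, target, class_weights)
        aux_val = aux.item()
        total = ag.add(main, ag.mul(aux, Tensor(float(aux_weight))))
    return LossBundle(
        main_loss=main.item(),
        aux_loss=aux_val,
        aux_weight=float(aux_weight),
        total_loss=main.item() + float(aux_weight) * aux_val,
        graph=total,
    )


def inference_equivalence_guard(model, image) -> None:
    """Assert the auxiliary branch cannot alter inference output.

    Runs the main head twice on ``image`` — once with the auxiliary
    branch enabled and once disabled — and demands bit-identical main
    logits (hence identical argmax masks).  Raises
    :class:`InvariantViolation` naming the first differing pixel.
    """
    logits_with = model.forward_logits(image, with_aux=True)[0].data
    logits_without = model.forward_logits(image, with_aux=False)[0].data
    diff = logits_with != logits_without
    if diff.any():
        first = tuple(int(v) for v in np.argwhere(diff)[0])
        raise InvariantViolation(
            "auxiliary branch altered main-head output; first differing "
            f"logit at (batch, class, row, col)={first}: "
            f"{logits_with[first]} vs {logits_without[first]}"
        )
    mask_with = logits_with.argmax(axis=1)
    mask_without = logits_without.argmax(axis=1)
    if (mask_with != mask_without).any():  # pragma: no cover - implied above
        raise InvariantViolation("masks differ between aux-enabled/disabled")
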