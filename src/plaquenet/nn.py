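"""Layer and optimizer building blocks on top of :mod:`plaquenet.autograd`.

Mirrors the familiar ``Module`` idiom: layers own named parameters,
``named_parameters`` walks the tree, and state can be round-tripped
through flat ``{name: array}`` dicts for checkpointing.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .exceptions import ConfigurationError, ShapeError


class Module:
    """Base class; submodules and parameters are discovered by attribute scan."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def add_module(self, name: str, module: "Module") -> None:
        self._modules[name] = module
        object.__setattr__(self, name, module)

    # -- traversal -----------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, self._buffers[name]
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- state dict ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state[name] = np.asarray(b).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {}
        for m_prefix, m in self._walk(""):
            for bname in m._buffers:
                buffers[m_prefix + bname] = m
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ShapeError(
                        f"parameter {name}: checkpoint shape {value.shape} "
                        f"!= model shape {params[name].data.shape}"
                    )
                params[name].data = np.asarray(value, dtype=np.float64).copy()
            elif name in buffers:
                mod = buffers[name]
                bname = name.rsplit(".", 1)[-1] if "." in name else name
                mod.register_buffer(bname, np.asarray(value, dtype=np.float64).copy())
            else:
                raise KeyError(f"unexpected entry in state dict: {name}")

    def _walk(self, prefix: str):
        yield prefix, self
        for name, m in self._modules.items():
            yield from m._walk(prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def parameter(data) -> Tensor:
    t = Tensor(data)
    t.requires_grad = True
    return t


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, dilation: int = 1, groups: int = 1,
                 bias: bool = True, padding="same", padding_mode: str = "zeros",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ConfigurationError("channels must be divisible by groups")
        k = kernel_size
        self.stride = stride
        self.dilation = dilation
        self.groups = groups
        self.padding = dilation * (k - 1) // 2 if padding == "same" else padding
        self.padding_mode = padding_mode
        rng = rng or np.random.default_rng(0)
        fan_in = (in_channels // groups) * k * k
        self.weight = parameter(
            he_init(rng, (out_channels, in_channels // groups, k, k), fan_in)
        )
        self.bias = parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(
            x, self.weight, self.bias, stride=self.stride,
            dilation=self.dilation, groups=self.groups,
            padding=self.padding, padding_mode=self.padding_mode,
        )


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = parameter(np.ones(channels))
        self.beta = parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = ag.tensor_mean(ag.mul(xc, xc), axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbias = n / max(n - 1, 1)
            self.register_buffer(
                "running_mean",
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.reshape(-1),
            )
            self.register_buffer(
                "running_var",
                (1 - self.momentum) * self.running_var
                + self.momentum * unbias * var.data.reshape(-1),
            )
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
            xc = x - mu
        inv = ag.power(var + Tensor(self.eps), -0.5)
        xhat = ag.mul(xc, inv)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return ag.add(ag.mul(xhat, g), b)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        for i, layer in enumerate(layers):
            self.add_module(str(i), layer)
        self._order = [str(i) for i in range(len(layers))]

    def forward(self, x: Tensor) -> Tensor:
        for name in self._order:
            x = self._modules[name](x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


def make_norm(kind: str, channels: int) -> Module:
    if kind == "bn":
        return BatchNorm2d(channels)
    if kind == "none":
        return Identity()
    raise ConfigurationError(f"unknown norm kind {kind!r}")


class Adam:
    """Adam optimizer (Kingma & Ba) over a list of parameters."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
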