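"""Neural-network layers and optimization on top of :mod:`endomoe.autograd`.

Layers follow the familiar Module pattern: parameters register themselves on
attribute assignment, ``parameters()`` walks the tree, and ``train()`` /
``eval()`` toggle batch-norm statistics and dropout.  Initialization is fully
seeded: constructors take a ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class ConfigurationError(ValueError):
    """A layer or model was configured inconsistently."""


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._children[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for name, child in self._children.items():
            yield from child.named_parameters(f"{prefix}{name}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for child in self._children.values():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state ---------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_modules():
            for bname, buf in getattr(m, "_buffers", {}).items():
                state[f"{name}{bname}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=np.float64)
        for name, m in self._named_modules():
            for bname in getattr(m, "_buffers", {}):
                m._buffers[bname] = np.array(state[f"{name}{bname}"], dtype=np.float64)

    def _named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, child in self._children.items():
            yield from child._named_modules(f"{prefix}{name}.")

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """2-D convolution with TF-style 'same' padding and optional groups."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: str | int = "same", groups: int = 1, bias: bool = True):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ConfigurationError(
                f"channels ({in_channels}->{out_channels}) must be divisible "
                f"by groups ({groups})"
            )
        self.in_channels = in_channels
        self.stride = stride
        self.padding = padding
        self.groups = groups
        fan_in = (in_channels // groups) * kernel * kernel
        self.weight = Parameter(
            he_normal(rng, (out_channels, in_channels // groups, kernel, kernel), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ConfigurationError(
                f"expected {self.in_channels} input channels, received {x.shape[1]}"
            )
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, groups=self.groups)

    __call__ = forward


class BatchNorm2d(Module):
    """Per-channel batch normalization.

    Training mode normalizes with batch statistics and updates running
    averages; eval mode uses the running averages.  Scale/shift initialize to
    1/0 so a freshly built layer in eval mode is the identity.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self._buffers = {
            "running_mean": np.zeros(channels),
            "running_var": np.ones(channels),
        }

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        if self.training:
            mu = ag.mean(x, axis=(0, 2, 3), keepdims=True)
            var = ag.mean((x - mu) ** 2.0, axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.data.reshape(C)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.data.reshape(C)
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(1, C, 1, 1))
            var = Tensor(self._buffers["running_var"].reshape(1, C, 1, 1))
        xhat = (x - mu) / ag.sqrt(var + self.eps)
        g = ag.reshape(self.gamma, (1, C, 1, 1))
        b = ag.reshape(self.beta, (1, C, 1, 1))
        return xhat * g + b

    __call__ = forward


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(he_normal(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out

    __call__ = forward


class Dropout(Module):
    """Inverted dropout; active in training mode only.

    Draws its masks from a generator owned by the model so that a fixed model
    seed makes training runs bit-reproducible.
    """

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ConfigurationError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)

    __call__ = forward


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
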