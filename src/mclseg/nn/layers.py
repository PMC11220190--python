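"""Parameterized layers built on the functional primitives.

A layer owns named :class:`Param` objects and exposes
``forward(x, train) -> (y, cache)`` / ``backward(cache, gy) -> gx``;
``backward`` *accumulates* into each parameter's ``.grad`` so one layer can
contribute from several forward passes before an optimizer step.
"""

from __future__ import annotations

import numpy as np

from . import functional as F

__all__ = ["Param", "Conv2d", "BatchNorm2d", "DoubleConv"]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Minimal container protocol: named parameters and buffers."""

    def named_parameters(self):
        for name, value in vars(self).items():
            if isinstance(value, Param):
                yield name, value
            elif isinstance(value, Module):
                for sub, p in value.named_parameters():
                    yield f"{name}.{sub}", p
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, p in item.named_parameters():
                            yield f"{name}.{i}.{sub}", p

    def named_buffers(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                for sub, b in value.named_buffers():
                    yield f"{name}.{sub}", b
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, b in item.named_buffers():
                            yield f"{name}.{i}.{sub}", b
            elif name.startswith("running_"):
                yield name, value

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


class Conv2d(Module):
    """Same-padding stride-1 convolution with He-normal initialization."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator):
        fan_in = cin * kernel * kernel
        self.weight = Param(
            rng.standard_normal((cout, cin, kernel, kernel)) * np.sqrt(2.0 / fan_in)
        )
        self.bias = Param(np.zeros(cout))

    def forward(self, x, train: bool = True):
        return F.conv2d_forward(x, self.weight.data, self.bias.data)

    def backward(self, cache, gy):
        gx, gw, gb = F.conv2d_backward(cache, gy)
        self.weight.grad += gw
        self.bias.grad += gb
        return gx


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train: bool = True):
        return F.batchnorm_forward(
            x, self.gamma.data, self.beta.data,
            self.running_mean, self.running_var,
            train, self.momentum, self.eps,
        )

    def backward(self, cache, gy):
        gx, ggamma, gbeta = F.batchnorm_backward(cache, gy)
        self.gamma.grad += ggamma
        self.beta.grad += gbeta
        return gx


class DoubleConv(Module):
    """(conv 3x3 - BN - ReLU) x 2, the basic block of the backbone."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, rng)
        self.bn2 = BatchNorm2d(cout)

    def forward(self, x, train: bool = True):
        y, c1 = self.conv1.forward(x, train)
        y, b1 = self.bn1.forward(y, train)
        y, r1 = F.relu_forward(y)
        y, c2 = self.conv2.forward(y, train)
        y, b2 = self.bn2.forward(y, train)
        y, r2 = F.relu_forward(y)
        return y, (c1, b1, r1, c2, b2, r2)

    def backward(self, cache, gy):
        c1, b1, r1, c2, b2, r2 = cache
        g = F.relu_backward(r2, gy)
        g = self.bn2.backward(b2, g)
        g = self.conv2.backward(c2, g)
        g = F.relu_backward(r1, g)
        g = self.bn1.backward(b1, g)
        return self.conv1.backward(c1, g)
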