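"""Layers, initialization and the Adam optimizer for the counting network."""

from __future__ import annotations

import math

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class; submodules and parameters are discovered by attribute scan."""

    def parameters(self) -> list[Tensor]:
        params = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = []
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, x):
        return self.forward(x)


class Conv2d(Module):
    """3x3 / 1x1 convolution, stride 1, He-normal initialized."""

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        std = math.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, size=(c_out, c_in, kernel, kernel)).astype(np.float32)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self.dilation = dilation
        self.padding = dilation * (kernel - 1) // 2  # "same" spatial size
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias,
                         dilation=self.dilation, padding=self.padding)

    def describe(self) -> str:
        return (f"conv{self.kernel}-{self.c_out}"
                + (f" (dilation {self.dilation})" if self.dilation > 1 else ""))


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()

    def describe(self) -> str:
        return "relu"


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()

    def describe(self) -> str:
        return "sigmoid"


class MaxPool2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.maxpool2x2(x)

    def describe(self) -> str:
        return "maxpool2"


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    def describe(self) -> str:
        return " -> ".join(l.describe() for l in self.layers)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
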