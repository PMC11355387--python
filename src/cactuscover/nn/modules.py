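"""Parameterised layers built on the autograd ops.

Initialisation is He-normal from a caller-supplied ``numpy.random.Generator``
so that a model build is fully reproducible from its seed.  Parameters are
float32 throughout.
"""

from __future__ import annotations

import numpy as np

from . import ops
from .tensor import Tensor


class Module:
    """Base class: recursively exposes parameters of attribute sub-modules."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
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

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state length mismatch")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("state shape mismatch")
            p.data = s.copy()


def _he(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    w = rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
    return Tensor(w.astype(np.float32), requires_grad=True)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, *,
                 stride: int = 1, dilation: int = 1, padding="same", bias: bool = True):
        self.stride, self.dilation, self.padding = stride, dilation, padding
        self.w = _he(rng, (cout, cin, k, k), cin * k * k)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return ops.conv2d(x, self.w, self.b, stride=self.stride,
                          dilation=self.dilation, padding=self.padding)


class ConvTranspose2x2(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = _he(rng, (cin, cout, 2, 2), cin * 4)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ops.conv_transpose2x2(x, self.w, self.b)


class SeparableConv2d(Module):
    """Depthwise 3x3 followed by pointwise 1x1 (the Xception building block)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, *, k: int = 3):
        self.dw = _he(rng, (cin, k, k), k * k)
        self.pw = Conv2d(cin, cout, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.pw(ops.depthwise_conv2d(x, self.dw))


class Adam:
    """Adam optimiser (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= lr_t * m / (np.sqrt(v) + self.eps)
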