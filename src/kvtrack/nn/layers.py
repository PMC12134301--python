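"""Layers and the Adam optimiser built on the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "InstanceNorm", "Adam"]


class Module:
    """Base class: recursive parameter collection and state (de)serialisation."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = np.asarray(a, dtype=np.float64).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2, pad: int = 1,
                 bias: bool = True, init_std: float = 0.02, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride, self.pad = stride, pad
        self.w = Tensor(rng.normal(0.0, init_std, (cout, cin, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b, self.stride, self.pad)


class ConvTranspose2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 4, stride: int = 2, pad: int = 1,
                 bias: bool = True, init_std: float = 0.02, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride, self.pad = stride, pad
        self.w = Tensor(rng.normal(0.0, init_std, (cin, cout, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2d(x, self.w, self.b, self.stride, self.pad)


class InstanceNorm(Module):
    def __init__(self, channels: int):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ad.instance_norm(x, self.gamma, self.beta)


class Adam:
    """Adam with GAN-customary moments (beta1 = 0.5 by default)."""

    def __init__(self, params, lr: float = 2e-4, betas=(0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
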