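"""Small neural-network building blocks on top of :mod:`ccaae.autodiff`.

Provides ``Linear`` layers, multilayer perceptrons with leaky-rectifier
activations, and the Adam optimiser.  Initialisation draws exclusively from
a caller-supplied ``numpy.random.Generator``, so network construction is
bitwise reproducible.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Linear", "MLP", "Adam"]


class Module:
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
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Linear(Module):
    """Affine map ``x @ W + b`` with He-style fan-in initialisation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)
        self.n_in, self.n_out = n_in, n_out

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.n_in:
            raise ValueError(
                f"Linear layer expected input dimension {self.n_in}, got {x.shape[-1]}"
            )
        return x @ self.W + self.b


class MLP(Module):
    """Fully-connected network; hidden layers use leaky-ReLU, output is linear."""

    def __init__(
        self,
        n_in: int,
        hidden: Sequence[int],
        n_out: int,
        rng: np.random.Generator,
        slope: float = 0.2,
    ):
        dims = [n_in, *hidden, n_out]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.slope = slope
        self.n_in, self.n_out = n_in, n_out

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).leaky_relu(self.slope)
        return self.layers[-1](x)


class Adam:
    """Adaptive-moment gradient descent over a fixed parameter list."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
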