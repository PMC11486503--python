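"""Building blocks: Xavier-initialized affine maps, two-layer MLPs and Adam."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["xavier_uniform", "Linear", "MLP", "Adam"]


def xavier_uniform(shape: tuple[int, int], rng: np.random.Generator) -> Tensor:
    """Glorot/Xavier uniform parameter: U(-a, a), a = sqrt(6/(fan_in+fan_out))."""
    bound = np.sqrt(6.0 / (shape[0] + shape[1]))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear:
    """Affine map x @ W (+ b).  Bias is optional; attention projections omit it."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = xavier_uniform((d_in, d_out), rng)
        self.bias = Tensor(np.zeros((1, d_out)), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class MLP:
    """Stack of affine layers with ReLU between them (none after the last)."""

    def __init__(self, dims: list[int], rng: np.random.Generator, bias: bool = True):
        if len(dims) < 2:
            raise ValueError("MLP needs at least input and output widths")
        self.layers = [Linear(a, b, rng, bias=bias) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
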