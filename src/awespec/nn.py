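"""Neural-network building blocks on top of :mod:`awespec.autodiff`.

Layers hold named :class:`Parameter` tensors; :class:`Module` provides
recursive parameter collection and a flat state dict for checkpointing.
Weights use Glorot (fan-based) uniform initialization from a caller-supplied
:class:`numpy.random.Generator`, so model construction is reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = ["Parameter", "Module", "Linear", "LayerNorm", "gelu", "softplus",
           "dropout", "Adam"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container with recursive parameter discovery and a flat state dict."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=float)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    """Affine map x @ W + b with Glorot-uniform W and zero b."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (in_dim + out_dim))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return as_tensor(x) @ self.weight + self.bias


class LayerNorm(Module):
    """Layer normalization over the last axis with learnable gain and bias."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * ((var + self.eps) ** -0.5) * self.gain + self.bias


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error linear unit, x * Phi(x), via erf."""
    x = as_tensor(x)
    return x * 0.5 * (1.0 + (x * (1.0 / np.sqrt(2.0))).erf())


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)) — smooth positive reparameterization for blur widths."""
    x = as_tensor(x)
    # stable form: max(x,0) + log1p(exp(-|x|)); the magnitudes here are mild,
    # so the direct composition is adequate and keeps the tape simple.
    return (1.0 + x.exp()).log()


def softplus_inverse(y: float) -> float:
    return float(np.log(np.expm1(y)))


def dropout(x: Tensor, p: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return as_tensor(x)
    if rng is None:
        raise ValueError("dropout in training mode requires an rng")
    mask = (rng.random(x.shape) >= p).astype(float) / (1.0 - p)
    return as_tensor(x) * mask


class Adam:
    """Adaptive-moment estimation with externally controlled learning rate."""

    def __init__(self, params, lr: float = 2e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
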