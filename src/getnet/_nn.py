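"""Minimal neural-network layer library over :mod:`getnet._tensor`.

Modules register parameters and sub-modules by attribute assignment, as
the major frameworks do.  Feature maps are channel-first ``(C, D, H, W)``
arrays without a batch axis — the training recipe this package follows
uses batch size 1, and group normalization (the only normalizer in the
network besides LayerNorm) is batch-independent by construction.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from ._tensor import Tensor, pad

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Linear",
    "LayerNorm",
    "Mlp",
    "Conv1x1x1",
    "DepthwiseConv3d",
    "Adam",
]


class Parameter(Tensor):
    """A tensor that is updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: tracks parameters/sub-modules via ``__setattr__``."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Parameter]:
        yield from self._params.values()
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, p in self._params.items():
            yield (f"{prefix}{k}", p)
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{k}.")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    """A registered, indexable list of sub-modules."""

    def __init__(self, modules=()):
        super().__init__()
        self._items = []
        for m in modules:
            self.append(m)

    def append(self, module: Module) -> None:
        self._modules[str(len(self._items))] = module
        self._items.append(module)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class Linear(Module):
    """Affine map on the last axis: ``y = x W^T + b``."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight.transpose(1, 0) + self.bias


class LayerNorm(Module):
    """Normalization over the last axis with learned affine."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class Mlp(Module):
    """Two-layer perceptron with GeLU, the standard transformer FFN."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class Conv1x1x1(Module):
    """Pointwise 3D convolution — a per-voxel channel mix on (C, D, H, W)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(in_channels)
        self.weight = Parameter(rng.uniform(-bound, bound, (out_channels, in_channels)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_channels))

    def forward(self, x: Tensor) -> Tensor:
        c, d, h, w = x.shape
        y = self.weight @ x.reshape(c, d * h * w)
        y = y + self.bias.reshape(-1, 1)
        return y.reshape(self.weight.shape[0], d, h, w)


class DepthwiseConv3d(Module):
    """Depth-wise 3D convolution: one k×k×k spatial filter per channel.

    Zero padding ``k // 2`` preserves the spatial shape.  Implemented as
    an accumulation over kernel offsets, which keeps it inside the
    autodiff graph without a dedicated convolution primitive.
    """

    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd to preserve shape")
        self.kernel_size = kernel_size
        k = kernel_size
        bound = 1.0 / np.sqrt(k**3)
        self.weight = Parameter(rng.uniform(-bound, bound, (channels, k, k, k)))
        self.bias = Parameter(rng.uniform(-bound, bound, channels))

    def forward(self, x: Tensor) -> Tensor:
        c, d, h, w = x.shape
        k = self.kernel_size
        p = k // 2
        xp = pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        out = None
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    patch = xp[:, i : i + d, j : j + h, l : l + w]
                    term = patch * self.weight[:, i, j, l].reshape(c, 1, 1, 1)
                    out = term if out is None else out + term
        return out + self.bias.reshape(c, 1, 1, 1)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
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
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
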