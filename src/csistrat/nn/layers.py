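"""Parameterised layers built on the autograd engine.

Initialisation is a seeded uniform fan-in scheme: every weight of a layer
with fan-in ``f`` is drawn from U(-1/sqrt(f), 1/sqrt(f)) using the
``numpy.random.Generator`` handed to the constructor, so two modules built
from generators in the same state are bit-identical.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .autograd import Tensor


class Module:
    """Base class with an ordered parameter registry."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for mn, m in self._modules.items():
            out.extend(m.named_parameters(prefix + mn + "."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            p.data = np.asarray(state[n], dtype=np.float64).reshape(p.data.shape)

    def weight_hash(self) -> str:
        """SHA-256 over all parameter arrays in registry order."""
        h = hashlib.sha256()
        for name, p in self.named_parameters():
            h.update(name.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _uniform(rng, (in_dim, out_dim), in_dim)
        self.bias = _uniform(rng, (out_dim,), in_dim)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    """Lookup table; row 0 is the padding token (trained like any other)."""

    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.table = Tensor(rng.uniform(-0.1, 0.1, size=(n_tokens, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.table.take_rows(idx)


class Conv1d(Module):
    """Same-padded 1D convolution over (B, L, C_in) -> (B, L, C_out)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        self.weight = _uniform(rng, (kernel * in_channels, out_channels), kernel * in_channels)
        self.bias = _uniform(rng, (out_channels,), kernel * in_channels)

    def __call__(self, x: Tensor) -> Tensor:
        return x.sliding_windows(self.kernel) @ self.weight + self.bias


class MLP(Module):
    """Fully connected stack with ReLU between layers; last layer is linear."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        super().__init__()
        self.n_layers = len(dims) - 1
        for i in range(self.n_layers):
            setattr(self, f"fc{i}", Dense(dims[i], dims[i + 1], rng))

    def __call__(self, x: Tensor) -> Tensor:
        for i in range(self.n_layers):
            x = getattr(self, f"fc{i}")(x)
            if i < self.n_layers - 1:
                x = x.relu()
        return x
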