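"""Layer primitives (Linear, LayerNorm, BatchNorm, MLP) on the Tensor engine."""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor

__all__ = ["Module", "Linear", "LayerNorm", "BatchNorm", "Mlp"]


class Module:
    """Tiny module base: recursive parameter discovery, train/eval mode."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in vars(self).values():
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in vars(self).values():
            mods.extend(_collect_modules(v))
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    training: bool = True

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        self._state("", out)
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {}
        self._state("", own)
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch: {sorted(missing)[:5]}")
        for k, arr in own.items():
            arr[...] = state[k]

    def _state(self, prefix: str, out: dict[str, np.ndarray]) -> None:
        for name, v in vars(self).items():
            _state_value(f"{prefix}{name}", v, out)


def _state_value(key: str, v, out: dict[str, np.ndarray]) -> None:
    if isinstance(v, Tensor):
        out[key] = v.data
    elif isinstance(v, np.ndarray):
        out[key] = v
    elif isinstance(v, Module):
        v._state(key + ".", out)
    elif isinstance(v, (list, tuple)):
        for i, item in enumerate(v):
            _state_value(f"{key}.{i}", item, out)


def _collect(v) -> list[Tensor]:
    if isinstance(v, Tensor) and v.requires_grad:
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect(item))
        return out
    return []


def _collect_modules(v) -> list[Module]:
    if isinstance(v, Module):
        return v.modules()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect_modules(item))
        return out
    return []


class Linear(Module):
    """Dense layer with Glorot-uniform weights (fast from-scratch convergence)."""

    def __init__(self, rng: np.random.Generator, in_features: int, out_features: int, bias: bool = True):
        limit = math.sqrt(6.0 / (in_features + out_features))
        w = rng.uniform(-limit, limit, size=(in_features, out_features)).astype(np.float32)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.weight = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.weight, self.bias, self.eps)


class BatchNorm(Module):
    """Channel-last batch norm over all leading axes; running stats for eval."""

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.1):
        self.weight = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(dim, dtype=np.float32)
        self.running_var = np.ones(dim, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum
        self.training = True
        # 1 after the first batch: running stats are seeded from it rather
        # than decayed from the (arbitrary) 0/1 init
        self.initialized = np.zeros(1, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            n = x.data.size // x.shape[-1]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            mom = self.momentum if self.initialized[0] else 1.0
            self.initialized[0] = 1.0
            self.running_mean += mom * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += mom * (unbiased - self.running_var)
            inv = (var + self.eps).pow(-0.5)
            xhat = xc * inv
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - Tensor(self.running_mean)) * Tensor(inv)
        return xhat * self.weight + self.bias


class Mlp(Module):
    """Transformer feed-forward block: Linear -> GELU -> Linear."""

    def __init__(self, rng: np.random.Generator, dim: int, hidden: int):
        self.fc1 = Linear(rng, dim, hidden)
        self.fc2 = Linear(rng, hidden, dim)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())
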