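"""Neural-network building blocks on top of the autograd engine.

Layers hold :class:`~sdsseg.autograd.Tensor` parameters; ``Module``
collects parameters recursively and toggles train/eval mode (the latter
only matters for batch normalization).  Weights use He-uniform
initialization drawn from a caller-supplied ``numpy.random.Generator``
so that whole networks are reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: parameter collection and train/eval switching."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in self.__dict__.values():
            mods.extend(_collect_modules(v))
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers (for checkpoints)."""
        out: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            out[f"param_{i}"] = p.data
        for j, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm):
                out[f"bn_{j}_mean"] = m.running_mean
                out[f"bn_{j}_var"] = m.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            arr = state[f"param_{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch for param_{i}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype)
        for j, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm):
                m.running_mean = state[f"bn_{j}_mean"].astype(np.float64)
                m.running_var = state[f"bn_{j}_var"].astype(np.float64)


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


def _collect_modules(v) -> list["Module"]:
    if isinstance(v, Module):
        return v.modules()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect_modules(item))
        return out
    return []


def he_uniform(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    limit = np.sqrt(6.0 / max(fan_in, 1))
    return Tensor(rng.uniform(-limit, limit, size=shape).astype(ag.DTYPE), requires_grad=True)


class Conv(Module):
    """n-dimensional convolution (2 or 3 spatial dims) with optional bias."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int, kernel,
                 stride=1, pad=0, bias: bool = True, ndim: int = 2):
        if isinstance(kernel, int):
            kernel = (kernel,) * ndim
        fan_in = cin * int(np.prod(kernel))
        self.w = he_uniform(rng, (cout, cin) + tuple(kernel), fan_in)
        self.b = Tensor(np.zeros(cout, dtype=ag.DTYPE), requires_grad=True) if bias else None
        self.stride = stride
        self.pad = pad

    def __call__(self, x: Tensor) -> Tensor:
        return ag.convnd(x, self.w, self.b, stride=self.stride, pad=self.pad)


class ConvTranspose2x(Module):
    """Transposed convolution with kernel 2 / stride 2 (spatial doubling)."""

    def __init__(self, rng: np.random.Generator, cin: int, cout: int, bias: bool = True):
        self.w = he_uniform(rng, (cin, cout, 2, 2), fan_in=cin * 4)
        self.b = Tensor(np.zeros(cout, dtype=ag.DTYPE), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2x(x, self.w, self.b)


class BatchNorm(Module):
    """Per-channel batch normalization for (N, C, *spatial) tensors."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(channels, dtype=ag.DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=ag.DTYPE), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.eps = eps
        self.momentum = momentum

    def __call__(self, x: Tensor) -> Tensor:
        nd = x.ndim
        axes = (0,) + tuple(range(2, nd))
        bshape = (1, -1) + (1,) * (nd - 2)
        if self.training:
            mu = ag.tmean(x, axis=axes, keepdims=True)
            xc = x - mu
            var = ag.tmean(ag.square(xc), axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            xn = xc * ag.div(1.0, ag.sqrt(var + self.eps))
        else:
            mu = self.running_mean.reshape(bshape).astype(ag.DTYPE)
            sd = np.sqrt(self.running_var + self.eps).reshape(bshape).astype(ag.DTYPE)
            xn = (x - mu) * (1.0 / sd)
        return xn * ag.reshape(self.gamma, bshape) + ag.reshape(self.beta, bshape)


class SGD:
    """Plain stochastic gradient descent with optional classical momentum."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params] if momentum else None

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + 2.0 * self.weight_decay * p.data
            if self._velocity is not None:
                self._velocity[i] = self.momentum * self._velocity[i] - self.lr * g
                p.data = p.data + self._velocity[i]
            else:
                p.data = p.data - self.lr * g

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
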