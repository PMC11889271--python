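"""Layer/module system for the numpy NN backend.

Mirrors the familiar layer API of mainstream deep-learning libraries at the
small scale this package needs: named parameters, train/eval modes, and
recursive submodule discovery via attribute assignment.
"""

from __future__ import annotations

from typing import Dict, Iterator, Tuple

import numpy as np

from . import functional as F
from .autograd import Tensor

__all__ = [
    "Parameter", "Module", "ModuleList", "Conv2d", "ConvTranspose2x2",
    "Linear", "BatchNorm2d", "Dropout2d", "Sequential",
]


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class: tracks parameters, submodules, buffers, and mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ----------------------------------------------------------

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def named_buffers(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, self._buffers[name]
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- state dict ----------------------------------------------------------

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state["buffer:" + name] = b.copy()
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        expected = set(params) | {"buffer:" + n for n in buffers}
        given = set(state)
        if expected != given:
            missing = sorted(expected - given)[:5]
            extra = sorted(given - expected)[:5]
            raise ValueError(
                f"state dict mismatch; missing={missing} unexpected={extra}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"parameter {name}: shape {arr.shape} != {p.data.shape}")
            p.data[...] = arr
        for name, b in buffers.items():
            arr = np.asarray(state["buffer:" + name], dtype=b.dtype)
            if arr.shape != b.shape:
                raise ValueError(f"buffer {name}: shape {arr.shape} != {b.shape}")
            b[...] = arr

    # -- mode ----------------------------------------------------------------

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    """An indexable container whose entries are registered submodules."""

    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, module: Module):
        idx = len(self._list)
        self._list.append(module)
        self._modules[str(idx)] = module
        return self

    def __getitem__(self, idx) -> Module:
        return self._list[idx]

    def __len__(self) -> int:
        return len(self._list)

    def __iter__(self):
        return iter(self._list)


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32):
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Conv2d(Module):
    """Stride-1 "same" convolution; weight [out, in, k, k], He-initialised."""

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int, rng: np.random.Generator,
                 dilation: int = 1, bias: bool = True, dtype=np.float32):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel_size, self.dilation = kernel_size, dilation
        fan_in = in_ch * kernel_size * kernel_size
        self.weight = Parameter(_he_init(rng, (out_ch, in_ch, kernel_size, kernel_size),
                                         fan_in, dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class ConvTranspose2x2(Module):
    """Kernel-2 stride-2 transposed convolution (2x learned upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.weight = Parameter(_he_init(rng, (in_ch, out_ch, 2, 2), in_ch * 4, dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2x2(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.weight = Parameter(_he_init(rng, (out_features, in_features), in_features, dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics.

    ``decay`` is the fraction of the previous running estimate retained per
    update (0.998 keeps 99.8%, folding in 0.2% of each batch).
    """

    def __init__(self, channels: int, decay: float = 0.998, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.decay, self.eps = decay, eps
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float64))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float64))

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.training, self.decay, self.eps)


class Dropout2d(Module):
    """Elementwise inverted dropout driven by an owned Generator.

    Reseedable via :meth:`reseed` so training runs are reproducible.
    """

    def __init__(self, rate: float, seed: int = 0):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._rng = np.random.default_rng(seed)

    def reseed(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        return F.dropout(x, self.rate, self._rng, self.training)
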