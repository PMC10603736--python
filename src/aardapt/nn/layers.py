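"""Neural-network layers built on the autodiff tensor.

Layers register parameters and submodules by attribute assignment, expose
``parameters()`` / ``state_dict()`` and a train/eval switch, and are seeded
explicitly through a ``numpy.random.Generator`` at construction so that two
builds from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module", "Sequential", "Conv1d", "ConvTranspose1d", "Linear",
    "BatchNorm1d", "LeakyReLU", "Dropout", "GlobalAvgPool1d",
]


class Module:
    """Base class: parameter registry plus train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Tensor]:
        params = [v for v in vars(self).values()
                  if isinstance(v, Tensor) and v.requires_grad]
        for _, child in self._children():
            params.extend(child.parameters())
        return params

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- serialisation ---------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor):
                state[prefix + name] = value.data.copy()
            elif isinstance(value, np.ndarray):  # running statistics
                state[prefix + name] = value.copy()
        for name, child in self._children():
            state.update(child.state_dict(prefix + name + "."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in vars(self).items():
            key = prefix + name
            if isinstance(value, Tensor) and key in state:
                value.data[...] = state[key]
            elif isinstance(value, np.ndarray) and key in state:
                value[...] = state[key]
        for name, child in self._children():
            child.load_state_dict(state, prefix + name + ".")


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming(rng: np.random.Generator, shape: tuple, fan_in: int,
             dtype=np.float32) -> np.ndarray:
    """Fan-in-scaled normal initialisation (He et al. style)."""
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Conv1d(Module):
    """Stride-1, same-padded temporal convolution; weight (C_out, C_in, k)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        fan_in = in_channels * kernel_size
        self.weight = Tensor(_kaiming(rng, (out_channels, in_channels, kernel_size),
                                      fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv1d(x, self.weight, self.bias)


class ConvTranspose1d(Conv1d):
    """Transposed temporal convolution at unit stride.

    With stride 1 the transpose of a same-padded convolution is itself a
    same-padded convolution with flipped kernels and swapped channel roles,
    so the layer shares the convolution forward path while keeping the
    decoder-side (in, out) naming.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__(in_channels, out_channels, kernel_size, rng, bias=bias)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Tensor(_kaiming(rng, (out_features, in_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.linear(x, self.weight, self.bias)


class BatchNorm1d(Module):
    """Per-channel batch normalisation for (N, C) or (N, C, T) input."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training,
                            momentum=self.momentum, eps=self.eps)


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.01):
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x: Tensor) -> Tensor:
        return F.leaky_relu(x, self.negative_slope)


class Dropout(Module):
    """Inverted dropout; the mask stream is seeded at construction."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep
        return F.dropout_mask(x, mask)


class GlobalAvgPool1d(Module):
    """Collapse (N, C, T) to (N, C) by averaging over all temporal positions."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=2)
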