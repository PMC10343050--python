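"""Layer/module abstractions over the autograd engine.

Conventions: activations are leaky ReLU with negative slope 0.01 and
normalization is group normalization (stateless, so evaluation is
deterministic on a single device), applied after every convolution unless
a layer feeds a sigmoid gate directly.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autograd import Tensor, conv3d, leaky_relu

__all__ = ["Parameter", "Module", "Sequential", "Conv3d", "GroupNorm",
           "LeakyReLU", "count_parameters"]

LEAKY_SLOPE = 0.01


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery."""

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield path, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=path + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{path}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{path}.{i}", item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def count_parameters(module: Module) -> int:
    """Exact count of trainable scalars in a module tree."""
    return int(sum(p.data.size for p in module.parameters()))


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv3d(Module):
    """3D convolution, stride 1, odd kernel, zero "same" padding.

    Weights use Kaiming (He) initialization with the leaky-ReLU gain.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: tuple[int, int, int] | int = (3, 3, 3),
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size,) * 3
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = tuple(kernel_size)
        rng = rng or np.random.default_rng()
        fan_in = in_channels * int(np.prod(kernel_size))
        gain = math.sqrt(2.0 / (1.0 + LEAKY_SLOPE ** 2))
        std = gain / math.sqrt(fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, (out_channels, in_channels, *kernel_size)).astype(dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias)


class GroupNorm(Module):
    """Group normalization with affine parameters over (N, C, D, H, W)."""

    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5,
                 dtype=np.float32):
        if num_channels % num_groups:
            raise ValueError(
                f"channels ({num_channels}) not divisible by groups ({num_groups})")
        self.num_groups = num_groups
        self.num_channels = num_channels
        self.eps = eps
        self.weight = Parameter(np.ones(num_channels, dtype=dtype))
        self.bias = Parameter(np.zeros(num_channels, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        N, C, D, H, W = x.shape
        g = self.num_groups
        xg = x.reshape(N, g, (C // g) * D * H * W)
        mu = xg.mean(axis=2, keepdims=True)
        centered = xg - mu
        var = (centered * centered).mean(axis=2, keepdims=True)
        xhat = centered / (var + self.eps).sqrt()
        y = xhat.reshape(N, C, D, H, W)
        w = self.weight.reshape(1, C, 1, 1, 1)
        b = self.bias.reshape(1, C, 1, 1, 1)
        return y * w + b


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = LEAKY_SLOPE):
        self.negative_slope = negative_slope

    def forward(self, x: Tensor) -> Tensor:
        return leaky_relu(x, self.negative_slope)


def norm_groups_for(channels: int, preferred: int = 8) -> int:
    """Largest divisor of ``channels`` not exceeding ``preferred``."""
    g = min(preferred, channels)
    while channels % g:
        g -= 1
    return g


def conv_norm_act(in_channels: int, out_channels: int, kernel_size,
                  rng: np.random.Generator, norm_groups: int = 8,
                  dtype=np.float32) -> Sequential:
    """Conv (no bias) -> group norm -> leaky ReLU, the standard block unit."""
    return Sequential(
        Conv3d(in_channels, out_channels, kernel_size, bias=False, rng=rng, dtype=dtype),
        GroupNorm(norm_groups_for(out_channels, norm_groups), out_channels, dtype=dtype),
        LeakyReLU(),
    )
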