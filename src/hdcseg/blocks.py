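"""Reusable network blocks.

* Periodic down-shuffling (PDS): a lossless space-to-depth rearrangement
  that halves every spatial dimension and octuples the channel count. It
  is a pure re-indexing — a bijection on tensor elements — so no
  information is discarded before a learned layer sees it.
* Hierarchical decoupled convolution (HDC): a lightweight replacement for
  dense 3x3x3 convolution. Channels are split into groups processed by
  in-plane (main) convolutions with hierarchical inter-group additions,
  then a through-plane (sub) convolution mixes all channels on the
  complementary view.
* Global attention mechanism (GAM): sequential channel-then-spatial
  multiplicative gating, F2 = Mc(F1) * F1 and F3 = Ms(F2) * F2, with a
  per-voxel two-layer MLP for the channel map and two wide-kernel
  convolutions for the spatial map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor, concat, sigmoid
from .nn import Conv3d, GroupNorm, LeakyReLU, Module, Sequential, conv_norm_act, norm_groups_for

__all__ = [
    "PDS_FACTOR", "HDCConfig", "GAMConfig",
    "pds_downshuffle", "pds_inverse", "HDCBlock", "GAM",
]

PDS_FACTOR = 2  # shuffle factor per spatial axis; channel multiplier is 2**3


def _wrap(t) -> tuple[Tensor, bool, bool]:
    """Promote (C,D,H,W) arrays/tensors to batched Tensors."""
    was_array = not isinstance(t, Tensor)
    t = as_tensor(t)
    squeeze = t.ndim == 4
    if squeeze:
        t = t.reshape(1, *t.shape)
    if t.ndim != 5:
        raise ValueError(f"expected a (C,D,H,W) or (N,C,D,H,W) tensor, got {t.shape}")
    return t, squeeze, was_array


def _unwrap(t: Tensor, squeeze: bool, as_array: bool):
    if squeeze:
        t = t.reshape(*t.shape[1:])
    return t.data if as_array else t


def pds_downshuffle(t):
    """Space-to-depth with factor 2: (C, 2d, 2h, 2w) -> (8C, d, h, w).

    Output channel c' encodes (source channel, x-parity, y-parity,
    z-parity) with the source channel varying fastest:
    ``c' = c + C*(px + 2*py + 4*pz)``.
    """
    x, squeeze, arr = _wrap(t)
    N, C, D, H, W = x.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"PDS requires even spatial dims, got {(D, H, W)}")
    d, h, w = D // 2, H // 2, W // 2
    y = x.reshape(N, C, d, 2, h, 2, w, 2)          # (N,C,d,px,h,py,w,pz)
    y = y.transpose((0, 7, 5, 3, 1, 2, 4, 6))      # (N,pz,py,px,C,d,h,w)
    y = y.reshape(N, 8 * C, d, h, w)
    return _unwrap(y, squeeze, arr)


def pds_inverse(t):
    """Inverse of :func:`pds_downshuffle`: (8C, d, h, w) -> (C, 2d, 2h, 2w)."""
    x, squeeze, arr = _wrap(t)
    N, C8, d, h, w = x.shape
    if C8 % 8:
        raise ValueError(f"channel count {C8} not divisible by 8")
    C = C8 // 8
    y = x.reshape(N, 2, 2, 2, C, d, h, w)          # (N,pz,py,px,C,d,h,w)
    y = y.transpose((0, 4, 5, 3, 6, 2, 7, 1))      # (N,C,d,px,h,py,w,pz)
    y = y.reshape(N, C, 2 * d, 2 * h, 2 * w)
    return _unwrap(y, squeeze, arr)


@dataclass
class HDCConfig:
    in_channels: int
    out_channels: int
    groups: int = 4
    main_kernel: int = 3   # in-plane (k, k, 1)
    sub_kernel: int = 3    # through-plane (1, 1, k)

    def __post_init__(self):
        if self.in_channels % self.groups:
            raise ValueError(
                f"in_channels ({self.in_channels}) not divisible by groups ({self.groups})")


@dataclass
class GAMConfig:
    channels: int
    reduction: int = 4
    spatial_kernel: int = 7

    def __post_init__(self):
        if self.reduction < 1 or self.channels % self.reduction:
            raise ValueError(
                f"reduction ({self.reduction}) must divide channels ({self.channels})")
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial kernel must be odd")


class HDCBlock(Module):
    """Hierarchical decoupled convolution unit (spatial shape preserving).

    Group i of the channel-split input receives the output of group i-1
    by element-wise addition before its in-plane main convolution; the
    concatenated group outputs pass through a through-plane
    sub-convolution that mixes all channels. Norm + activation follow
    every convolution.
    """

    def __init__(self, cfg: HDCConfig, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        cpg = cfg.in_channels // cfg.groups
        k = cfg.main_kernel
        self.mains = [
            conv_norm_act(cpg, cpg, (k, k, 1), rng,
                          norm_groups=norm_groups_for(cpg), dtype=dtype)
            for _ in range(cfg.groups)
        ]
        self.sub = conv_norm_act(cfg.in_channels, cfg.out_channels,
                                 (1, 1, cfg.sub_kernel), rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        if x.shape[1] != cfg.in_channels:
            raise ValueError(f"expected {cfg.in_channels} channels, got {x.shape[1]}")
        cpg = cfg.in_channels // cfg.groups
        outs = []
        prev = None
        for i, main in enumerate(self.mains):
            xi = x[:, i * cpg:(i + 1) * cpg]
            if prev is not None:
                xi = xi + prev
            prev = main(xi)
            outs.append(prev)
        return self.sub(concat(outs, axis=1))


class GAM(Module):
    """Global attention: channel gate then spatial gate, both sigmoid-bounded.

    The channel map applies a two-layer MLP (C -> C/r -> C) at every
    voxel — realized as two 1x1x1 convolutions, equivalent to permuting
    channels last and applying the MLP — followed by a sigmoid. The
    spatial map uses two wide-kernel convolutions (C -> C/r -> C).
    Because both gates lie in (0, 1), |output| <= |input| elementwise.
    """

    def __init__(self, cfg: GAMConfig, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        c, cr, k = cfg.channels, cfg.channels // cfg.reduction, cfg.spatial_kernel
        self.mlp = Sequential(
            Conv3d(c, cr, 1, bias=True, rng=rng, dtype=dtype),
            LeakyReLU(),
            Conv3d(cr, c, 1, bias=True, rng=rng, dtype=dtype),
        )
        self.spatial = Sequential(
            Conv3d(c, cr, (k, k, k), bias=False, rng=rng, dtype=dtype),
            GroupNorm(norm_groups_for(cr), cr, dtype=dtype),
            LeakyReLU(),
            Conv3d(cr, c, (k, k, k), bias=True, rng=rng, dtype=dtype),
        )

    def forward(self, f1: Tensor) -> Tensor:
        mc = sigmoid(self.mlp(f1))
        f2 = mc * f1
        ms = sigmoid(self.spatial(f2))
        return ms * f2
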