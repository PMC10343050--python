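"""Encoder-decoder segmentation network assembly.

The encoder opens with a plain 3x3x3 convolution, then three coding units
of [PDS -> 1x1x1 channel-reducing convolution -> HDC block]. PDS does all
spatial downsampling losslessly (channels octuple, a 1x1x1 convolution
immediately reduces them to the stage width). The decoder mirrors the
encoder with trilinear upsampling; the two shallow skip connections are
plain concatenation, while the deepest skip hosts the feature interaction
module (or a GAM, or nothing, depending on the ablation arm). The head is
a 1x1x1 convolution to 4 classes followed by a voxelwise softmax.

The shipped default stage widths are pinned so that exact parameter
enumeration gives 1.20 M for the full model and 0.29 M for the baseline.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .autograd import Tensor, as_tensor, concat, softmax, upsample_trilinear2x
from .blocks import GAM, GAMConfig, HDCBlock, HDCConfig, pds_downshuffle
from .interaction import FeatureInteraction, InteractionConfig
from .nn import Module, count_parameters, conv_norm_act, Conv3d

__all__ = ["NetworkConfig", "SegNet", "build", "count_parameters",
           "predict_case", "ARCH_PRESETS", "arch_config"]

#: class index <-> BraTS label correspondence used by the softmax head
CLASS_LABELS = (0, 1, 2, 4)

DEFAULT_STAGE_WIDTHS = (16, 32, 64, 128)


@dataclass
class NetworkConfig:
    in_channels: int = 4
    n_classes: int = 4
    stage_widths: tuple[int, int, int, int] = DEFAULT_STAGE_WIDTHS
    n_downsamplings: int = 3
    use_interaction: bool = True
    use_gam: bool = True
    hdc_groups: int = 4
    hdc_main_kernel: int = 3
    hdc_sub_kernel: int = 3
    gam_reduction: int = 4
    gam_spatial_kernel: int = 7
    interaction_nodes: int = 16
    interaction_node_channels: int = 96
    interaction_crf_iters: int = 2
    interaction_context_kernel: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_downsamplings != 3:
            raise ValueError("the architecture is defined for exactly 3 downsamplings")
        if len(self.stage_widths) != self.n_downsamplings + 1:
            raise ValueError("stage_widths must list one width per stage (4)")
        if any(w <= 0 for w in self.stage_widths):
            raise ValueError("stage widths must be positive")
        if any(w % self.hdc_groups for w in self.stage_widths):
            raise ValueError("stage widths must be divisible by the HDC group count")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_widths"] = list(self.stage_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["stage_widths"] = tuple(d["stage_widths"])
        return cls(**d)


ARCH_PRESETS = {
    "baseline": dict(use_interaction=False, use_gam=False),
    "cga": dict(use_interaction=True, use_gam=False),
    "gam": dict(use_interaction=False, use_gam=True),
    "full": dict(use_interaction=True, use_gam=True),
}


def arch_config(arch: str = "full", **overrides) -> NetworkConfig:
    """Config for one of the four ablation arms: baseline/cga/gam/full."""
    if arch not in ARCH_PRESETS:
        raise ValueError(f"unknown arch {arch!r}; choose from {sorted(ARCH_PRESETS)}")
    return NetworkConfig(**{**ARCH_PRESETS[arch], **overrides})


class SegNet(Module):
    """The assembled segmentation network (see module docstring)."""

    def __init__(self, cfg: NetworkConfig, dtype=np.float32):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        w = cfg.stage_widths

        def hdc(cin, cout):
            return HDCBlock(HDCConfig(cin, cout, groups=cfg.hdc_groups,
                                      main_kernel=cfg.hdc_main_kernel,
                                      sub_kernel=cfg.hdc_sub_kernel),
                            rng=rng, dtype=dtype)

        # encoder
        self.enc0 = conv_norm_act(cfg.in_channels, w[0], (3, 3, 3), rng, dtype=dtype)
        self.enc_reduce = []
        self.enc_hdc = []
        for i in range(1, 4):
            self.enc_reduce.append(
                conv_norm_act(8 * w[i - 1], w[i], (1, 1, 1), rng, dtype=dtype))
            self.enc_hdc.append(hdc(w[i], w[i]))

        # deepest skip (level 2, feature width w[2])
        self.interaction = None
        self.skip_gam = None
        if cfg.use_interaction:
            gam_cfg = (GAMConfig(w[2], cfg.gam_reduction, cfg.gam_spatial_kernel)
                       if cfg.use_gam else None)
            self.interaction = FeatureInteraction(
                InteractionConfig(channels=w[2], nodes=cfg.interaction_nodes,
                                  node_channels=cfg.interaction_node_channels,
                                  crf_iters=cfg.interaction_crf_iters,
                                  context_kernel=cfg.interaction_context_kernel,
                                  gam=gam_cfg),
                rng=rng, dtype=dtype)
        elif cfg.use_gam:
            self.skip_gam = GAM(GAMConfig(w[2], cfg.gam_reduction,
                                          cfg.gam_spatial_kernel), rng=rng, dtype=dtype)

        # decoder: reduce channels at low res, upsample, concat skip, HDC
        self.dec_reduce = []
        self.dec_hdc = []
        for i in (2, 1, 0):
            self.dec_reduce.append(
                conv_norm_act(w[i + 1], w[i], (1, 1, 1), rng, dtype=dtype))
            cat_width = 2 * w[i]
            if i == 2 and cfg.use_interaction:
                cat_width = 3 * w[i]  # [X_F, X, decoder]
            self.dec_hdc.append(hdc(cat_width, w[i]))

        self.head = Conv3d(w[0], cfg.n_classes, 1, bias=True, rng=rng, dtype=dtype)

    # -- forward ---------------------------------------------------------
    def forward(self, x) -> Tensor:
        squeeze = False
        x = as_tensor(x) if isinstance(x, Tensor) else Tensor(np.asarray(x))
        if x.ndim == 4:
            x = x.reshape(1, *x.shape)
            squeeze = True
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} input channels")
        if any(s % 2 ** self.cfg.n_downsamplings for s in x.shape[2:]):
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be divisible by "
                f"{2 ** self.cfg.n_downsamplings}")

        skips = []
        h = self.enc0(x)
        for reduce_conv, hdc_block in zip(self.enc_reduce, self.enc_hdc):
            skips.append(h)
            h = hdc_block(reduce_conv(pds_downshuffle(h)))

        for level, (reduce_conv, hdc_block) in zip((2, 1, 0),
                                                   zip(self.dec_reduce, self.dec_hdc)):
            up = upsample_trilinear2x(reduce_conv(h))
            skip = skips[level]
            if level == 2 and self.interaction is not None:
                skip = self.interaction(skip)      # concat[X_F, X], 2*w2 channels
            elif level == 2 and self.skip_gam is not None:
                skip = self.skip_gam(skip)
            h = hdc_block(concat([skip, up], axis=1))

        probs = softmax(self.head(h), axis=1)
        if squeeze:
            probs = probs.reshape(*probs.shape[1:])
        return probs


def build(cfg: NetworkConfig, dtype=np.float32) -> SegNet:
    """Build the network described by ``cfg`` (seeded weight init)."""
    return SegNet(cfg, dtype=dtype)


def pad_depth(data: np.ndarray, multiple: int = 8) -> tuple[np.ndarray, int]:
    """Zero-pad the last (depth) axis up to the next multiple; return pad size."""
    d = data.shape[-1]
    target = -(-d // multiple) * multiple
    pad = target - d
    if pad == 0:
        return data, 0
    width = [(0, 0)] * (data.ndim - 1) + [(0, pad)]
    return np.pad(data, width), pad


def predict_case(net: SegNet, vol) -> np.ndarray:
    """Segment one (4, X, Y, Z) volume into BraTS labels {0, 1, 2, 4}.

    Pads the depth axis with zeros to a network-divisible size (155 -> 160
    for BraTS geometry), runs the forward pass, takes the voxelwise argmax
    and maps class indices back to labels, then crops the padding off.
    """
    from .io import MultimodalVolume  # local import avoids a cycle via losses
    data = vol.data if isinstance(vol, MultimodalVolume) else np.asarray(vol)
    if data.ndim != 4:
        raise ValueError("expected a (modalities, X, Y, Z) array")
    mult = 2 ** net.cfg.n_downsamplings
    padded, pad = pad_depth(data, multiple=mult)
    if any(s % mult for s in padded.shape[1:]):
        raise ValueError(f"in-plane dims {padded.shape[1:3]} must be divisible by {mult}")
    probs = net.forward(padded[None]).data[0]
    classes = probs.argmax(axis=0)
    labels = np.asarray(CLASS_LABELS, dtype=np.int16)[classes]
    if pad:
        labels = labels[:, :, :-pad]
    return labels
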