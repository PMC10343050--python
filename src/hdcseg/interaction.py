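"""Feature interaction module replacing the deepest skip connection.

The encoder feature X is processed along two branches and fused:

* graph branch — X is projected into an interaction space of K node
  features via learned soft spatial assignments (adaptive sampling),
  a Laplacian-smoothing graph update X_G = sigmoid((I - A)·X_P·W) mixes
  information across nodes, and the node features are re-projected back
  to the voxel grid;
* context branch — a convolution produces X_C, optionally refined by the
  global attention mechanism into X_A;
* CGA-CRF fusion — a gated mean-field-style recursion combines the graph
  context X_G with the attended visual feature X_A into X_F:
  H_0 = X_A;  H_t = G_t * M_t + (1 - G_t) * H_{t-1}  with
  G_t = sigmoid(conv([H_{t-1}, X_G])) and M_t = conv(X_G).
  With zero iterations X_F equals X_A exactly.

The module's output concatenates X_F with the untouched skip feature X so
the decoder consumes both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor, concat, matmul, sigmoid, softmax
from .blocks import GAM, GAMConfig
from .nn import Conv3d, Module, Parameter, conv_norm_act

__all__ = [
    "InteractionConfig", "Projector", "GraphReasoner", "reproject",
    "ContextBranch", "CGACRFFusion", "FeatureInteraction",
]


@dataclass
class InteractionConfig:
    channels: int                 # channels of the skip feature X
    nodes: int = 16               # K, interaction-space size
    node_channels: int = 96       # C_node
    crf_iters: int = 2            # T
    context_kernel: int = 3       # kernel of the X -> X_C convolution
    gate_kernel: tuple[int, int, int] = (1, 1, 1)  # CRF gate convolution
    gam: GAMConfig | None = None  # attention in the context branch (None = off)

    def __post_init__(self):
        if self.nodes < 1:
            raise ValueError("need at least one interaction node")
        if self.crf_iters < 0:
            raise ValueError("crf_iters must be >= 0")


class Projector(Module):
    """Adaptive-sampling projection of a feature map into K node features.

    A 1x1x1 convolution produces one logit map per node; a softmax over
    space turns each into an assignment density (weights over voxels that
    sum to one), concentrating samples where the logits — hence the local
    image content — demand. A second 1x1x1 convolution reduces channels
    to the node width, and each node feature is the assignment-weighted
    sum of the reduced feature over space.
    """

    def __init__(self, channels: int, nodes: int, node_channels: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        if nodes < 1:
            raise ValueError("nodes must be >= 1")
        self.nodes = nodes
        self.node_channels = node_channels
        self.assign = Conv3d(channels, nodes, 1, bias=True, rng=rng, dtype=dtype)
        self.reduce = Conv3d(channels, node_channels, 1, bias=False, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        N, _, D, H, W = x.shape
        logits = self.assign(x).reshape(N, self.nodes, D * H * W)
        a = softmax(logits, axis=2)                      # (N, K, V), rows sum to 1
        xt = self.reduce(x).reshape(N, self.node_channels, D * H * W)
        xp = matmul(a, xt.transpose((0, 2, 1)))          # (N, K, C_node)
        return xp, a


class GraphReasoner(Module):
    """Interaction graph reasoning: X_G = sigmoid((I - A)·X_P·W).

    The adjacency A (K x K) and channel weights W (C_node x C_node) are
    free parameters, the 1x1-convolution realization of the graph update;
    (I - A) is the Laplacian-smoothing form that spreads node features
    across the graph. A initializes at zero so the first update is a pure
    channel mix of each node with itself.
    """

    def __init__(self, nodes: int, node_channels: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.nodes = nodes
        self.adjacency = Parameter(np.zeros((nodes, nodes), dtype=dtype))
        std = 1.0 / np.sqrt(node_channels)
        self.weight = Parameter(
            rng.normal(0.0, std, (node_channels, node_channels)).astype(dtype))

    def forward(self, xp: Tensor) -> Tensor:
        if xp.shape[-2] != self.nodes:
            raise ValueError(f"expected {self.nodes} nodes, got {xp.shape[-2]}")
        if xp.shape[-1] != self.weight.shape[0]:
            raise ValueError(
                f"node channels {xp.shape[-1]} do not match weight {self.weight.shape}")
        eye = as_tensor(np.eye(self.nodes, dtype=xp.dtype))
        smoothed = matmul(eye - self.adjacency, xp)
        return sigmoid(matmul(smoothed, self.weight))


def reproject(xg: Tensor, assignments: Tensor, spatial_shape: tuple[int, int, int]) -> Tensor:
    """Map node features back to the voxel grid.

    At each voxel the per-node assignment weights (which were normalized
    over *space*) are renormalized over *nodes*, and the spatial feature
    is the weight-averaged node feature:
    X_G(v) = sum_k a_k(v) xg[k] / sum_k a_k(v).
    """
    D, H, W = spatial_shape
    if assignments.shape[-1] != D * H * W:
        raise ValueError("assignment maps do not match the target spatial shape")
    denom = assignments.sum(axis=1, keepdims=True)       # (N, 1, V)
    abar = assignments / denom
    xs = matmul(abar.transpose((0, 2, 1)), xg)           # (N, V, C_node)
    N, _, c = xs.shape
    return xs.transpose((0, 2, 1)).reshape(N, c, D, H, W)


class ContextBranch(Module):
    """Convolutional context branch: X_C = conv(X); X_A = GAM(X_C) if enabled."""

    def __init__(self, channels: int, kernel: int = 3, gam_cfg: GAMConfig | None = None,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.conv = conv_norm_act(channels, channels, (kernel,) * 3, rng, dtype=dtype)
        self.gam = GAM(gam_cfg, rng=rng, dtype=dtype) if gam_cfg is not None else None

    def forward(self, x: Tensor) -> Tensor:
        xc = self.conv(x)
        return self.gam(xc) if self.gam is not None else xc


class CGACRFFusion(Module):
    """Context-guided attentive CRF fusion of X_G (graph) and X_A (visual).

    A gated mean-field-style recursion with convolutions shared across
    iterations; T = 0 returns X_A unchanged, and a gate saturated at zero
    does the same for any T.
    """

    def __init__(self, channels: int, iters: int = 2,
                 gate_kernel: tuple[int, int, int] = (3, 3, 1),
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.iters = iters
        self.gate = Conv3d(2 * channels, channels, gate_kernel, bias=True,
                           rng=rng, dtype=dtype)
        self.message = Conv3d(channels, channels, 1, bias=True, rng=rng, dtype=dtype)

    def forward(self, xg: Tensor, xa: Tensor, iters: int | None = None) -> Tensor:
        if xg.shape != xa.shape:
            raise ValueError(f"X_G shape {xg.shape} != X_A shape {xa.shape}")
        T = self.iters if iters is None else iters
        h = xa
        for _ in range(T):
            g = sigmoid(self.gate(concat([h, xg], axis=1)))
            m = self.message(xg)
            h = g * m + (1.0 - g) * h
        return h


class FeatureInteraction(Module):
    """The full interaction module hosted at the deepest skip connection."""

    def __init__(self, cfg: InteractionConfig,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        c = cfg.channels
        self.projector = Projector(c, cfg.nodes, cfg.node_channels, rng=rng, dtype=dtype)
        self.reasoner = GraphReasoner(cfg.nodes, cfg.node_channels, rng=rng, dtype=dtype)
        # embed the re-projected node field back to the skip width
        self.embed = conv_norm_act(cfg.node_channels, c, (1, 1, 1), rng, dtype=dtype)
        self.context = ContextBranch(c, kernel=cfg.context_kernel, gam_cfg=cfg.gam,
                                     rng=rng, dtype=dtype)
        self.fuse = CGACRFFusion(c, iters=cfg.crf_iters, gate_kernel=cfg.gate_kernel,
                                 rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        xp, a = self.projector(x)
        xg_nodes = self.reasoner(xp)
        xg = self.embed(reproject(xg_nodes, a, x.shape[2:]))
        xa = self.context(x)
        xf = self.fuse(xg, xa)
        return concat([xf, x], axis=1)
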