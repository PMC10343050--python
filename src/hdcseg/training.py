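"""Training loop: Adam + polynomial LR decay on the generalized Dice loss.

Defaults follow the segmentation recipe the network was designed around:
Adam with initial learning rate 1e-4 decaying as (1 - step/total)^0.9,
L2 weight decay 1e-5, random 128^3 patches with flips / small rotations /
intensity jitter. A single global seed fixes weight initialization, case
order, patch positions and augmentation draws, so two runs with equal
seeds produce identical loss curves on one device.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass


import numpy as np

from .io import LabelVolume, MultimodalVolume, augment as augment_fn, crop_patch, normalize
from .losses import generalized_dice_loss, one_hot_labels
from .network import NetworkConfig, SegNet, build


__all__ = ["TrainConfig", "Adam", "polynomial_lr", "train",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    steps: int = 200
    batch_size: int = 8
    lr_init: float = 1e-4
    lr_power: float = 0.9
    weight_decay: float = 1e-5
    patch_size: tuple[int, int, int] = (128, 128, 128)
    augment: bool = True
    foreground_prob: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.steps < 1 or self.batch_size < 1:
            raise ValueError("steps and batch_size must be positive")
        if self.lr_init <= 0 or self.lr_power <= 0:
            raise ValueError("learning rate and schedule exponent must be positive")


def polynomial_lr(step: int, total_steps: int, lr_init: float, power: float = 0.9) -> float:
    """lr_init * (1 - step/total)^power; equals lr_init at step 0, ~0 at the end."""
    frac = min(step, total_steps) / total_steps
    return lr_init * (1.0 - frac) ** power


class Adam:
    """Adam with classic (non-decoupled) L2 weight decay."""

    def __init__(self, params, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)


def _prepare_cases(cases) -> list[tuple[MultimodalVolume, LabelVolume]]:
    prepared = []
    for vol, lab in cases:
        if lab is None:
            raise ValueError("training requires labelled cases")
        prepared.append((normalize(vol), lab))
    return prepared


def train(net: SegNet, cases, cfg: TrainConfig, log_path=None) -> list[dict]:
    """Optimize ``net`` on (volume, labels) pairs; returns the step log.

    Each step draws ``batch_size`` cases with replacement, crops a random
    (foreground-biased) patch from each, optionally augments, and takes
    one Adam step on the generalized Dice loss. Log entries are
    ``{"step", "lr", "loss"}``, also written as JSON lines to ``log_path``.
    """
    if not cases:
        raise ValueError("no training cases provided")
    mult = 2 ** net.cfg.n_downsamplings
    if any(s % mult for s in cfg.patch_size):
        raise ValueError(f"patch size {cfg.patch_size} not divisible by {mult}")
    prepared = _prepare_cases(cases)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.parameters(), weight_decay=cfg.weight_decay)
    history = []
    log_file = open(log_path, "w") if log_path else None
    try:
        for step in range(cfg.steps):
            xs, ts = [], []
            for _ in range(cfg.batch_size):
                vol, lab = prepared[rng.integers(len(prepared))]
                pvol, plab = crop_patch(vol, lab, cfg.patch_size, rng,
                                        foreground_prob=cfg.foreground_prob)
                if cfg.augment:
                    pvol, plab = augment_fn(pvol, plab, rng)
                xs.append(pvol.data)
                ts.append(one_hot_labels(plab.labels))
            x = np.stack(xs)
            t = np.stack(ts)
            net.zero_grad()
            probs = net.forward(x)
            loss = generalized_dice_loss(probs, t)
            loss.backward()
            lr = polynomial_lr(step, cfg.steps, cfg.lr_init, cfg.lr_power)
            opt.step(lr)
            entry = {"step": step, "lr": lr, "loss": float(loss.item())}
            history.append(entry)
            if log_file:
                log_file.write(json.dumps(entry) + "\n")
    finally:
        if log_file:
            log_file.close()
    return history


def save_checkpoint(path, net: SegNet, train_cfg: TrainConfig | None = None) -> None:
    """Store network config + weights (+ training config) in one .npz file."""
    payload = {f"param/{k}": v for k, v in net.state_dict().items()}
    meta = {"network": net.cfg.to_dict()}
    if train_cfg is not None:
        meta["train"] = asdict(train_cfg)
    payload["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple[SegNet, dict]:
    """Rebuild the network stored by :func:`save_checkpoint`."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    net = build(NetworkConfig.from_dict(meta["network"]))
    net.load_state_dict(state)
    return net, meta
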