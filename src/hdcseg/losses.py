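"""Generalized Dice loss (GDL) for class-imbalanced segmentation.

GDL = 1 - 2 * (Σ_l ω_l Σ_n p_ln t_ln) / (Σ_l ω_l Σ_n (p_ln + t_ln))

with per-class weights ω_l = 1 / (Σ_n g_ln)^2 computed from the one-hot
ground truth, so rare classes (enhancing core) weigh as much as abundant
ones (background). When a class is absent (Σ g = 0) its weight is clamped
to a large finite cap so the loss stays finite.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor
from .network import CLASS_LABELS

__all__ = ["one_hot_labels", "generalized_dice_loss", "WEIGHT_CAP"]

WEIGHT_CAP = 1e8


def one_hot_labels(labels: np.ndarray,
                   class_labels: tuple[int, ...] = CLASS_LABELS) -> np.ndarray:
    """One-hot encode a label volume: (X, Y, Z) -> (len(classes), X, Y, Z)."""
    labels = np.asarray(labels)
    return np.stack([(labels == c).astype(np.float32) for c in class_labels])


def generalized_dice_loss(p, t) -> Tensor:
    """GDL between predicted probabilities ``p`` and one-hot truth ``t``.

    ``p``: Tensor/array (C, ...) or (N, C, ...) of probabilities in [0, 1];
    ``t``: array of the same shape, one-hot over the class axis. The result
    is a scalar Tensor in [0, 1], differentiable in ``p``.
    """
    p = as_tensor(p)
    t = np.asarray(t, dtype=p.dtype)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs t {t.shape}")
    class_axis = 0 if p.ndim == 4 else 1
    sums = t.sum(axis=class_axis)
    if not np.allclose(sums, 1.0, atol=1e-5) or not np.all((t == 0) | (t == 1)):
        raise ValueError("t must be one-hot over the class axis")
    reduce_axes = tuple(a for a in range(p.ndim) if a != class_axis)

    class_volumes = t.sum(axis=reduce_axes)
    with np.errstate(divide="ignore"):
        w = 1.0 / np.square(class_volumes)
    w = np.minimum(w, WEIGHT_CAP)

    intersect = (p * t).sum(axis=reduce_axes)          # Σ_n p t, per class
    total = p.sum(axis=reduce_axes) + class_volumes    # Σ_n (p + t), per class
    num = (intersect * w).sum()
    den = (total * w).sum()
    return 1.0 - 2.0 * num / den
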