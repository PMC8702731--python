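"""Class-imbalance-aware training objective.

The trigeminal nerve occupies a vanishing fraction of the working volume
(it appears in roughly 3 axial slices), so an unweighted objective lets the
network ignore it. Training therefore minimizes

    L = alpha * L_wce + (1 - alpha) * L_dice,   alpha = 0.5,

where L_wce is a per-voxel cross-entropy with class weights
(background, brainstem, cerebrovasculature, trigeminal nerve) =
(1, 5, 20, 300), and L_dice is the soft multi-class Dice loss with a
Laplace smoothing term epsilon = 1:

    L_dice = 1 - (1/C) * sum_c (2 sum_v p_c g_c + eps) /
                               (sum_v p_c^2 + sum_v g_c^2 + eps).

A literal variant squaring the Dice numerator terms is available behind a
flag for comparison; it is not zero-minimized at perfect soft predictions
and is not used for training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .volume import LabelVolume, NUM_CLASSES, one_hot

__all__ = ["LossConfig", "weighted_ce", "dice_loss", "combined_loss"]


@dataclass
class LossConfig:
    alpha: float = 0.5
    class_weights: tuple[float, ...] = (1.0, 5.0, 20.0, 300.0)
    epsilon: float = 1.0
    num_classes: int = NUM_CLASSES
    squared_numerator: bool = False   # literal printed Dice variant
    aux_coarse_weight: float = 0.0    # optional auxiliary loss on the coarse stage

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if len(self.class_weights) != self.num_classes:
            raise ValueError("need one class weight per class")
        if any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _prep(probs, target, cfg: LossConfig) -> tuple[Tensor, np.ndarray]:
    """Coerce inputs to a channels-last probability Tensor and one-hot target."""
    if not isinstance(probs, Tensor):
        probs = Tensor(np.asarray(probs, dtype=np.float64))
    if isinstance(target, LabelVolume):
        target = target.values
    target = np.asarray(target)
    if probs.shape[:-1] != target.shape:
        raise ValueError(
            f"probability grid {probs.shape} does not match target {target.shape}"
        )
    if probs.shape[-1] != cfg.num_classes:
        raise ValueError(f"expected {cfg.num_classes} channels, got {probs.shape[-1]}")
    sums = probs.data.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-3):
        raise ValueError("probabilities are not normalized per voxel")
    return probs, one_hot(target, cfg.num_classes).astype(probs.data.dtype)


def weighted_ce(probs, target, cfg: LossConfig | None = None) -> Tensor:
    """Weighted cross-entropy, averaged over voxels.

    Per voxel the contribution is ``-w_c * log p_c`` for the true class c;
    the log is clamped for numerical safety.
    """
    cfg = cfg or LossConfig()
    probs, g = _prep(probs, target, cfg)
    w = np.asarray(cfg.class_weights, dtype=probs.data.dtype)
    weighted_onehot = g * w  # (..., C)
    nvox = int(np.prod(g.shape[:-1]))
    picked = nn.tensor_sum(nn.log(probs) * weighted_onehot)
    return picked * (-1.0 / nvox)


def dice_loss(probs, target, cfg: LossConfig | None = None) -> Tensor:
    """Soft multi-class Dice loss with Laplace smoothing; value in [0, 1)."""
    cfg = cfg or LossConfig()
    probs, g = _prep(probs, target, cfg)
    axes = tuple(range(probs.data.ndim - 1))
    eps = cfg.epsilon
    if cfg.squared_numerator:
        inter = nn.tensor_sum(probs * probs * (g * g), axis=axes)
    else:
        inter = nn.tensor_sum(probs * g, axis=axes)
    psq = nn.tensor_sum(probs * probs, axis=axes)
    gsq = Tensor((g * g).sum(axis=axes))
    ratio = (inter * 2.0 + eps) * nn.power(psq + gsq + eps, -1.0)
    return 1.0 - nn.tensor_mean(ratio)


def combined_loss(
    coarse_logits: Tensor | None,
    refined_logits: Tensor | None,
    target,
    cfg: LossConfig | None = None,
) -> Tensor:
    """L = alpha * L_wce + (1 - alpha) * L_dice on the final-stage logits.

    When both stages are present the loss applies to the refined output;
    ``aux_coarse_weight`` optionally adds the same objective on the coarse
    stage (off by default).
    """
    cfg = cfg or LossConfig()
    final = refined_logits if refined_logits is not None else coarse_logits
    if final is None:
        raise ValueError("need at least one stage's logits")

    def stage_loss(logits: Tensor) -> Tensor:
        probs = nn.softmax(logits, axis=-1)
        return cfg.alpha * weighted_ce(probs, target, cfg) \
            + (1.0 - cfg.alpha) * dice_loss(probs, target, cfg)

    loss = stage_loss(final)
    if cfg.aux_coarse_weight > 0 and refined_logits is not None and coarse_logits is not None:
        loss = loss + cfg.aux_coarse_weight * stage_loss(coarse_logits)
    return loss
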