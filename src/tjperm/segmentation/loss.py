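"""Soft Dice coefficient: the segmentation training objective.

Junction pixels are vastly outnumbered by non-junction pixels, so pixel-wise
cross entropy would be dominated by the background class; the Dice overlap
between the predicted probability map and the binary label is insensitive to
that imbalance. The training loss is ``1 - soft_dice``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["soft_dice", "soft_dice_loss_grad"]


def soft_dice(prediction: np.ndarray, target: np.ndarray, smoothing: float = 1.0) -> float:
    """Soft Dice overlap ``(2*sum(p*g) + eps) / (sum(p) + sum(g) + eps)``.

    ``prediction`` is a probability map in [0, 1]; ``target`` a binary mask
    of the same shape. Returns a value in [0, 1]; 1 means perfect overlap.
    """
    prediction = np.asarray(prediction, dtype=float)
    target = np.asarray(target, dtype=float)
    if prediction.shape != target.shape:
        raise ValueError(
            f"shape mismatch: prediction {prediction.shape} vs target {target.shape}"
        )
    num = 2.0 * float((prediction * target).sum()) + smoothing
    den = float(prediction.sum()) + float(target.sum()) + smoothing
    return num / den


def soft_dice_loss_grad(prediction: np.ndarray, target: np.ndarray,
                        smoothing: float = 1.0):
    """Loss ``1 - soft_dice`` and its gradient w.r.t. the prediction."""
    prediction = np.asarray(prediction, dtype=float)
    target = np.asarray(target, dtype=float)
    num = 2.0 * (prediction * target).sum() + smoothing
    den = prediction.sum() + target.sum() + smoothing
    loss = 1.0 - num / den
    grad = -(2.0 * target * den - num) / den**2
    return float(loss), grad
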