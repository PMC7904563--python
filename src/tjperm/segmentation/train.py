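"""Training loop, loss bookkeeping and checkpoint selection.

Training minimises ``1 - soft_dice`` with Adam. The held-out loss curve is
evaluated every ``eval_interval`` updates on a fixed set of crops from the
held-out pairs, and the checkpoint whose *smoothed* held-out loss is lowest
is selected — the curve is noisy, and on small training sets it shows the
classic overfitting signature (held-out minimum before the final update
while the train loss keeps falling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .loss import soft_dice_loss_grad
from .network import Adam, RefineNet, SegmenterConfig

__all__ = ["TrainState", "TrainingDiverged", "train_segmenter", "select_checkpoint"]

Pair = Tuple[np.ndarray, np.ndarray]


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class TrainState:
    """Loss curves and per-evaluation checkpoints of one training run."""

    train_loss: List[float] = field(default_factory=list)       # one per update
    eval_updates: List[int] = field(default_factory=list)
    heldout_loss: List[float] = field(default_factory=list)     # one per eval
    checkpoints: Dict[int, list] = field(default_factory=dict)  # update -> params
    selected_update: Optional[int] = None

    @property
    def n_updates(self) -> int:
        return len(self.train_loss)


def _crop(image: np.ndarray, size: int, r0: int, c0: int) -> np.ndarray:
    return image[r0 : r0 + size, c0 : c0 + size]


def _random_crop_pair(pair: Pair, size: int, rng: np.random.Generator) -> Pair:
    img, lab = pair
    if img.shape[0] == size and img.shape[1] == size:
        return img, lab
    r0 = int(rng.integers(0, img.shape[0] - size + 1))
    c0 = int(rng.integers(0, img.shape[1] - size + 1))
    return _crop(img, size, r0, c0), _crop(lab, size, r0, c0)


def _heldout_crops(pairs: Sequence[Pair], size: int, max_crops: int = 16) -> List[Pair]:
    """Deterministic centre crops of the held-out pairs."""
    out = []
    for img, lab in pairs:
        r0 = (img.shape[0] - size) // 2
        c0 = (img.shape[1] - size) // 2
        out.append((_crop(img, size, r0, c0), _crop(lab, size, r0, c0)))
        if len(out) >= max_crops:
            break
    return out


def _batch_loss_grad(model: RefineNet, batch: List[Pair], smoothing: float,
                     train: bool) -> float:
    imgs = np.stack([p[0] for p in batch]).astype(float)
    labs = np.stack([p[1] for p in batch]).astype(float)
    pred = model.forward(imgs, cache=train)
    loss, dp = soft_dice_loss_grad(pred, labs, smoothing)
    if train:
        model.zero_grad()
        model.backward(dp)
    return loss


def train_segmenter(
    train_pairs: Sequence[Pair],
    heldout_pairs: Sequence[Pair],
    config: SegmenterConfig,
) -> Tuple[RefineNet, TrainState]:
    """Train the segmentation network; returns the selected-checkpoint model.

    ``train_pairs`` / ``heldout_pairs`` are sequences of
    ``(image, binary_mask)`` with images in [0, 1]. Pairs larger than
    ``config.input_size_px`` are randomly (train) or centre (held-out)
    cropped. Fully seeded: identical inputs and config give bit-identical
    loss curves.
    """
    if not len(train_pairs) or not len(heldout_pairs):
        raise ValueError("training and held-out sets must be nonempty")
    for _, lab in list(train_pairs) + list(heldout_pairs):
        uniq = np.unique(lab)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("label masks must be binary")

    rng = np.random.default_rng(config.rng_seed)
    model = RefineNet(config)
    optim = Adam(model.parameters(), config.learning_rate, config.weight_decay)
    state = TrainState()
    heldout = _heldout_crops(heldout_pairs, config.input_size_px)

    updates_per_epoch = max(len(train_pairs) // config.batch_size, 1)
    total_updates = config.n_epochs * updates_per_epoch
    if config.max_updates is not None:
        total_updates = min(total_updates, config.max_updates)

    update = 0
    while update < total_updates:
        order = rng.permutation(len(train_pairs))
        for start in range(0, updates_per_epoch * config.batch_size, config.batch_size):
            if update >= total_updates:
                break
            idx = order[start % len(order) : start % len(order) + config.batch_size]
            if len(idx) < config.batch_size:
                extra = rng.integers(0, len(train_pairs), config.batch_size - len(idx))
                idx = np.concatenate([idx, extra])
            batch = [
                _random_crop_pair(train_pairs[i], config.input_size_px, rng) for i in idx
            ]
            loss = _batch_loss_grad(model, batch, config.dice_smoothing, train=True)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"train loss became {loss} at update {update}; "
                    "reduce the learning rate"
                )
            optim.step(model.gradients())
            state.train_loss.append(loss)
            update += 1
            if update % config.eval_interval == 0 or update == total_updates:
                h_loss = np.mean(
                    [
                        _batch_loss_grad(model, [pair], config.dice_smoothing, train=False)
                        for pair in heldout
                    ]
                )
                state.eval_updates.append(update)
                state.heldout_loss.append(float(h_loss))
                state.checkpoints[update] = model.get_state()

    state.selected_update = select_checkpoint(state)
    model.set_state(state.checkpoints[state.selected_update])
    return model, state


def select_checkpoint(state: TrainState, smooth_window: int = 5) -> int:
    """Update index minimising the smoothed held-out loss (ties: earliest).

    Smoothing is a centred moving average over ``smooth_window`` evaluation
    points, truncated at the curve ends; ``smooth_window=1`` disables it.
    """
    if not state.heldout_loss:
        raise ValueError("held-out loss curve is empty")
    losses = np.asarray(state.heldout_loss, dtype=float)
    smooth_window = min(smooth_window, len(losses))
    if smooth_window > 1:
        kernel = np.ones(smooth_window)
        smoothed = np.convolve(losses, kernel, mode="same") / np.convolve(
            np.ones_like(losses), kernel, mode="same"
        )
    else:
        smoothed = losses
    return int(state.eval_updates[int(np.argmin(smoothed))])
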