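"""Inference: probability maps for images of any size via tiled prediction."""

from __future__ import annotations

import numpy as np

from .network import RefineNet

__all__ = ["predict"]


def _pad_to_multiple(img: np.ndarray, multiple: int):
    h, w = img.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
    return img, (h, w)


def _forward_whole(model: RefineNet, img: np.ndarray) -> np.ndarray:
    multiple = 2 ** (model.config.n_levels - 1)
    padded, (h, w) = _pad_to_multiple(img, multiple)
    out = model.forward(padded[None], cache=False)[0]
    return out[:h, :w]


def predict(model: RefineNet, border_image: np.ndarray,
            tile: int | None = None, overlap: int = 16) -> np.ndarray:
    """Per-pixel junction probability map for a single-channel image.

    Images larger than ``tile`` (default: the model's training input size)
    are processed in overlapping tiles blended with a tapered weight window,
    so tile seams do not appear in the output.
    """
    img = np.asarray(border_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if tile is None:
        tile = model.config.input_size_px
    h, w = img.shape
    if h <= tile and w <= tile:
        return _forward_whole(model, img)

    step = tile - overlap
    acc = np.zeros((h, w))
    wacc = np.zeros((h, w))
    window = _taper_window(tile)
    for r0 in _tile_starts(h, tile, step):
        for c0 in _tile_starts(w, tile, step):
            patch = img[r0 : r0 + tile, c0 : c0 + tile]
            pred = _forward_whole(model, patch)
            win = window[: patch.shape[0], : patch.shape[1]]
            acc[r0 : r0 + tile, c0 : c0 + tile] += pred * win
            wacc[r0 : r0 + tile, c0 : c0 + tile] += win
    return acc / wacc


def _tile_starts(extent: int, tile: int, step: int):
    starts = list(range(0, max(extent - tile, 0) + 1, step))
    if starts[-1] + tile < extent:
        starts.append(extent - tile)
    return starts


def _taper_window(tile: int) -> np.ndarray:
    # raised-cosine taper, strictly positive so the weight sum never vanishes
    t = np.linspace(0, np.pi, tile)
    prof = 0.05 + 0.95 * np.sin(t) ** 2
    prof[tile // 4 : 3 * tile // 4] = prof.max()
    return np.outer(prof, prof)
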