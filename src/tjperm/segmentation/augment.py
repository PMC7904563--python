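"""Training-set augmentation: crops, right-angle rotations, flips, colour jitter.

Geometric transforms are applied identically to image and label; colour
jitter (brightness/contrast) perturbs the image only, so labels stay binary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

__all__ = ["AugmentationSpec", "augment_pair"]

_VALID_ROTATIONS = {90, 180, 270}


@dataclass(frozen=True)
class AugmentationSpec:
    crop_size_px: int = 256
    rotations: frozenset = frozenset({90, 180, 270})
    horizontal_flip: bool = True
    brightness_range: float = 0.1   # additive, uniform in +-range
    contrast_range: float = 0.1     # multiplicative, uniform in 1 +- range
    rng_seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.rotations) - _VALID_ROTATIONS
        if bad:
            raise ValueError(f"rotations must be a subset of {_VALID_ROTATIONS}, got {bad}")
        if self.crop_size_px <= 0:
            raise ValueError("crop_size_px must be positive")
        if self.brightness_range < 0 or self.contrast_range < 0:
            raise ValueError("jitter ranges must be nonnegative")


def _grid_crops(shape: Tuple[int, int], size: int) -> List[Tuple[int, int]]:
    h, w = shape
    return [(r, c) for r in range(0, h - size + 1, size) for c in range(0, w - size + 1, size)]


def augment_pair(
    image: np.ndarray, label_mask: np.ndarray, spec: AugmentationSpec
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Deterministic grid crops x rotations x flip, with seeded colour jitter.

    One full-frame crop with all three rotations and the flip enabled yields
    8 pairs (the full orbit of the right-angle rotation/reflection group).
    """
    if image.shape != label_mask.shape:
        raise ValueError("image and label must have the same shape")
    if spec.crop_size_px > min(image.shape):
        raise ValueError(
            f"crop size {spec.crop_size_px} exceeds image extent {image.shape}"
        )
    rng = np.random.default_rng(spec.rng_seed)
    rot_ks = [0] + sorted(r // 90 for r in spec.rotations)
    flips = [False, True] if spec.horizontal_flip else [False]
    out: List[Tuple[np.ndarray, np.ndarray]] = []
    for r0, c0 in _grid_crops(image.shape, spec.crop_size_px):
        img_c = image[r0 : r0 + spec.crop_size_px, c0 : c0 + spec.crop_size_px]
        lab_c = label_mask[r0 : r0 + spec.crop_size_px, c0 : c0 + spec.crop_size_px]
        for k in rot_ks:
            for flip in flips:
                img_v = np.rot90(img_c, k)
                lab_v = np.rot90(lab_c, k)
                if flip:
                    img_v = np.fliplr(img_v)
                    lab_v = np.fliplr(lab_v)
                img_v = _colour_jitter(np.ascontiguousarray(img_v), spec, rng)
                out.append((img_v, np.ascontiguousarray(lab_v)))
    return out


def _colour_jitter(
    image: np.ndarray, spec: AugmentationSpec, rng: np.random.Generator
) -> np.ndarray:
    if spec.brightness_range == 0 and spec.contrast_range == 0:
        return image
    brightness = rng.uniform(-spec.brightness_range, spec.brightness_range)
    contrast = rng.uniform(1 - spec.contrast_range, 1 + spec.contrast_range)
    mean = image.mean()
    return np.clip((image - mean) * contrast + mean + brightness, 0.0, 1.0)
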