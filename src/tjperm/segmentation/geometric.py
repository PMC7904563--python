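"""Deterministic junction detector from border-skeleton branch points.

Thresholds the border channel, skeletonises the ridges, and reports
skeleton pixels with >= 3 skeleton neighbours (branch points) as junction
centroids after merging clusters within 3 px. Needs bright ridges on a dark
background; serves as an independent oracle for the trained segmenter and
as a fast junction source for quantification-only pipelines.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from ..datatypes import JunctionSet

__all__ = ["geometric_detector"]

BRANCH_MERGE_RADIUS_PX = 2.5


def geometric_detector(border_image: np.ndarray, threshold: float | None = None) -> JunctionSet:
    """Detect junction centroids as merged skeleton branch points.

    ``threshold`` defaults to Otsu's value; a blank (near-constant) image
    yields an empty set. Thinning is applied in all four right-angle
    orientations and the branch points pooled, which makes detection exactly
    equivariant under 90-degree image rotation (raw thinning is not).
    """
    img = np.asarray(border_image, dtype=float)
    # quantise so images equal up to float rounding give identical detections
    img = np.round(img * 65535.0) / 65535.0
    if img.std() < 1e-6:
        return JunctionSet(coords=np.empty((0, 2)))
    if threshold is None:
        threshold = threshold_otsu(img)
    fg = img > threshold
    if not fg.any():
        return JunctionSet(coords=np.empty((0, 2)))
    h, w = fg.shape
    coords_list = []
    for k in range(4):
        skel = skeletonize(np.rot90(fg, k))
        neighbours = convolve(skel.astype(int), np.ones((3, 3), int), mode="constant") - skel
        rows, cols = np.nonzero(skel & (neighbours >= 3))
        pts = np.column_stack([cols.astype(float), rows.astype(float)])
        # rotate branch coordinates back into the original frame, one
        # 90-degree step at a time: (x, y) in frame t+1 -> (W_t - 1 - y, x)
        for step in range(k):
            t = k - step - 1
            width_t = w if t % 2 == 0 else h
            if len(pts):
                pts = np.column_stack([width_t - 1 - pts[:, 1], pts[:, 0]])
        coords_list.append(pts)
    coords = np.vstack(coords_list)
    if len(coords) == 0:
        return JunctionSet(coords=np.empty((0, 2)))
    return JunctionSet(coords=_merge_points(coords, BRANCH_MERGE_RADIUS_PX))


def _merge_points(coords: np.ndarray, radius: float) -> np.ndarray:
    """Single-linkage clustering within ``radius``; cluster means returned."""
    from scipy.spatial import cKDTree

    n = len(coords)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(coords)
    for i, j in tree.query_pairs(radius):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return np.array([coords[m].mean(axis=0) for m in groups.values()])
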