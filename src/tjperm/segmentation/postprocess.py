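"""Probability-map post-processing: threshold, watershed split, centroids.

Two junctions close together can appear as one contiguous blob in the
predicted map; the watershed transform on the negated distance transform of
the thresholded foreground splits such blobs before centroids are taken.
The output includes a uniform-size binary map (a fixed-radius disk at each
centroid), treating every junction as the same size.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from ..datatypes import JunctionSet

__all__ = ["binarize_and_split"]

CENTROID_MERGE_RADIUS_PX = 3.0


def binarize_and_split(
    probability_map: np.ndarray,
    prob_threshold: float = 0.5,
    junction_radius_px: float = 3.0,
    min_region_px: int = 2,
) -> Tuple[JunctionSet, np.ndarray]:
    """Threshold a probability map and split merged blobs by watershed.

    Returns the junction centroids (region centroids after splitting,
    merged within 3 px) and the uniform-size binary map. Regions smaller
    than ``min_region_px`` pixels are discarded as speckle.
    """
    if not 0 < prob_threshold < 1:
        raise ValueError("prob_threshold must be in (0, 1)")
    if junction_radius_px <= 0:
        raise ValueError("junction_radius_px must be positive")
    pmap = np.asarray(probability_map, dtype=float)
    fg = pmap >= prob_threshold
    if not fg.any():
        return JunctionSet(coords=np.empty((0, 2))), np.zeros(pmap.shape, dtype=bool)

    dist = ndimage.distance_transform_edt(fg)
    # watershed seeds: regional maxima of the distance transform, at least a
    # junction diameter apart so one blob is not oversplit
    seeds_rc = peak_local_max(
        dist, min_distance=max(int(round(junction_radius_px)), 1),
        exclude_border=False, labels=fg,
    )
    markers = np.zeros(pmap.shape, dtype=int)
    markers[tuple(seeds_rc.T)] = np.arange(1, len(seeds_rc) + 1)
    labels = watershed(-dist, markers=markers, mask=fg)

    idx = np.arange(1, labels.max() + 1)
    counts = ndimage.sum_labels(np.ones_like(labels), labels, idx)
    rows = ndimage.mean(np.indices(pmap.shape)[0], labels, idx)
    cols = ndimage.mean(np.indices(pmap.shape)[1], labels, idx)
    keep = counts >= min_region_px
    coords = np.column_stack([cols[keep], rows[keep]])
    if len(coords):
        from .geometric import _merge_points

        coords = _merge_points(coords, CENTROID_MERGE_RADIUS_PX)
    junctions = JunctionSet(coords=coords)

    uniform = np.zeros(pmap.shape, dtype=bool)
    h, w = pmap.shape
    for x, y in junctions.coords:
        r0, r1 = max(int(y - junction_radius_px), 0), min(int(y + junction_radius_px) + 1, h)
        c0, c1 = max(int(x - junction_radius_px), 0), min(int(x + junction_radius_px) + 1, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        uniform[r0:r1, c0:c1] |= (xx - x) ** 2 + (yy - y) ** 2 <= junction_radius_px**2
    return junctions, uniform
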