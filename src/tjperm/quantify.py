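"""Tracer-spot detection, junction association, and permeability metrics.

The tracer channel records substrate-bound fluorescence where the tracer
crossed the monolayer. Adaptive thresholding separates accumulation from
background; connected components become labelled spots; a junction is
*permeable* when its centroid lies within 2 px of a spot pixel; and four
per-image metrics summarise the result: the permeable fraction of
junctions, total accumulation, the junction-associated share of it, and
the mean accumulation per permeable junction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .datatypes import JunctionSet, PermeabilityReport, SpotSet

__all__ = [
    "ThresholdParams",
    "adaptive_threshold",
    "total_accumulation",
    "label_spots",
    "associate",
    "compute_report",
    "quantify_image",
]

DISTANCE_THRESHOLD_PX = 2.0


@dataclass(frozen=True)
class ThresholdParams:
    """Adaptive (local Gaussian-mean) threshold parameters.

    A pixel is foreground iff ``value > local_mean * (1 + k)`` with
    ``k = 2 * (1 - sensitivity)``: higher sensitivity lowers the bar and
    admits more foreground. ``neighbourhood_px`` sets the Gaussian window
    (sigma = neighbourhood/6); by default roughly image_size / 8.
    """

    neighbourhood_px: Optional[int] = None   # odd; None -> image_size // 8 | 1
    sensitivity: float = 0.5

    def __post_init__(self) -> None:
        if self.neighbourhood_px is not None:
            if self.neighbourhood_px < 3 or self.neighbourhood_px % 2 == 0:
                raise ValueError("neighbourhood_px must be an odd integer >= 3")
        if not 0 <= self.sensitivity <= 1:
            raise ValueError("sensitivity must be in [0, 1]")


def adaptive_threshold(
    tracer_image: np.ndarray, params: ThresholdParams = ThresholdParams()
) -> np.ndarray:
    """Binary foreground: pixels exceeding their local Gaussian-weighted mean.

    Deterministic; an exactly constant image yields an empty foreground
    (the inequality is strict).
    """
    img = np.asarray(tracer_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    nb = params.neighbourhood_px
    if nb is None:
        nb = max((min(img.shape) // 8) | 1, 3)
    sigma = nb / 6.0
    local_mean = ndimage.gaussian_filter(img, sigma, mode="reflect")
    k = 2.0 * (1.0 - params.sensitivity)
    return img > local_mean * (1.0 + k)


def total_accumulation(tracer_image: np.ndarray, foreground: np.ndarray) -> float:
    """Sum of original pixel values over the thresholded foreground (RFU)."""
    img = np.asarray(tracer_image, dtype=float)
    fg = np.asarray(foreground, dtype=bool)
    if img.shape != fg.shape:
        raise ValueError("image and foreground shapes differ")
    return float(img[fg].sum())


def label_spots(foreground: np.ndarray, tracer_image: np.ndarray) -> SpotSet:
    """8-connected components of the foreground, with integrated intensities."""
    fg = np.asarray(foreground, dtype=bool)
    img = np.asarray(tracer_image, dtype=float)
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    pixels: List[np.ndarray] = []
    intensities = np.zeros(n)
    centroids = np.zeros((n, 2))
    if n:
        idx = np.arange(1, n + 1)
        intensities = ndimage.sum_labels(img, labels, idx)
        rows = ndimage.mean(np.indices(fg.shape)[0], labels, idx)
        cols = ndimage.mean(np.indices(fg.shape)[1], labels, idx)
        centroids = np.column_stack([cols, rows])
        order = ndimage.value_indices(labels)
        for i in idx:
            rr, cc = order[i]
            pixels.append(np.column_stack([rr, cc]))
    return SpotSet(pixels=pixels, intensities=intensities, centroids=centroids)


def associate(
    junctions: JunctionSet,
    spots: SpotSet,
    distance_threshold_px: float = DISTANCE_THRESHOLD_PX,
) -> Tuple[np.ndarray, List[Optional[int]]]:
    """Apply the 2-px rule between junction centroids and spot pixels.

    A junction is permeable iff the Euclidean distance from its centroid to
    the nearest pixel centre of any spot is <= the threshold (inclusive).
    Each spot within threshold of at least one junction is assigned to the
    nearest such junction (ties: lowest junction index); other spots remain
    unassigned (``None``).
    """
    n_j = len(junctions)
    flags = np.zeros(n_j, dtype=bool)
    assignment: List[Optional[int]] = [None] * len(spots)
    if n_j == 0 or len(spots) == 0:
        return flags, assignment
    all_pix = np.vstack(spots.pixels)                       # (row, col)
    spot_of_pixel = np.repeat(
        np.arange(len(spots)), [len(p) for p in spots.pixels]
    )
    tree = cKDTree(all_pix[:, ::-1].astype(float))          # as (x, y)
    # min distance from each junction to each nearby spot
    best: List[dict] = [dict() for _ in range(len(spots))]  # spot -> {junction: dist}
    for j, centroid in enumerate(junctions.coords):
        hits = tree.query_ball_point(centroid, distance_threshold_px)
        if not hits:
            continue
        flags[j] = True
        d = np.hypot(
            all_pix[hits, 1] - centroid[0], all_pix[hits, 0] - centroid[1]
        )
        for pix_i, dist in zip(hits, d):
            s = spot_of_pixel[pix_i]
            if j not in best[s] or dist < best[s][j]:
                best[s][j] = dist
    for s, cand in enumerate(best):
        if cand:
            # nearest junction; ties resolved to the lowest index
            assignment[s] = min(cand, key=lambda j: (cand[j], j))
    return flags, assignment


def compute_report(
    junctions: JunctionSet,
    spots: SpotSet,
    flags: np.ndarray,
    assignment: List[Optional[int]],
    tracer_image: np.ndarray,
    foreground: np.ndarray,
) -> PermeabilityReport:
    """Assemble the four permeability metrics for one image.

    Each assigned spot contributes its integrated intensity to the
    junction-associated accumulation exactly once. Images with zero
    junctions are rejected as unanalysable.
    """
    if len(junctions) == 0:
        raise ValueError("no junctions detected: image rejected as unanalysable")
    tj_acc = float(
        sum(spots.intensities[s] for s, j in enumerate(assignment) if j is not None)
    )
    return PermeabilityReport(
        n_junctions=len(junctions),
        n_permeable=int(np.asarray(flags, dtype=bool).sum()),
        total_accumulation=total_accumulation(tracer_image, foreground),
        tj_accumulation=tj_acc,
    )


def quantify_image(
    tracer_image: np.ndarray,
    junctions: JunctionSet,
    threshold_params: ThresholdParams = ThresholdParams(),
    distance_threshold_px: float = DISTANCE_THRESHOLD_PX,
) -> Tuple[PermeabilityReport, SpotSet, np.ndarray, List[Optional[int]]]:
    """Full per-image quantification: threshold, label, associate, report."""
    fg = adaptive_threshold(tracer_image, threshold_params)
    spots = label_spots(fg, tracer_image)
    flags, assignment = associate(junctions, spots, distance_threshold_px)
    report = compute_report(junctions, spots, flags, assignment, tracer_image, fg)
    return report, spots, flags, assignment
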