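"""Shared containers passed between pipeline stages.

Coordinate convention used throughout the package: images are ``(row, col)``
NumPy arrays with the origin at the top-left; geometric points are ``(x, y)``
with ``x`` along columns and ``y`` along rows, and the centre of pixel
``(r, c)`` is the point ``(c, r)``. All geometry is in pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["JunctionSet", "SpotSet", "PermeabilityReport"]


@dataclass
class JunctionSet:
    """Tricellular-junction centroids, detected or ground truth.

    Parameters
    ----------
    coords : (n, 2) float array
        Junction centroids as ``(x, y)`` pixel coordinates.
    permeable : (n,) bool array, optional
        Whether each junction was (or is known to be) permeable.
    signal : (n,) float array, optional
        Tracer signal associated with each junction.
    region_pixels : list of (m_i, 2) int arrays, optional
        Pixel ``(row, col)`` lists of the detected region behind each
        centroid, when a segmentation produced one.
    """

    coords: np.ndarray
    permeable: Optional[np.ndarray] = None
    signal: Optional[np.ndarray] = None
    region_pixels: Optional[list] = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.size == 0:
            self.coords = np.empty((0, 2), dtype=float)
        if self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array of (x, y) points")
        if self.permeable is not None:
            self.permeable = np.asarray(self.permeable, dtype=bool)
            if self.permeable.shape[0] != len(self):
                raise ValueError("permeable flags must match number of junctions")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_permeable(self) -> int:
        if self.permeable is None:
            raise ValueError("this JunctionSet carries no permeable flags")
        return int(self.permeable.sum())


@dataclass
class SpotSet:
    """Labelled connected components of thresholded tracer signal.

    ``pixels[i]`` is the (m_i, 2) array of ``(row, col)`` indices of spot
    ``i``; ``intensities[i]`` is the sum of the *original* image over those
    pixels; ``centroids[i]`` is the unweighted centroid in ``(x, y)``.
    """

    pixels: list
    intensities: np.ndarray
    centroids: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass
class PermeabilityReport:
    """Per-image permeability metrics.

    The four headline quantities are ``fraction_permeable`` (permeable
    junctions / all junctions), ``total_accumulation`` (sum of pixel values
    over the thresholded tracer foreground, in RFU), ``tj_fraction``
    (junction-associated accumulation / total accumulation) and
    ``mean_per_permeable`` (junction-associated accumulation per permeable
    junction; NaN when there are none).
    """

    n_junctions: int
    n_permeable: int
    total_accumulation: float
    tj_accumulation: float

    @property
    def fraction_permeable(self) -> float:
        return self.n_permeable / self.n_junctions

    @property
    def tj_fraction(self) -> float:
        if self.total_accumulation == 0:
            return 0.0
        return self.tj_accumulation / self.total_accumulation

    @property
    def mean_per_permeable(self) -> float:
        if self.n_permeable == 0:
            return float("nan")
        return self.tj_accumulation / self.n_permeable

    def to_dict(self) -> dict:
        return {
            "n_junctions": self.n_junctions,
            "n_permeable": self.n_permeable,
            "total_accumulation": self.total_accumulation,
            "tj_accumulation": self.tj_accumulation,
            "fraction_permeable": self.fraction_permeable,
            "tj_fraction": self.tj_fraction,
            "mean_per_permeable": self.mean_per_permeable,
        }
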