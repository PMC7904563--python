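"""Reading and writing of channels, ground truth and result tables.

Channels live in ``[0, 1]`` in memory and are quantised to 8/16-bit only on
export. TIFF via tifffile, PNG via imageio; tables via pandas.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .datatypes import JunctionSet, PermeabilityReport, SpotSet
from .synthetic import GroundTruth

PathLike = Union[str, Path]


def to_uint(image: np.ndarray, bit_depth: int = 16) -> np.ndarray:
    """Quantise a float image in [0, 1] to uint8/uint16 full scale."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    scale = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return np.round(np.clip(image, 0.0, 1.0) * scale).astype(dtype)


def from_uint(image: np.ndarray) -> np.ndarray:
    """Rescale an integer image to float [0, 1]; float input passes through."""
    if np.issubdtype(image.dtype, np.floating):
        return np.asarray(image, dtype=float)
    info = np.iinfo(image.dtype)
    return image.astype(float) / info.max


def save_image(path: PathLike, image: np.ndarray, bit_depth: int = 16) -> None:
    path = Path(path)
    data = to_uint(image, bit_depth)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, data)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")


def load_image(path: PathLike) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        data = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    if data.ndim != 2:
        raise ValueError("expected a single-plane single-channel image")
    return from_uint(data)


def save_junctions_csv(path: PathLike, junctions: JunctionSet) -> None:
    df = pd.DataFrame(junctions.coords, columns=["x", "y"])
    if junctions.permeable is not None:
        df["permeable"] = junctions.permeable.astype(int)
    df.to_csv(path, index=False)


def load_junctions_csv(path: PathLike) -> JunctionSet:
    df = pd.read_csv(path)
    perm = df["permeable"].to_numpy(bool) if "permeable" in df else None
    return JunctionSet(coords=df[["x", "y"]].to_numpy(float), permeable=perm)


def save_ground_truth(path: PathLike, truth: GroundTruth) -> None:
    payload = {
        "junctions": {
            "coords": truth.junctions.coords.tolist(),
            "permeable": truth.junctions.permeable.astype(int).tolist(),
        },
        "spots": [dataclasses.asdict(sp) for sp in truth.spots],
        "tj_signal": truth.tj_signal,
        "total_signal": truth.total_signal,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_ground_truth(path: PathLike) -> GroundTruth:
    from .synthetic import SpotRecord

    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        junctions=JunctionSet(
            coords=np.array(payload["junctions"]["coords"], dtype=float).reshape(-1, 2),
            permeable=np.array(payload["junctions"]["permeable"], dtype=bool),
        ),
        spots=[SpotRecord(**sp) for sp in payload["spots"]],
        tj_signal=payload["tj_signal"],
        total_signal=payload["total_signal"],
    )


def save_spots_csv(path: PathLike, spots: SpotSet, assignment=None) -> None:
    rows = []
    for i in range(len(spots)):
        rows.append(
            {
                "label": i,
                "x": spots.centroids[i, 0],
                "y": spots.centroids[i, 1],
                "n_pixels": len(spots.pixels[i]),
                "integrated_intensity": spots.intensities[i],
                "assigned_junction": -1 if assignment is None or assignment[i] is None
                else assignment[i],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def report_to_frame(reports: list, **extra_cols) -> pd.DataFrame:
    """Stack PermeabilityReports into one DataFrame, with constant extras."""
    df = pd.DataFrame([r.to_dict() for r in reports])
    for k, v in extra_cols.items():
        df[k] = v
    return df
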