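"""Synthetic confluent-monolayer image generator with known ground truth.

Emulates the two channels of a spatially resolved transendothelial
permeability assay: a cell-border channel (immunostained borders of a
confluent endothelial monolayer, rendered from a centroid-relaxed random
tessellation) and a tracer channel (substrate-bound fluorescent tracer
accumulating in spots at a controllable fraction of tricellular junctions,
plus off-junction spots and background). Every image comes with the exact
realised ground truth, so detection and quantification stages can be tested
for parameter recovery.

Intensities are kept in ``[0, 1]`` internally and quantised only on export
(see :mod:`tjperm.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import Voronoi, cKDTree

from .datatypes import JunctionSet

__all__ = [
    "FieldSpec",
    "CellTessellation",
    "RenderParams",
    "TracerParams",
    "SpotRecord",
    "GroundTruth",
    "TimeSeriesParams",
    "TimeSeriesTruth",
    "CONDITION_PRESETS",
    "generate_tessellation",
    "render_border_channel",
    "make_annotation_mask",
    "render_tracer_channel",
    "condition_preset",
    "generate_timeseries",
    "sample_opening_frames",
    "free_diffusion_radius",
]

# Vertices closer than this are treated as one junction (a >=4-cell meeting
# point is a single junction, not several).
VERTEX_MERGE_RADIUS_PX = 2.0

# Off-junction spots are kept at least this far from every junction centroid
# so their ground-truth labels are unambiguous under the 2-px association rule.
OFFJUNCTION_CLEARANCE_PX = 5.0

# Generated junction spots are jittered at most this far from the centroid,
# keeping them inside the 2-px association radius by construction.
SPOT_JITTER_MAX_PX = 1.0


@dataclass(frozen=True)
class FieldSpec:
    """Geometry of one acquisition field, in pixels."""

    height_px: int = 512
    width_px: int = 512
    n_cells: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 64 or self.width_px < 64:
            raise ValueError("field must be at least 64 x 64 pixels")
        if self.n_cells < 3:
            raise ValueError("need at least 3 cells for a tricellular junction")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.height_px, self.width_px)


@dataclass
class CellTessellation:
    """Space-filling polygonal tessellation of a field.

    ``vertices`` are the interior points where ``vertex_degrees[i] >= 3``
    cells meet — the ground-truth tricellular junctions.
    """

    field: FieldSpec
    cell_seeds: np.ndarray          # (n, 2) (x, y)
    edges: List[np.ndarray]         # each (2, 2): [[x0, y0], [x1, y1]]
    vertices: np.ndarray            # (m, 2) (x, y)
    vertex_degrees: np.ndarray      # (m,) int, all >= 3

    @property
    def junctions(self) -> JunctionSet:
        return JunctionSet(coords=self.vertices.copy())


@dataclass(frozen=True)
class RenderParams:
    """Rendering of the cell-border channel."""

    border_width_px: float = 3.0
    border_peak_intensity: float = 0.8
    blur_sigma_px: float = 1.0
    noise_sd: float = 0.02
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.border_width_px <= 0:
            raise ValueError("border_width_px must be positive")
        if not 0 < self.border_peak_intensity <= 1:
            raise ValueError("border_peak_intensity must be in (0, 1]")
        if self.blur_sigma_px < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma_px and noise_sd must be nonnegative")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass(frozen=True)
class TracerParams:
    """Set-points of the tracer channel.

    ``permeable_fraction`` is the fraction of junctions that receive a spot;
    ``tj_signal_share`` is the target fraction of total above-background
    signal carried by junction-centred spots.
    """

    permeable_fraction: float = 0.381
    tj_signal_share: float = 0.85
    spot_sigma_px: float = 1.5
    spot_amplitude_mean: float = 0.45
    spot_amplitude_cv: float = 0.2
    n_offjunction_spots: int = 12
    background_level: float = 0.05
    background_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.permeable_fraction <= 1:
            raise ValueError("permeable_fraction must be in [0, 1]")
        if not 0 <= self.tj_signal_share <= 1:
            raise ValueError("tj_signal_share must be in [0, 1]")
        if self.spot_sigma_px <= 0 or self.spot_amplitude_mean <= 0:
            raise ValueError("spot sigma and amplitude mean must be positive")
        if self.n_offjunction_spots < 0:
            raise ValueError("n_offjunction_spots must be nonnegative")
        if self.background_level < 0 or self.background_noise_sd < 0:
            raise ValueError("background parameters must be nonnegative")


@dataclass
class SpotRecord:
    """Provenance of one generated tracer spot."""

    x: float
    y: float
    sigma: float
    amplitude: float
    integral: float                 # discrete sum of this spot's contribution
    junction_index: Optional[int]   # None for off-junction spots


@dataclass
class GroundTruth:
    """Exact realised ground truth of one tracer rendering."""

    junctions: JunctionSet          # with permeable flags
    spots: List[SpotRecord]
    tj_signal: float                # sum of junction-spot integrals
    total_signal: float             # sum of all spot integrals

    @property
    def n_permeable(self) -> int:
        return self.junctions.n_permeable

    @property
    def fraction_permeable(self) -> float:
        return self.n_permeable / len(self.junctions)

    @property
    def tj_signal_share(self) -> float:
        if self.total_signal == 0:
            return 0.0
        return self.tj_signal / self.total_signal


@dataclass(frozen=True)
class TimeSeriesParams:
    """Live-imaging emulation: spots grow and junctions open over time."""

    n_frames: int = 10
    frame_interval_s: float = 60.0
    spot_growth_rate: float = 0.2       # sigma increase per frame, px
    junction_opening_rate: float = 0.3  # P(closed designate opens) per frame
    initial_open: bool = False          # open every designate at frame 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.frame_interval_s <= 0 or self.spot_growth_rate <= 0:
            raise ValueError("frame interval and growth rate must be positive")
        if not 0 <= self.junction_opening_rate <= 1:
            raise ValueError("junction_opening_rate must be in [0, 1]")


@dataclass
class TimeSeriesTruth:
    """Per-designate opening frames and per-frame spot bookkeeping."""

    junctions: JunctionSet              # designated-permeable flags
    designate_indices: np.ndarray       # indices into junctions
    open_frame: np.ndarray              # frame each designate opened, or -1
    spot_counts: np.ndarray             # (n_frames,) open-spot count
    spot_integrals: np.ndarray          # (n_frames, n_designates), NaN if closed
    spot_sigmas: np.ndarray             # (n_frames, n_designates), NaN if closed


# --------------------------------------------------------------------------
# tessellation


def generate_tessellation(spec: FieldSpec, relaxation_steps: int = 2) -> CellTessellation:
    """Generate a space-filling polygonal tessellation with known junctions.

    Random seed points are tessellated (Voronoi) with the field boundary
    enforced by mirroring the seeds across the four field edges; optional
    Lloyd (centroid) relaxation rounds the cells into more regular,
    endothelial-like polygons. Interior points where >= 3 cells meet are
    returned, each exactly once (vertices closer than 2 px are merged).
    """
    if relaxation_steps < 0:
        raise ValueError("relaxation_steps must be nonnegative")
    w, h = spec.width_px - 1.0, spec.height_px - 1.0
    mean_diameter = np.sqrt(spec.height_px * spec.width_px / spec.n_cells)
    if mean_diameter < 4.0:
        raise ValueError(
            f"n_cells={spec.n_cells} is too large for a "
            f"{spec.height_px}x{spec.width_px} field: mean cell diameter "
            f"{mean_diameter:.1f} px < 4 px"
        )
    rng = np.random.default_rng(spec.rng_seed)
    pts = np.column_stack(
        [rng.uniform(0.0, w, spec.n_cells), rng.uniform(0.0, h, spec.n_cells)]
    )
    for _ in range(relaxation_steps):
        pts = _lloyd_step(pts, w, h)
    vor = Voronoi(_mirror_points(pts, w, h))
    return _extract_tessellation(spec, pts, vor, w, h)


def _mirror_points(pts: np.ndarray, w: float, h: float) -> np.ndarray:
    """Reflect seeds across the four field edges so in-field cells are bounded."""
    left = pts * [-1, 1]
    right = np.column_stack([2 * w - pts[:, 0], pts[:, 1]])
    top = pts * [1, -1]
    bottom = np.column_stack([pts[:, 0], 2 * h - pts[:, 1]])
    return np.vstack([pts, left, right, top, bottom])


def _lloyd_step(pts: np.ndarray, w: float, h: float) -> np.ndarray:
    vor = Voronoi(_mirror_points(pts, w, h))
    out = pts.copy()
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            continue
        poly = vor.vertices[region]
        out[i] = _polygon_centroid(poly)
    np.clip(out[:, 0], 0.0, w, out=out[:, 0])
    np.clip(out[:, 1], 0.0, h, out=out[:, 1])
    return out


def _polygon_centroid(poly: np.ndarray) -> np.ndarray:
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-12:
        return poly.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return np.array([cx, cy])


def _extract_tessellation(
    spec: FieldSpec, pts: np.ndarray, vor: Voronoi, w: float, h: float
) -> CellTessellation:
    n = len(pts)
    eps = 1e-9
    # incidence of Voronoi vertices on original (non-mirror) cells
    incident: dict = {}
    edges: List[np.ndarray] = []
    for (p, q), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if -1 in verts:
            continue
        orig = [i for i in (p, q) if i < n]
        for v in verts:
            incident.setdefault(v, set()).update(orig)
        if p < n and q < n:
            seg = _clip_segment(vor.vertices[verts[0]], vor.vertices[verts[1]], w, h)
            if seg is not None:
                edges.append(seg)
    cand_idx = [
        v
        for v, cells in incident.items()
        if len(cells) >= 3
        and eps < vor.vertices[v][0] < w - eps
        and eps < vor.vertices[v][1] < h - eps
    ]
    coords = vor.vertices[cand_idx] if cand_idx else np.empty((0, 2))
    merged_pos, merged_deg = _merge_vertices(
        coords, [incident[v] for v in cand_idx], VERTEX_MERGE_RADIUS_PX
    )
    return CellTessellation(
        field=spec,
        cell_seeds=pts,
        edges=edges,
        vertices=merged_pos,
        vertex_degrees=merged_deg,
    )


def _merge_vertices(
    coords: np.ndarray, incident_sets: Sequence[set], radius: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Union-find merge of vertices closer than ``radius``."""
    m = len(coords)
    if m == 0:
        return np.empty((0, 2)), np.empty(0, dtype=int)
    parent = list(range(m))

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
    for i in range(m):
        groups.setdefault(find(i), []).append(i)
    pos = np.array([coords[members].mean(axis=0) for members in groups.values()])
    deg = np.array(
        [len(set().union(*[incident_sets[i] for i in members])) for members in groups.values()],
        dtype=int,
    )
    return pos, deg


def _clip_segment(
    a: np.ndarray, b: np.ndarray, w: float, h: float
) -> Optional[np.ndarray]:
    """Liang-Barsky clip of segment ab to the box [0, w] x [0, h]."""
    t0, t1 = 0.0, 1.0
    d = b - a
    for p, q in (
        (-d[0], a[0]),
        (d[0], w - a[0]),
        (-d[1], a[1]),
        (d[1], h - a[1]),
    ):
        if p == 0:
            if q < 0:
                return None
            continue
        t = q / p
        if p < 0:
            t0 = max(t0, t)
        else:
            t1 = min(t1, t)
        if t0 > t1:
            return None
    if t1 - t0 < 1e-12:
        return None
    return np.array([a + t0 * d, a + t1 * d])


# --------------------------------------------------------------------------
# border channel


def render_border_channel(
    tess: CellTessellation, params: RenderParams, rng_seed: int = 0
) -> np.ndarray:
    """Rasterise cell borders as bright ridges; blur and add noise.

    Pixels whose centre lies within ``border_width_px / 2`` of an edge are
    set to ``border_peak_intensity`` before blurring; output is a float
    image in ``[0, 1]``.
    """
    shape = tess.field.shape
    dist = _min_distance_to_segments(shape, tess.edges, params.border_width_px / 2 + 1)
    img = np.where(dist <= params.border_width_px / 2, params.border_peak_intensity, 0.0)
    if params.blur_sigma_px > 0:
        img = gaussian_filter(img, params.blur_sigma_px)
    if params.noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        img = img + rng.normal(0.0, params.noise_sd, size=shape)
    return np.clip(img, 0.0, 1.0)


def _min_distance_to_segments(
    shape: Tuple[int, int], segments: Sequence[np.ndarray], max_dist: float
) -> np.ndarray:
    """Per-pixel distance to the nearest segment, exact up to ``max_dist``."""
    h, w = shape
    dist = np.full(shape, np.inf)
    pad = int(np.ceil(max_dist))
    for seg in segments:
        (x0, y0), (x1, y1) = seg
        r0 = max(int(np.floor(min(y0, y1))) - pad, 0)
        r1 = min(int(np.ceil(max(y0, y1))) + pad, h - 1)
        c0 = max(int(np.floor(min(x0, x1))) - pad, 0)
        c1 = min(int(np.ceil(max(x0, x1))) + pad, w - 1)
        if r0 > r1 or c0 > c1:
            continue
        yy, xx = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        dx, dy = x1 - x0, y1 - y0
        len2 = dx * dx + dy * dy
        if len2 == 0:
            d = np.hypot(xx - x0, yy - y0)
        else:
            t = np.clip(((xx - x0) * dx + (yy - y0) * dy) / len2, 0.0, 1.0)
            d = np.hypot(xx - (x0 + t * dx), yy - (y0 + t * dy))
        np.minimum(dist[r0 : r1 + 1, c0 : c1 + 1], d, out=dist[r0 : r1 + 1, c0 : c1 + 1])
    return dist


# --------------------------------------------------------------------------
# annotation masks


def make_annotation_mask(
    junctions: JunctionSet, radius_px: float, fieldspec: FieldSpec
) -> np.ndarray:
    """Binary mask with a disk of ``radius_px`` at each junction centroid.

    A pixel belongs to a disk iff its centre is within ``radius_px`` of the
    centroid (0-based ``(row, col)``, origin top-left); overlapping disks are
    unioned. This emulates uniform-size hand annotation of junctions.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    h, w = fieldspec.shape
    mask = np.zeros((h, w), dtype=bool)
    for x, y in junctions.coords:
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise ValueError(f"junction ({x}, {y}) outside {h}x{w} field")
        r0 = max(int(np.floor(y - radius_px)), 0)
        r1 = min(int(np.ceil(y + radius_px)), h - 1)
        c0 = max(int(np.floor(x - radius_px)), 0)
        c1 = min(int(np.ceil(x + radius_px)), w - 1)
        yy, xx = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        mask[r0 : r1 + 1, c0 : c1 + 1] |= (xx - x) ** 2 + (yy - y) ** 2 <= radius_px**2
    return mask


# --------------------------------------------------------------------------
# tracer channel


def _spot_patch(
    shape: Tuple[int, int], x: float, y: float, sigma: float, amplitude: float
) -> Tuple[slice, slice, np.ndarray]:
    """Gaussian spot evaluated on its 5-sigma pixel window."""
    h, w = shape
    ext = int(np.ceil(5 * sigma))
    r0 = max(int(np.floor(y)) - ext, 0)
    r1 = min(int(np.ceil(y)) + ext, h - 1)
    c0 = max(int(np.floor(x)) - ext, 0)
    c1 = min(int(np.ceil(x)) + ext, w - 1)
    yy, xx = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    patch = amplitude * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    return slice(r0, r1 + 1), slice(c0, c1 + 1), patch


def _sample_amplitudes(
    rng: np.random.Generator, n: int, params: TracerParams, cap: float
) -> np.ndarray:
    mean, cv = params.spot_amplitude_mean, params.spot_amplitude_cv
    amps = rng.normal(mean, cv * mean, size=n)
    return np.clip(amps, 0.05 * mean, cap)


def _sample_offjunction_positions(
    rng: np.random.Generator,
    tess: CellTessellation,
    n: int,
    junction_tree: Optional[cKDTree],
) -> np.ndarray:
    """Spot positions on edges / in interiors, > 5 px from every junction."""
    w, h = tess.field.width_px - 1.0, tess.field.height_px - 1.0
    out = []
    attempts = 0
    max_attempts = 200 * max(n, 1)
    while len(out) < n and attempts < max_attempts:
        attempts += 1
        if tess.edges and rng.random() < 0.5:
            seg = tess.edges[rng.integers(len(tess.edges))]
            t = rng.random()
            p = seg[0] + t * (seg[1] - seg[0])
        else:
            p = np.array([rng.uniform(3, w - 3), rng.uniform(3, h - 3)])
        if not (3 <= p[0] <= w - 3 and 3 <= p[1] <= h - 3):
            continue
        if junction_tree is not None:
            d, _ = junction_tree.query(p)
            if d <= OFFJUNCTION_CLEARANCE_PX:
                continue
        out.append(p)
    if len(out) < n:
        warnings.warn(
            f"placed only {len(out)}/{n} off-junction spots with "
            f"> {OFFJUNCTION_CLEARANCE_PX} px clearance"
        )
    return np.array(out) if out else np.empty((0, 2))


def render_tracer_channel(
    tess: CellTessellation, params: TracerParams, rng_seed: int = 0
) -> Tuple[np.ndarray, GroundTruth]:
    """Render the tracer channel and return the exact realised ground truth.

    ``round(permeable_fraction * n_junctions)`` junctions are selected
    without replacement and given a Gaussian spot jittered <= 1 px from the
    centroid; ``n_offjunction_spots`` additional spots are placed > 5 px from
    every junction; off-junction amplitudes are scaled so the realised
    junction-associated share of above-background signal matches
    ``tj_signal_share``; background and noise are added last.
    """
    rng = np.random.default_rng(rng_seed)
    shape = tess.field.shape
    junctions = tess.vertices
    n_j = len(junctions)
    if n_j == 0:
        raise ValueError("tessellation has no junctions")
    amp_cap = max(0.95 - params.background_level, 0.1)

    n_perm = int(np.floor(params.permeable_fraction * n_j + 0.5))
    if n_perm == 0 and params.tj_signal_share > 0 and params.permeable_fraction * n_j < 1:
        warnings.warn(
            "permeable_fraction * n_junctions < 1: rendering zero permeable junctions"
        )
    perm_idx = rng.choice(n_j, size=n_perm, replace=False) if n_perm else np.empty(0, int)
    flags = np.zeros(n_j, dtype=bool)
    flags[perm_idx] = True

    # junction spots, jittered uniformly within a 1-px disk
    theta = rng.uniform(0, 2 * np.pi, n_perm)
    rad = SPOT_JITTER_MAX_PX * np.sqrt(rng.random(n_perm))
    jitter = np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
    j_pos = junctions[perm_idx] + jitter
    j_pos[:, 0] = np.clip(j_pos[:, 0], 0, shape[1] - 1)
    j_pos[:, 1] = np.clip(j_pos[:, 1], 0, shape[0] - 1)
    j_amp = _sample_amplitudes(rng, n_perm, params, amp_cap)

    tree = cKDTree(junctions) if n_j else None
    o_pos = _sample_offjunction_positions(rng, tess, params.n_offjunction_spots, tree)
    o_amp = _sample_amplitudes(rng, len(o_pos), params, amp_cap)

    sigma = params.spot_sigma_px
    # discrete per-spot integrals at unit amplitude, for share scaling
    j_unit = np.array(
        [_spot_patch(shape, x, y, sigma, 1.0)[2].sum() for x, y in j_pos]
    )
    o_unit = np.array(
        [_spot_patch(shape, x, y, sigma, 1.0)[2].sum() for x, y in o_pos]
    )
    s = params.tj_signal_share
    s_j = float((j_amp * j_unit).sum()) if n_perm else 0.0
    s_o = float((o_amp * o_unit).sum()) if len(o_pos) else 0.0
    if n_perm > 0 and s_j > 0 and s_o > 0 and 0 < s < 1:
        o_amp = np.minimum(o_amp * (s_j * (1 - s) / s) / s_o, amp_cap)
    elif s >= 1:
        o_amp = np.zeros_like(o_amp)

    img = np.full(shape, params.background_level)
    spots: List[SpotRecord] = []
    per_junction_signal = np.zeros(n_j)
    for (x, y), amp, ji in zip(
        np.vstack([j_pos, o_pos]) if len(o_pos) else j_pos,
        np.concatenate([j_amp, o_amp]) if len(o_pos) else j_amp,
        list(perm_idx) + [None] * len(o_pos),
    ):
        rs, cs, patch = _spot_patch(shape, x, y, sigma, amp)
        img[rs, cs] += patch
        integral = float(patch.sum())
        spots.append(
            SpotRecord(x=float(x), y=float(y), sigma=float(sigma),
                       amplitude=float(amp), integral=integral,
                       junction_index=None if ji is None else int(ji))
        )
        if ji is not None:
            per_junction_signal[ji] += integral
    tj_signal = float(sum(sp.integral for sp in spots if sp.junction_index is not None))
    total_signal = float(sum(sp.integral for sp in spots))

    if params.background_noise_sd > 0:
        img = img + rng.normal(0.0, params.background_noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)

    truth = GroundTruth(
        junctions=JunctionSet(
            coords=junctions.copy(), permeable=flags, signal=per_junction_signal
        ),
        spots=spots,
        tj_signal=tj_signal,
        total_signal=total_signal,
    )
    return img, truth


# --------------------------------------------------------------------------
# condition presets

# Set-points encode the measured per-condition statistics: the fraction of
# junctions that are permeable, the junction-associated share of total
# transport (0.80-0.87 across conditions), and the per-junction amplitude
# relative to the untreated / multidirectional baseline (+25% thrombin,
# -31% uniaxial).
CONDITION_PRESETS = {
    "untreated": dict(permeable_fraction=0.381, tj_signal_share=0.85, amplitude_scale=1.00),
    "s1p": dict(permeable_fraction=0.203, tj_signal_share=0.84, amplitude_scale=1.00),
    "thrombin": dict(permeable_fraction=0.473, tj_signal_share=0.82, amplitude_scale=1.25),
    "multidirectional": dict(permeable_fraction=0.407, tj_signal_share=0.85, amplitude_scale=1.00),
    "uniaxial": dict(permeable_fraction=0.289, tj_signal_share=0.87, amplitude_scale=0.69),
}


def offjunction_count_for_share(
    n_junctions: int, permeable_fraction: float, tj_signal_share: float,
    minimum: int = 5,
) -> int:
    """Off-junction spot count that hits a target share at comparable amplitude.

    With junction and off-junction spots drawn from the same amplitude
    distribution, a share ``s`` needs ``n_perm * (1 - s) / s`` off-junction
    spots. Sizing the count (rather than dimming individual spots far below
    the detection floor) keeps every generated spot comparably bright, which
    is how off-junction accumulations appear in the assay.
    """
    if not 0 < tj_signal_share < 1:
        raise ValueError("tj_signal_share must be in (0, 1) to size a count")
    n_perm = int(np.floor(permeable_fraction * n_junctions + 0.5))
    return max(int(round(n_perm * (1 - tj_signal_share) / tj_signal_share)), minimum)


def condition_preset(name: str) -> TracerParams:
    """Tracer parameters encoding one of the five study conditions."""
    try:
        preset = CONDITION_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown condition {name!r}; valid names: {sorted(CONDITION_PRESETS)}"
        ) from None
    base = TracerParams()
    return replace(
        base,
        permeable_fraction=preset["permeable_fraction"],
        tj_signal_share=preset["tj_signal_share"],
        spot_amplitude_mean=base.spot_amplitude_mean * preset["amplitude_scale"],
    )


# --------------------------------------------------------------------------
# time series


def sample_opening_frames(
    n_designates: int, rate: float, n_frames: int, rng: np.random.Generator,
    initial_open: bool = False,
) -> np.ndarray:
    """Frame at which each designated-permeable junction opens (-1 = never).

    Designates start closed at frame 0 (unless ``initial_open``) and each
    closed designate opens independently with probability ``rate`` at every
    subsequent frame; opened junctions stay open.
    """
    if initial_open:
        return np.zeros(n_designates, dtype=int)
    open_frame = np.full(n_designates, -1, dtype=int)
    draws = rng.random((n_designates, n_frames - 1)) < rate
    for i in range(n_designates):
        hits = np.flatnonzero(draws[i])
        if hits.size:
            open_frame[i] = hits[0] + 1
    return open_frame


def generate_timeseries(
    tess: CellTessellation,
    t_params: TracerParams,
    ts: TimeSeriesParams,
    rng_seed: int = 0,
) -> Tuple[List[np.ndarray], TimeSeriesTruth]:
    """Tracer time series with growing spots and junctions opening over time.

    Each open junction's spot width grows by ``spot_growth_rate`` px/frame at
    fixed amplitude, so per-spot integrated intensity is nondecreasing.
    """
    rng = np.random.default_rng(rng_seed)
    shape = tess.field.shape
    n_j = len(tess.vertices)
    n_desig = int(np.floor(t_params.permeable_fraction * n_j + 0.5))
    desig = rng.choice(n_j, size=n_desig, replace=False) if n_desig else np.empty(0, int)
    flags = np.zeros(n_j, dtype=bool)
    flags[desig] = True

    theta = rng.uniform(0, 2 * np.pi, n_desig)
    rad = SPOT_JITTER_MAX_PX * np.sqrt(rng.random(n_desig))
    pos = tess.vertices[desig] + np.column_stack(
        [rad * np.cos(theta), rad * np.sin(theta)]
    )
    pos[:, 0] = np.clip(pos[:, 0], 0, shape[1] - 1)
    pos[:, 1] = np.clip(pos[:, 1], 0, shape[0] - 1)
    amp_cap = max(0.95 - t_params.background_level, 0.1)
    amps = _sample_amplitudes(rng, n_desig, t_params, amp_cap)
    open_frame = sample_opening_frames(
        n_desig, ts.junction_opening_rate, ts.n_frames, rng, ts.initial_open
    )

    frames: List[np.ndarray] = []
    counts = np.zeros(ts.n_frames, dtype=int)
    integrals = np.full((ts.n_frames, n_desig), np.nan)
    sigmas = np.full((ts.n_frames, n_desig), np.nan)
    for k in range(ts.n_frames):
        img = np.full(shape, t_params.background_level)
        n_open = 0
        for i in range(n_desig):
            if open_frame[i] < 0 or k < open_frame[i]:
                continue
            sigma_k = t_params.spot_sigma_px + ts.spot_growth_rate * (k - open_frame[i])
            rs, cs, patch = _spot_patch(shape, pos[i, 0], pos[i, 1], sigma_k, amps[i])
            img[rs, cs] += patch
            integrals[k, i] = patch.sum()
            sigmas[k, i] = sigma_k
            n_open += 1
        counts[k] = n_open
        if t_params.background_noise_sd > 0:
            img = img + rng.normal(0.0, t_params.background_noise_sd, size=shape)
        frames.append(np.clip(img, 0.0, 1.0))

    truth = TimeSeriesTruth(
        junctions=JunctionSet(coords=tess.vertices.copy(), permeable=flags),
        designate_indices=desig,
        open_frame=open_frame,
        spot_counts=counts,
        spot_integrals=integrals,
        spot_sigmas=sigmas,
    )
    return frames, truth


# --------------------------------------------------------------------------
# diffusion bound


def free_diffusion_radius(diffusivity: float, elapsed: float) -> float:
    """2-D root-mean-square displacement ``sqrt(4 * D * t)``.

    A sanity bound for spot growth: a tracer diffusing freely (without
    binding to the substrate) would spread this far, orders of magnitude
    faster than bound-spot growth. Units are the caller's (length^2/time
    and time).
    """
    if diffusivity <= 0 or elapsed <= 0:
        raise ValueError("diffusivity and elapsed time must be positive")
    return float(np.sqrt(4.0 * diffusivity * elapsed))
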