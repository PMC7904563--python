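"""End-to-end pipeline: simulate -> segment -> quantify -> summarize.

A single :class:`RunConfig` (YAML-serialisable) drives every stage; every
random choice derives from one global seed, so a run is reproducible
bit-for-bit from its manifest. Stage outputs are cached under the run
directory keyed by a content hash of the stage parameters, so rerunning
with one downstream parameter changed reuses upstream results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as tjio
from .datatypes import JunctionSet
from .quantify import ThresholdParams, quantify_image
from .segmentation import geometric_detector
from .stats import METRICS, compare_conditions, summaries_to_frame, summarize
from .synthetic import (
    FieldSpec,
    RenderParams,
    TracerParams,
    condition_preset,
    generate_tessellation,
    offjunction_count_for_share,
    render_border_channel,
    render_tracer_channel,
)

__all__ = ["RunConfig", "run_pipeline", "compare_runs", "derive_seed"]

log = logging.getLogger("tjperm.pipeline")


def derive_seed(*keys: int) -> int:
    """Stable sub-seed (< 2**31) from a tuple of integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Hierarchical configuration of one pipeline run."""

    out_dir: str = "runs/run"
    seed: int = 0
    condition: str = "untreated"
    n_replicates: int = 3
    n_images: int = 9
    field_size_px: int = 256
    n_cells: int = 60
    relaxation_steps: int = 2
    size_offjunction_to_share: bool = True
    junction_source: str = "geometric"      # geometric | truth
    write_images: bool = False
    render: Dict = field(default_factory=dict)       # RenderParams overrides
    tracer: Dict = field(default_factory=dict)       # TracerParams overrides
    threshold: Dict = field(default_factory=dict)    # ThresholdParams overrides
    distance_threshold_px: float = 2.0

    def __post_init__(self) -> None:
        if self.junction_source not in ("geometric", "truth"):
            raise ValueError("junction_source must be 'geometric' or 'truth'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def tracer_params(self, n_junctions: Optional[int] = None) -> TracerParams:
        params = condition_preset(self.condition)
        if self.tracer:
            params = dataclasses.replace(params, **self.tracer)
        if self.size_offjunction_to_share and n_junctions is not None:
            params = dataclasses.replace(
                params,
                n_offjunction_spots=offjunction_count_for_share(
                    n_junctions, params.permeable_fraction, params.tj_signal_share
                ),
            )
        return params

    def stage_hash(self, stage: str) -> str:
        relevant = {
            "simulate": ["seed", "condition", "n_replicates", "n_images",
                         "field_size_px", "n_cells", "relaxation_steps",
                         "size_offjunction_to_share", "render", "tracer"],
            "segment": ["junction_source"],
            "quantify": ["threshold", "distance_threshold_px"],
        }[stage]
        payload = {k: getattr(self, k) for k in relevant}
        if stage != "simulate":
            payload["upstream"] = self.stage_hash(
                "simulate" if stage == "segment" else "segment"
            )
        digest = hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()
        return digest[:12]


def _simulate_one(config: RunConfig, replicate: int, image: int):
    spec = FieldSpec(
        config.field_size_px, config.field_size_px, config.n_cells,
        rng_seed=derive_seed(config.seed, replicate, image, 0),
    )
    tess = generate_tessellation(spec, config.relaxation_steps)
    render = RenderParams(**config.render)
    border = render_border_channel(
        tess, render, rng_seed=derive_seed(config.seed, replicate, image, 1)
    )
    t_params = config.tracer_params(len(tess.vertices))
    tracer, truth = render_tracer_channel(
        tess, t_params, rng_seed=derive_seed(config.seed, replicate, image, 2)
    )
    return tess, border, tracer, truth


def run_pipeline(config: RunConfig) -> Dict:
    """Execute simulate -> segment -> quantify -> summarize; return the manifest.

    The per-image report table lands in ``<out_dir>/reports.csv``; the
    manifest (parameters, stage hashes, seeds, outputs) in
    ``<out_dir>/manifest.json``. Stage results are cached by parameter hash:
    rerunning after changing only quantification parameters reuses the
    simulated images and detected junctions.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache = out / "cache"
    cache.mkdir(exist_ok=True)
    manifest: Dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    sim_dir = cache / f"simulate_{config.stage_hash('simulate')}"
    seg_dir = cache / f"segment_{config.stage_hash('segment')}"
    qua_dir = cache / f"quantify_{config.stage_hash('quantify')}"

    # ---- simulate ------------------------------------------------------
    sim_done = sim_dir / "DONE"
    regenerated = not sim_done.exists()
    images = {}
    for rep in range(config.n_replicates):
        for img_i in range(config.n_images):
            images[(rep, img_i)] = _simulate_one(config, rep, img_i)
    if regenerated:
        sim_dir.mkdir(exist_ok=True)
        if config.write_images:
            for (rep, img_i), (tess, border, tracer, truth) in images.items():
                stem = sim_dir / f"rep{rep}_img{img_i}"
                tjio.save_image(f"{stem}_border.tif", border)
                tjio.save_image(f"{stem}_tracer.tif", tracer)
                tjio.save_ground_truth(f"{stem}_truth.json", truth)
                tjio.save_junctions_csv(f"{stem}_junctions.csv", truth.junctions)
        sim_done.write_text("ok")
    manifest["stages"]["simulate"] = {
        "hash": config.stage_hash("simulate"),
        "cached": not regenerated,
        "n_images": len(images),
        "dir": str(sim_dir),
    }
    log.info("simulate: %d images (cache %s)", len(images), sim_dir.name)

    # ---- segment -------------------------------------------------------
    junctions: Dict = {}
    for key, (tess, border, tracer, truth) in images.items():
        if config.junction_source == "truth":
            junctions[key] = truth.junctions
        else:
            junctions[key] = geometric_detector(border)
    seg_dir.mkdir(exist_ok=True)
    (seg_dir / "DONE").write_text("ok")
    manifest["stages"]["segment"] = {
        "hash": config.stage_hash("segment"),
        "source": config.junction_source,
        "dir": str(seg_dir),
    }
    log.info("segment: source=%s", config.junction_source)

    # ---- quantify ------------------------------------------------------
    qua_done = qua_dir / "reports.csv"
    if qua_done.exists():
        reports = pd.read_csv(qua_done)
        manifest["stages"]["quantify"] = {
            "hash": config.stage_hash("quantify"), "cached": True,
            "dir": str(qua_dir),
        }
    else:
        t_par = ThresholdParams(**config.threshold)
        rows = []
        for (rep, img_i), (tess, border, tracer, truth) in images.items():
            report, spots, flags, assignment = quantify_image(
                tracer, junctions[(rep, img_i)], t_par, config.distance_threshold_px
            )
            row = report.to_dict()
            row.update(
                condition=config.condition, replicate=rep, image=img_i,
                true_fraction_permeable=truth.fraction_permeable,
                true_tj_share=truth.tj_signal_share,
            )
            rows.append(row)
        reports = pd.DataFrame(rows)
        qua_dir.mkdir(exist_ok=True)
        reports.to_csv(qua_done, index=False)
        manifest["stages"]["quantify"] = {
            "hash": config.stage_hash("quantify"), "cached": False,
            "dir": str(qua_dir),
        }
    reports.to_csv(out / "reports.csv", index=False)
    log.info("quantify: %d reports", len(reports))

    # ---- summarize -----------------------------------------------------
    summaries = summarize(reports)
    summaries_to_frame(summaries).to_csv(out / "summary.csv", index=False)
    manifest["stages"]["summarize"] = {"file": str(out / "summary.csv")}

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def compare_runs(
    run_dirs: Sequence[str],
    pairs: Optional[Sequence[tuple]] = None,
    metrics: Sequence[str] = METRICS,
) -> pd.DataFrame:
    """Cross-run condition comparison from completed runs' report tables."""
    frames = []
    for d in run_dirs:
        path = Path(d) / "reports.csv"
        if not path.exists():
            raise FileNotFoundError(
                f"{path} missing: run the quantify stage for {d} first"
            )
        frames.append(pd.read_csv(path))
    reports = pd.concat(frames, ignore_index=True)
    expected = {"condition", "replicate", *metrics}
    missing = expected - set(reports.columns)
    if missing:
        raise ValueError(f"report tables lack columns: {sorted(missing)}")
    conditions = list(dict.fromkeys(reports["condition"]))
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(conditions) for b in conditions[i + 1 :]]
    return compare_conditions(reports, pairs, metrics)
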