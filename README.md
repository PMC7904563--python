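# tjperm

Spatially resolved quantification of transendothelial macromolecule
transport at **tricellular junctions** — the points where three or more
endothelial cells meet.

In a substrate-binding permeability assay (e.g. FITC-avidin over a
biotinylated matrix), tracer that crosses an endothelial monolayer is
immobilised where it crossed, so a fluorescence image of bound tracer is a
spatial map of transport. Pairing that channel with an immunostained
cell-border channel (e.g. VE-cadherin) lets one ask *where* the transport
happened: at tricellular junctions, at bicellular junctions, or through the
cells. `tjperm` implements the full analysis:

1. **Junction detection** in the border channel — either a trainable
   multi-resolution residual segmentation network optimised with the
   soft-Dice objective (junction pixels are rare, so Dice overlap beats
   pixel-wise cross entropy), post-processed by a watershed split of merged
   detections into centroids; or a deterministic geometric detector
   (border skeleton branch points) that needs no training.
2. **Spot detection** in the tracer channel by adaptive local-mean
   thresholding and 8-connected component labelling.
3. **Association** by the 2-pixel rule: a junction is *permeable* iff its
   centroid lies within 2 px of a pixel of a tracer spot; each such spot is
   assigned to its nearest junction.
4. **Per-image metrics**: the permeable fraction of junctions
   `n_permeable / n_junctions`, total accumulation `sum(I[fg])` (RFU), the
   junction-associated share of accumulation, and the mean accumulation per
   permeable junction.
5. **Condition statistics**: replicate-first averaging (mean ± SEM across
   donors) and pooled-variance Student *t* tests with significance stars.

Because no imaging data are deposited with the study this package models,
it ships a first-class **synthetic monolayer generator**: centroid-relaxed
random tessellations (polygonal cells, border ridges, ground-truth junction
vertices), tracer channels with a controllable permeable fraction and
junction signal share, live-imaging time series with growing spots, and
presets encoding the five study conditions (untreated, S1P, thrombin,
multidirectional shear, uniaxial shear). Every image carries its exact
realised ground truth, so the whole pipeline is validated by parameter
recovery.

## Worked example

```python
from tjperm.synthetic import (FieldSpec, RenderParams, condition_preset,
                              generate_tessellation, render_border_channel,
                              render_tracer_channel)
from tjperm.segmentation import geometric_detector
from tjperm.quantify import quantify_image

spec = FieldSpec(height_px=512, width_px=512, n_cells=100, rng_seed=7)
tess = generate_tessellation(spec, relaxation_steps=2)
border = render_border_channel(tess, RenderParams(), rng_seed=1)
tracer, truth = render_tracer_channel(tess, condition_preset("untreated"), rng_seed=2)

junctions = geometric_detector(border)
report, spots, flags, assignment = quantify_image(tracer, junctions)
```

which prints (via the obvious f-strings):

```
junctions detected:      151 (ground truth 153)
permeable junctions:     58 (38.4%; truth 37.9%)
total accumulation:      455.2 RFU over 67 spots
share through junctions: 85.1% (truth 85.0%)
mean per permeable:      6.68 RFU
```

Read: of 151 detected tricellular junctions, 38.4% show tracer
accumulation within 2 px (the generator's untreated set-point is 38.1%),
and 85% of all bound-tracer signal sits at junction-associated spots —
tricellular junctions dominate transport even though most junctions are
closed.

A command-line interface mirrors the stages
(`tjperm simulate | train | segment | quantify | summarize | compare | run`);
`tjperm run --config cfg.yaml` executes the whole pipeline with caching and
a reproducibility manifest.

## Layout

```
src/tjperm/
  synthetic.py        tessellations, border/tracer rendering, presets, time series
  segmentation/       soft-Dice loss, augmentation, NumPy segmentation network,
                      training + checkpoint selection, prediction, geometric
                      detector, watershed post-processing
  quantify.py         adaptive threshold, spot labelling, 2-px association, reports
  stats.py            replicate summaries, Student t, percent change
  pipeline.py, cli.py orchestration, caching, manifests, CLI
docs/methods.md       model, parameters, numerical choices, limitations
```
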