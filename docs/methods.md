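# Methods

## The measurement being modelled

A confluent endothelial monolayer on a biotinylated substrate is exposed to
a fluorescent avidin tracer; tracer that crosses the monolayer binds the
substrate where it crossed. Imaging bound tracer together with
immunostained cell borders yields, per field, four quantities: the fraction
of tricellular junctions that are *permeable* (show accumulation within a
2-px distance of their centroid), the total bound-tracer accumulation
(RFU), the share of that accumulation associated with tricellular
junctions, and the mean accumulation per permeable junction. `tjperm`
implements this measurement and a synthetic generator with exact ground
truth to validate it.

## Synthetic monolayer generator

**Geometry.** Cell layouts are Voronoi tessellations of uniformly random
seed points, with the field boundary enforced by mirroring seeds across the
four field edges (every in-field cell is then bounded, and cells are
clipped exactly at the boundary). Lloyd (centroid) relaxation — default 2
steps — rounds cells toward the fairly regular polygons of a confluent
endothelial monolayer; the step count is exposed. Ground-truth tricellular
junctions are the interior Voronoi vertices incident to ≥ 3 cells; vertices
closer than 2 px are merged into a single junction (a ≥ 4-cell meeting
point is one junction). The generator refuses fields whose mean cell
diameter would fall below 4 px.

**Border channel.** Edges are rasterised as ridges: any pixel whose centre
lies within `border_width_px / 2` (default 3/2 px) of an edge segment gets
`border_peak_intensity` (default 0.8), followed by Gaussian blur (default
σ = 1 px) and additive Gaussian noise (default SD 0.02). Intensities live
in [0, 1] internally and are quantised to 8/16-bit only on export, which
decouples the mathematics from bit depth.

**Tracer channel.** `round(permeable_fraction × n_junctions)` junctions are
drawn without replacement and receive a Gaussian spot (default σ = 1.5 px,
amplitude ~ N(0.45, (0.2·0.45)²) clipped to a detectable floor and a cap
that keeps background + peak ≤ 0.95). Spot centres are jittered uniformly
within 1 px of the junction centroid, which keeps every generated junction
spot inside the 2-px association radius by construction. Off-junction
spots (bicellular / transcellular routes) are placed on edges or in
interiors at > 5 px from every junction centroid so their ground-truth
labels are unambiguous. Off-junction amplitudes are then scaled so the
realised junction-associated share of above-background signal equals
`tj_signal_share` exactly; the returned ground truth records the realised
per-spot discrete integrals, counts and share.

The default `n_offjunction_spots = 12` reflects how off-junction
accumulation looks in this assay: a handful of spots comparable in
brightness to junction spots, not a large population of barely-visible
ones. For studies that vary the share set-point,
`offjunction_count_for_share()` sizes the count as
`n_perm · (1 − s) / s`, which keeps off-spot amplitudes near the common
amplitude mean for any share; without this, extreme set-points would force
off-spot amplitudes either far below any plausible detection floor or
above the [0, 1] intensity range.

**Condition presets** encode the five study conditions through three
set-points: the permeable fraction (untreated 0.381, S1P 0.203, thrombin
0.473, multidirectional 0.407, uniaxial 0.289), the junction signal share
(0.82–0.87), and a per-junction amplitude scale (thrombin ×1.25,
uniaxial ×0.69, others ×1).

**Time series.** Designated-permeable junctions start closed (optionally
open) and open independently with probability `junction_opening_rate` per
frame; opened junctions stay open, and an open spot's σ grows by
`spot_growth_rate` px/frame at fixed amplitude, so per-spot integrated
intensity and spot count are nondecreasing. `free_diffusion_radius(D, t) =
√(4Dt)` is provided as the documented sanity bound: unbound tracer would
spread to a ~350 µm radius within minutes (e.g. D = 4.2×10⁻⁷ cm²/s for
12 min), orders of magnitude beyond observed bound-spot growth, which is
why growing-but-small spots indicate binding near a persistent opening.
Both the diffusivity and the formula's inputs are caller-supplied; no
diffusivity is hard-coded.

**What the generator does not emulate:** realistic point-spread functions
(blur is plain Gaussian), 3-D structure, uneven illumination, staining
artefacts, cell motion, or any mechanistic link between shear/agonist and
junction state (presets encode measured output statistics only). Passing
tests therefore demonstrate correctness of the *analysis* under controlled
geometry and noise, not performance on real micrographs.

## Junction segmentation

**Network.** A multi-resolution residual refinement network implemented
directly in NumPy: a 3×3 stem, one residual block (two 3×3 convolutions
with ReLU and identity skip) per resolution level at strides 1/2/4/…
(default 4 levels), and a top-down decoder that upsamples, sums with the
skip feature and fuses with a 3×3 convolution, ending in a 1×1 sigmoid
head. Forward/backward passes use im2col convolutions; gradients were
verified against central differences (relative error ~2×10⁻⁷). Adam with
configurable weight decay is the only optimiser.

**Objective.** Junction pixels are vastly outnumbered, so training
minimises `1 − softDice`, with `softDice = (2Σpg + ε)/(Σp + Σg + ε)` and
ε = 1 in numerator and denominator (the standard smooth form; ε also
defines the empty-vs-empty case as perfect overlap).

**Training defaults** mirror the full-scale recipe: input 256 px, batch 32,
learning rate 1e-5, 3×3 filters, stride 1, 128 channels, Adam, weight
decay 0, 320 epochs. All of it is overridable;
`SegmenterConfig.desk_scale()` is the CPU schedule used by the tests:
64-px crops, batch 8, 8 channels, 3 levels, learning rate 1e-3, a few
hundred updates. On ~200 augmented synthetic 256² pairs this reaches
held-out soft Dice ≈ 0.83 and centroid F1 ≈ 0.97 in under two minutes on
one CPU.

**Augmentation** is the deterministic orbit of grid crops × rotations
{0°, 90°, 180°, 270°} × horizontal flip (8 variants per crop with
everything enabled), applied identically to image and label; seeded
brightness/contrast jitter perturbs the image only.

**Checkpoint selection.** The held-out loss is evaluated every 25 updates
(resolving a minimum near update ~300 at desk scale and ~3000 at full
scale); the selected checkpoint minimises a centred 5-point moving average
of that curve (ties → earliest), since the raw curve is noisy. Selection
uses the held-out split throughout. On deliberately tiny training sets the
curve shows the classic overfitting signature — a held-out minimum well
before the final update while train loss keeps falling — and the selector
picks near that minimum.

**Post-processing.** Probability maps are thresholded at 0.5 (default);
the foreground's negated Euclidean distance transform is watershed-split
from regional-maximum seeds at least one junction radius apart, splitting
blobs where two junctions merged; region centroids closer than 3 px are
merged; regions under 2 px are dropped as speckle. A uniform-size binary
map (default 3-px disk per centroid) is emitted alongside, treating every
junction as the same size.

**Geometric detector.** An independent, training-free path: Otsu
threshold → skeletonise → branch points (skeleton pixels with ≥ 3 skeleton
neighbours) → cluster-merge within 2.5 px. Because lookup-table thinning is
not 90°-equivariant, thinning runs in all four right-angle orientations
with the branch points pooled before clustering, making detection exactly
invariant under 90° image rotation; inputs are quantised to 16-bit levels
first so float-rounding differences cannot flip threshold decisions. On
noiseless renderings it achieves recall ≥ 0.95 and precision ≥ 0.98
against generator ground truth, and serves both as the test oracle for the
trained model and as a fast junction source in quantification-only runs.

## Tracer quantification

**Adaptive threshold.** A pixel is foreground iff
`value > localMean · (1 + k)` with `k = 2·(1 − sensitivity)` (default
sensitivity 0.5 → threshold at twice the local mean) and the local mean a
Gaussian-weighted average with neighbourhood ≈ image_size/8 (σ =
neighbourhood/6). The inequality is strict, so a constant image has empty
foreground. The multiplicative form keeps the false-positive rate on
Gaussian background noise negligible (the default sits ≈ 5 noise SDs above
the background mean at the generator's defaults) while covering ≥ 90 % of
each spot's half-maximum support. A hysteresis variant (grow supports to a
lower threshold) was evaluated and rejected: grown supports merge adjacent
junction/off-junction components into single spots and bias the
junction-share estimate upward.

**Spots** are 8-connected components of the foreground; per spot the pixel
list, the unweighted centroid, and the integrated intensity (sum of
*original* pixel values — raw, not background-subtracted, matching the
total-accumulation definition) are recorded.

**Association (2-px rule).** A junction is permeable iff the Euclidean
distance from its centroid to the nearest spot pixel centre is ≤ 2 px
(inclusive; distances in continuous coordinates). A spot within threshold
of several junctions makes each of them permeable but contributes its
intensity once, to the nearest junction (ties → lowest junction index).
Images with zero detected junctions are rejected rather than reported as
zeros, avoiding silent division artefacts.

**Recovery performance.** With ground-truth junctions supplied, estimates
track realised truth to within ±0.05 (typically ±0.03) for permeable
fractions 0.2–0.6 and shares 0.5–0.85 on 512² fields of ~100 cells; the
residual positive bias comes from spots of near-neighbour junctions
(5–8 px apart) touching, which mirrors the resolution limit of the real
measurement.

## Condition statistics

Image reports are averaged within each replicate (donor) first; condition
summaries are mean ± SEM over replicate means (SEM = sample SD/√n). The
between-condition test is the classical pooled-variance Student unpaired
*t* (not Welch), two-sided, df = nₐ+n_b−2; stars use strict thresholds
(* p<0.05, ** p<0.01, *** p<0.001, so p = 0.05 exactly is "ns"). Zero
pooled variance with equal means returns p = 1; with unequal means the
result is flagged degenerate. No multiple-testing correction is applied.
Percent change is `100·(treated − reference)/reference`.

## Pipeline and reproducibility

Every random draw derives from one global seed through
`SeedSequence`-based sub-seeds keyed by (seed, replicate, image, stage), so
a run is bit-reproducible and any single image can be regenerated in
isolation. Stage outputs are cached under the run directory keyed by a
hash of the stage's parameters plus its upstream hash; changing only a
downstream parameter (e.g. the association distance) reuses the simulated
images. The manifest records config, stage hashes and outputs.

The end-to-end condition study in the tests and the acceptance script uses
3 replicates × 9 images per condition at 256² / 60 cells with the
geometric junction source — sizes chosen to keep the whole study at a few
seconds per condition while leaving ~100+ junctions per field; the
detector and recovery studies use 512² / ~100 cells. The desk-scale
training schedule is stated above.

## Known limitations

- The network is CPU-oriented NumPy; full-scale (128-channel, 12k-update)
  training is supported in configuration but impractical without
  acceleration.
- The segmentation prediction is only approximately rotation-equivariant
  (learned, not architectural); exact 90° invariance holds for the
  geometric detector path.
- Spots of junctions closer than ~8 px can merge into one connected
  component; the association rule still flags both junctions but the
  intensity is attributed to the nearer one.
- The generator's set-point for the junction signal share is achieved
  exactly only while the amplitude cap does not bind; the returned ground
  truth is always the realised value, and consumers should compare against
  that.
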