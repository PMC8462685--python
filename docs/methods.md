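# Methods

This note records the models, conventions and design choices behind
`madmdet`, in the order data flows through the package.

## Coordinate and class conventions

Boxes are 0-based and half-open (`[x_min, x_max) × [y_min, y_max)`), so
`area = (x_max − x_min)(y_max − y_min)` with no off-by-one corrections.
VOC-style XML (1-based inclusive, the LabelImg dialect) is converted on
read/write (`x_min ← xmin − 1`, `x_max ← xmax`).  Annotation CSV rows are
`image_path,x1,y1,x2,y2,class_name`; detection rows append a confidence.

Three class schemes are supported: two color-independent classes
(`neuron`, `glia`), six classes ({red, green, yellow} × {neuron, glia}),
and seven (six plus `glia_cluster`).  Mapping into the two-class scheme
drops the color; `glia_cluster` has no counterpart outside the seven-class
scheme and mapping it elsewhere is an error.

Centroid-style annotations become fixed-size square boxes.  The side length
is configurable with a 20 µm default (converted through the image's pixel
size) — roughly a soma diameter with margin at 10× magnification; the
choice matters only for annotation import, not for the synthetic truth.
Boxes at image borders are clipped rather than shifted, keeping the box
centered on the cell.

## Synthetic scenes

The generator emulates the image properties that drive errors in this
problem, not microscope optics.  All geometry is parameterized in µm and
scaled by `pixel_size` (default 1 µm/px so area arithmetic is transparent).

* **Neurons**: soft-edged bright discs (soma radius 2.2–3.0 µm, peak ≈215
  of an 8-bit range) with 1–3 thin processes 6–12 µm long.  Above-background
  footprint ≈40–150 µm².
* **Glia**: flat-topped, radially modulated plateaus (peak ≈115, soft edge
  1.2 µm) — larger, fuzzier and lower-contrast than neurons.  The arbor
  radius default (25.4 µm) was set by measuring the mean above-background
  footprint of rendered singletons with the same adaptive threshold and
  morphology the counting stage uses (`calibrate_cell_area`), targeting the
  2000 µm² per-cell quantum; the shipped default measures ≈1994 µm² over
  50 cells.  The flat-top profile makes the footprint insensitive to the
  exact threshold, which is what keeps area-based counting stable between
  the singleton calibration context and the in-cluster context.
* **Clusters**: ≥2 glia placed chain-wise at center spacing 1.8–1.96 arbor
  radii, so adjacent members overlap slightly (a few percent of their area)
  and the summed intensity is elevated in the overlap.  The ground-truth
  cluster box is the union footprint's tight box dilated by 5 px — a loose
  box, as a human annotator would draw.  A cluster flagged `saturated` has
  its accumulated signal scaled until its peak exceeds the intensity
  ceiling; after quantization those pixels sit exactly at the ceiling.
  Unsaturated content is quantized into `[0, ceiling − 1]`, so a scene
  contains ceiling-valued pixels if and only if a saturated cluster put
  them there — an exact, testable invariant.
* **Colors**: red cells render only into the RFP channel, green only into
  GFP, yellow into both; the DAPI channel receives soft-disc nuclei at a
  configurable density (default 1.5·10⁻⁴ /µm²) everywhere, independent of
  the reporter labels, plus the common background (level 8, Gaussian noise
  SD 3 on the 8-bit scale).

Scenes are pure functions of their config (which embeds the seed): the same
config is bit-identical, and the returned truth carries per-record footprint
areas and per-cluster member counts.  Individual-cell truth boxes are the
tight boxes of the rendered above-background footprint (background level +
2 SD), which is the box a detector judged at IoU 0.5 should reproduce.
Object placement is rejection sampling with exclusion radii; impossible
requests raise instead of silently dropping objects.

What the generator does **not** model: 3-D structure, PSF/shot-noise
optics, autofluorescence, touching cells of different classes, annotation
noise.  Passing tests on these scenes therefore demonstrate the correctness
of the workflow's logic (augmentation algebra, merging semantics, counting
arithmetic, metric construction) and the internal consistency of the
calibrated renderer — not detection performance on real tissue.

## Augmentation

`color_swap` exchanges channels 0 and 1 and relabels red ↔ green (cluster
member counts included); it is an exact involution and never touches boxes.
`saturate` computes `min(ceil(pixel × factor), ceiling)` with factor
default 1.5.  The ceiling is applied after rounding the scaled value toward
+∞, a declared convention (the rounding mode is not fixed by the physics);
the operator is pixelwise monotone and only brightens, so factors < 1 are
rejected.  `expand_dataset` emits original/swap/saturate/swap+saturate
variants (4× with both enabled, 2× with one) with provenance tags.
Classical geometric augmentation is deliberately out of scope: it is
standard detector-training machinery, not part of this workflow's logic.

## Detection

The pipeline is detector-agnostic: anything that maps an image to a list of
(box, label, confidence) under a declared scheme satisfies the contract,
and serialized predictions of an external model are ingested (and
validated) from detection CSV.  `zero_center` provides the standard
per-channel mean-subtraction preprocessing for trained models.

The shipped reference detector is classical and deterministic: per reporter
channel, foreground is `intensity > mean + k·SD` (k = 2) with background
statistics refined once by excluding first-pass foreground; connected
components (8-connectivity) of the combined foreground above 25 µm² become
candidates; a component is yellow when both channel means inside it exceed
their thresholds, otherwise it takes the dominant channel's color;
phenotype is by area (≥500 µm² → glia; ≥3500 µm² → cluster, in the cluster
stream); confidence is peak intensity over the ceiling.  The detector is
exactly channel-symmetric, so swapping GFP/RFP swaps red/green labels and
changes nothing else — a property the tests check exactly.  DAPI is never
an input to detection, the configuration found to work best for this
problem.  The area split points are renderer-matched conveniences of the
reference detector, not claims about real data.

## Merging

Rules (i)–(iii) with thresholds 0.5/0.3 (strict comparisons — "above") and
redundancy measured as intersection over the **smaller** box's area with a
strict 0.5 default (IoU is available as a config alternative).  Overlap in
rule (ii) means any positive intersection area: cluster boxes are loose, so
center tests would miss peripheral members.  Rule-(iii) suppression is
greedy by confidence with deterministic tie-breaks (larger area, then input
order).  Neurons are never removed.  Ground truth is merged with identical
logic at confidence 1.0, and absorbed ground-truth glia increment the
cluster's per-color member counts.

Two choices here are the package's own, made where the rule text alone is
ambiguous:

* A cluster kept through rule (ii) records its absorbed glia as
  `evidence` — on every overlapping surviving cluster, not only the
  best-overlap owner.  Recorded evidence still counts as rule-(ii) support,
  which makes merging a fixed point under re-application (otherwise a
  supported cluster would lose its support the moment the support is
  absorbed).  The provenance sidecar names the single best-overlap owner.
* Monotonicity of the surviving-cluster count in `t_high` is not a theorem
  for any suppression-style rule (iii): dropping a high-confidence cluster
  that suppressed two mutually non-overlapping duplicates can raise the
  count.  The property holds throughout the seeded random instances the
  tests generate; it is checked there as a behavioral regression, not
  asserted as a law.

## Counting

Per surviving cluster and per reporter channel: background statistics come
from pixels outside **all** object boxes in the patch; detected-neuron
boxes inside the cluster are masked out before computing in-cluster
statistics (masking first, then thresholding — removing bright neuron
pixels lowers the threshold slightly, which is the intended behavior of
estimating glia-only statistics); threshold
`½(mean_BKG + mean_cluster) + ½(SD_BKG + SD_cluster)`; binary mask; opening
then closing with a disc of radius 2 µm scaled to pixels (removes speckle
without erasing processes); per-pixel color partition (above threshold in
both channels → yellow, else the single positive channel — mirroring the
generative definition of yellow); per-color area in µm²;
`n̂ = round(area / 2000 µm²)` with round-half-away-from-zero (a half-cell
blob more plausibly represents one dim cell than none; configurable).
Degenerate inputs: an empty background set raises with instructions to use
a larger patch; a constant image yields a threshold equal to its mean and
an empty mask (no pixel is strictly above); clusters partially outside the
image are clipped with a flag in the result.

Counting quality is RMSE over matched clusters.  In the pipeline,
estimated clusters are paired with ground-truth clusters by >0.5
smaller-box overlap; unmatched estimates contribute nothing, and in the
acceptance computation a missed cluster is scored as estimate 0 (a full
error) rather than skipped.

## Evaluation

Greedy confidence-ranked matching per class: each prediction claims the
unmatched ground-truth box of highest IoU if that IoU is strictly above 0.5;
second hits on an already-claimed object are false positives.  Ties in
confidence are broken by stable input order.  P, R and F₁ use the standard
formulas with zero conventions for empty denominators.  AP accumulates
cumulative P/R pairs at every rank, replaces each precision with the
maximum precision at equal-or-higher recall, and integrates the step
function over recall from 0 to the maximum achieved recall (all-point
interpolation; no 11-point sampling, no multi-IoU averaging).  The
multiclass score is the unweighted mean of per-class APs over classes with
ground truth.  Workflow F-scores are computed after filtering predictions
at confidence > 0.5, the display threshold.

## Pipeline

Stage order is fixed: simulate/load → (augment) → detect cells → detect
clusters → merge → count → evaluate.  Scene seeds are derived from the
global seed via a seed sequence, so a run directory (images, detection and
merged CSVs, per-cluster counts, evaluation JSON, stage log, provenance
with config hash/seed/version) can be re-created bit-identically.
Training-set export tiles images on a grid (default 512 px; the tile size
of the original acquisitions is not fixed by the problem), assigns each box
to the tile containing its center (clipping boxes that straddle borders),
and drops annotation-free background tiles unless asked to keep them.

Problem sizes in the tests and the acceptance script — 1000 random
instances for the AP oracle, 300 for the merging oracle, 27 clusters of
2–10 members for count recovery, 10 sparse scenes (60 cells) for detection
quality — were chosen as the sizes at which these checks are already
exhaustive of the behavior they probe while keeping the default run quick.

## Known limitations

* The reference detector is a desk-scale stand-in: it shares none of a
  trained network's failure modes (it is essentially noise-free on the
  synthetic renderer it was calibrated against) and its accuracy numbers
  say nothing about real tissue.
* Area-based counting assumes the calibrated per-cell footprint; strongly
  saturated clusters inflate the above-threshold area and bias counts
  upward, which is inherent to the area quantum approach.
* No instance segmentation inside clusters: resolving individual somas is
  explicitly beyond this workflow.
* Cross-validation harnesses, network training, and GUI annotation tools
  are out of scope.
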