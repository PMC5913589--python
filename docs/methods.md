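# Methods

## The measurement model

The package treats a plant's drought response as two observable geometric
signals in projected (2-D) silhouette space:

1. **Leaf-rolling** narrows the silhouette. A narrower silhouette keeps
   most of its boundary length while losing area, so the perimeter/area
   ratio (PAR) rises; it fills less of its bounding rectangle and convex
   hull, so TBR and TCR fall. All three descriptors are dimensionless
   pixel-count ratios; no metric calibration is attempted because ratios
   cancel the scale.
2. **Senescence** recolors tissue from green to yellow without changing
   geometry. GPAR — the green share of plant pixels — isolates this
   signal. Yellow is separated from green by the two-gate rule on
   chromaticity indices: a greenness pixel needs ExG = 2Ng − Nr − Nb above
   a threshold *and* ExR = 1.4Nr − Nb below one. Yellow tissue passes the
   ExG gate (≈ 0.5 for saturated yellow) but fails the ExR gate (≈ 0.7),
   which is why a single ExG threshold cannot measure stay-green.

Assumptions: the background is chromatically separable from vegetation;
one plant (or one plot) per image; 8-bit channels; illumination constant
enough that fixed thresholds hold across a time series.

## Pipeline conventions

* **HSI transform.** Several incompatible "HSI" definitions circulate; the
  package fixes the arccos formulation (I = (R+G+B)/3 on the 0–255 scale,
  S = 1 − 3·min/(R+G+B), H = θ or 360° − θ when B > G, achromatic pixels
  assigned H = 0). The choice round-trips 8-bit RGB within ±1 level, which
  the suite verifies.
* **Black pixels** (R+G+B = 0) get Nr = Ng = Nb = 0, hence ExG = ExR = 0
  and S = 0: black is background on both rigs, and the convention makes
  background blanking idempotent with respect to segmentation.
* **Edge count.** The perimeter is the number of true pixels with at least
  one false 4-neighbor, image border counted as background. This is
  deterministic and parameter-free; an 8-neighbor boundary definition
  would differ by a few percent on diagonal edges, which is a known
  convention risk when comparing absolute PAR values across
  implementations (ratios within one implementation are unaffected).
* **Bounding rectangle** is axis-aligned with inclusive pixel endpoints
  (width = x_max − x_min + 1).
* **Convex hull area is a pixel count**, not a polygon area: the number of
  pixel centers inside or on the hull of the true-pixel centers, ties
  broken toward inclusion (tolerance 1e−9 px). Collinear masks degrade to
  the rasterized segment. A brute-force all-pairs half-plane oracle backs
  this in the tests.
* **Region filter** uses 8-connected components (4-connectivity would
  detach diagonal leaf tips).
* **Multiview averaging** drops views whose segmentation is empty rather
  than zero-filling them — a zero ratio is not a feature value — and
  reports the contributing-view count.
* **Field mode** gates vegetation on ExG > threshold instead of hue
  (paddy water and wet soil defeat hue gates) and computes PAR on image
  rows 0 .. floor(height/3) − 1. The top third is taken as *image* rows,
  not plant-height fraction. Plot GPAR is computed on the full image; if a
  deployment crops it, the same crop should be applied consistently.
* All index planes are double precision; nothing is quantized before
  thresholding.

## Segmentation defaults

| parameter | default | meaning |
|-----------|---------|---------|
| h_min, h_max | 50°, 180° | hue gate spanning yellow-green through cyan-green |
| s_min | 0.15 | rejects gray/achromatic background |
| i_min, i_max | 20, 255 | rejects near-black pixels |
| min_region_area | 50 px | speck/noise component removal |
| exg_threshold | 0.10 | greenness requires ExG above this |
| exr_threshold | 0.10 | greenness requires ExR below this |

These are rig-specific conventions, not universal constants; every real
deployment should calibrate them on its own background and palette. The
defaults are chosen so the synthetic palette is classified unambiguously:
saturated yellow sits at hue ≈ 57°, so the hue gate opens at 50° — a gate
starting at 60° would cut senescent tissue out of the *plant* mask and
corrupt GPAR's denominator.

## Time-series analytics

The first derivative is the plain difference d_i = X_i − X_{i−1} indexed
by the later day. Gaps are never interpolated — derivatives across a
missing day are missing — because interpolation would invent exactly the
dynamics the derivative is meant to detect; the intended sampling is dense
(daily or sub-daily).

Rolling onset is called from the derivative extremum of each shape
descriptor (peak for PAR, valley for TBR/TCR). The three candidates vote;
the majority wins and ties fall to the PAR candidate, PAR being the most
robust and sensitive descriptor of the three — TBR and TCR respond to any
change of the enclosing box or hull (a single wind-bent leaf moves both),
while PAR responds to boundary-to-area structure. GPAR is excluded from
the vote: it tracks senescence, which need not coincide with rolling. An
all-flat series returns an explicit no-onset result rather than an index.

One-way ANOVA is computed from the classical sums of squares with
df = (k − 1, N − k) and the upper-tail F p-value. When within-group
variance is exactly zero with distinct means, F is reported infinite with
p = 0 and a degenerate flag, rather than raising — constant groups do
occur with quantized features at tiny n. Pearson correlation drops
incomplete pairs pairwise and refuses zero-variance input.

## The synthetic generator

Each plant is a fan of quadratically curved, tapering leaves rendered by
stamping disks along Bézier centerlines — integer rasterization from a
single seeded generator, so output is bit-identical across platforms.
Controls map one-to-one onto the phenomena:

* `leaf_width` (default 12 px) → rolling; time courses narrow it.
* `green_fraction` (default 0.95) → senescence, applied from the leaf tips
  inward (tips yellow first), giving pixel-exact ground truth for GPAR.
* `speck_count`/`speck_size` (default 0, 5 px) → green debris off the
  plant, removed by the region filter.
* `drought_schedule()` builds a 13-day stress course: width constant
  before the onset day, roughly half the total decline on the onset day
  itself (visible rolling is abrupt), then a linear tail; greenness
  declines linearly from onset; optional rehydration reverses both.
  Day-to-day leaf sway (σ = 1.5°) adds realistic jitter to the series.
* `discrimination_cohort()` renders exchangeable groups before stress;
  after stress, resistant plants roll hard (width 12 → ~6 px) with mild
  senescence (green fraction −0.10), sensitive plants barely roll
  (≤ 1 px) but senesce strongly (−0.42).

What the generator does **not** emulate: 3-D leaf geometry and
self-occlusion, lighting and shadow, soil texture, panicles, overlapping
neighbors beyond simple compositing, and camera noise. Passing tests
therefore demonstrate that the *feature arithmetic and detection logic*
are correct under controlled conditions where the silhouette and palette
are known, not that segmentation thresholds transfer to any particular
rig; threshold calibration against real backgrounds remains the user's
task.

## Problem sizes and tolerances

The suite and the acceptance script run at desk scale, chosen to exercise
every code path with comfortable statistical margins: 160×160-pixel
plants, a ten-level width sweep, 50 thirteen-day series for onset
recovery (±1 day, ≥ 90% required), 20 + 20 plants for the discrimination
rehearsal, 200 random masks (≤ 20×20) for oracle equivalence with zero
tolerated discrepancies, and 1,000 replicates for the ANOVA type-I-error
check (5% ± 2%). Hand-computed index values are asserted to 1e−12;
GPAR-vs-ground-truth comparisons use ±0.02 to absorb the rounding of the
yellow-pixel count. Before-stress ANOVA p-values in the cohort are
null-distributed by construction, so the minimum across the four features
fluctuates run to run like any order statistic of four uniform draws.

## Known limitations

* The edge count and hull rasterization conventions are fixed choices
  among several defensible ones; absolute PAR/TCR values are comparable
  only within a single convention.
* Field GPAR assumes the ExG gate cleanly separates vegetation from
  background; heavy algal water or yellow stubble would need re-tuned
  thresholds or a different gate.
* Onset detection reports a single global extremum; multi-episode stress
  (roll, recover, roll again) yields only the strongest episode.
* No instance separation inside field plots: plot features are
  population-level by design.
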