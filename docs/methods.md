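# Methods

This note documents the models, parameter choices and numerical decisions
behind `metacad`, and what its synthetic experiments can and cannot show.

## Synthetic scene model (`metacad.synth`)

Each ROI is an 8-bit single-channel image, by default 872×512 px (one
quarter, linearly, of the 3488×2048 field of the scanner this emulates; the
features are scale-covariant, so the reduced raster changes magnitudes but
not the comparisons). A scene is composed of:

* **Chromosomes** — bent rods: all pixels within `width/2` of a two-segment
  polyline, length 10–30 px, width 3–6.5 px, bend 0–1 rad, uniform random
  orientation. In a *single-spread* (analyzable) scene, chromosomes are
  placed with a Gaussian scatter (σ = spread/2.5, hard-capped at the
  spread radius, default spread 100 px) around the cluster center and are
  forbidden to touch, so connected-component labeling recovers each one.
  In *overlapped-spread* scenes two or three clusters are placed with
  centers mutually closer than the spread and touching is allowed, so
  chromosomes merge into fewer, larger regions — exactly why such fields
  defeat region counting in practice.
* **Interphase nuclei** — disks, radius 7–40 px drawn from a right-skewed
  Beta(1.2, 3.5) law: marrow fields are dominated by small cells, large
  nuclei are rare. Placed anywhere in the field, non-touching.
* **Debris** — small bright rods (length 5–12 px) standing in for stain
  precipitate and chromatin fragments, which real slides always carry.
  Debris shifts region counts modestly and similarly in every class but
  adds many small regions, strongly perturbing the mean-type features;
  omitting it makes every mean feature an implausibly perfect classifier.

Intensities follow the contrast ordering of the imaging problem: background
20, nuclei 80–120, chromosomes and debris 150–230 (8-bit levels). A
per-scene base level (staining/illumination) is drawn first and individual
objects jitter around it by at most ±12 levels. Pixel noise is additive
Gaussian, σ = 5, clipped to [0, 255].

The dataset generator fixes the class design of the emulated study — 67
analyzable and 133 unanalyzable fields, the latter split 80/20 between
interphase-only and overlapped scenes — and randomizes per scene: countable
chromosomes per spread 30–46 (slide preparation breaks and clumps part of
every spread), nuclei per field 1–10 (interphase-only) or 0–8 (fields with
spreads; cellularity does not depend on whether a spread is present),
debris load 0–35, clusters 2–3 with per-scene spread 70–120 px for
overlapped fields. Per-scene seeds derive from the master seed via
`SeedSequence`, so a dataset is reproducible bit-for-bit.

**What passing tests do not show.** The generator reproduces the *geometry
and contrast structure* of the detection problem, not its photometric
detail: no banding, focus blur, illumination gradients, sensor artifacts,
or touching-chromosome splitting. Results on it validate the pipeline's
statistics and the qualitative feature ranking, never absolute performance
on real slides.

## Segmentation (`metacad.segment`)

Foreground is "strictly above a global threshold", Otsu by default.
Single-stage Otsu provably mis-splits when bright objects cover a tiny
fraction of the field (the between-class criterion then peaks inside the
background noise); if the foreground fraction exceeds `max_foreground`
(default 0.25) the threshold is re-estimated by Otsu on the pixels above
the first split. Components are 8-connected by default (4-connectivity via
config) and components under `min_area` = 20 px are dropped as speckle
(scale this with the square of the linear image scale). Region gravity
centers are unweighted pixel centroids; coordinates are 0-based (row, col)
with pixel centers at integers.

## Features (`metacad.features`)

Circularity places the equal-area circle at the region's centroid (the
placement that makes a disk score ≈ 1) and counts region pixels whose
centers fall within the radius — a discrete overlap consistent with the
discrete area. All standard deviations are population (÷N) values, so a
single-region image has SD 0 rather than a missing value. The global
gravity center is area-weighted (equivalently, the centroid of the union of
labeled pixels); a plain mean of region centroids is available via config.
An image with no surviving regions reports `n_regions = 0` and NaN for the
other eight features, which downstream statistics drop pairwise.

## ROC analysis (`metacad.roc`)

Continuous scores are reduced to 10 ordinal categories at pooled-score
quantiles (duplicate boundaries collapse with a warning). The binormal
likelihood is maximized over (a, log b, first cutpoint, log-increments)
with L-BFGS-B from three slope initializations (b₀ ∈ {0.7, 1, 1.4}, the
intercept initialized from the empirical AUC); bounds cap |a| at 5 and
log b at ±2.5. Empty cells receive a 0.25 continuity correction and such
fits carry a `degenerate` flag — a perfectly separated sample therefore
yields a finite, slightly shrunken AUC rather than a crash. The
convergence flag requires the per-observation gradient norm to fall below
1e-4; tighter thresholds sit below finite-difference noise and misflag
converged fits. `se_auc` comes from the observed information (numerical
Hessian) through the delta method on AUC(a, log b).

Feature orientation (which tail means "analyzable") is chosen on the first
half of each class's images so the choice cannot inflate the AUC of an
uninformative feature, and is recorded in the report. Screening keeps
features with AUC ≥ 0.55 ("at or near 0.5 is no better than random"; the
floor is configurable). Pairwise tests use fully-paired DeLong covariance —
appropriate because every feature scores the same images — with a seeded
case-resampling bootstrap available via config. No multiple-testing
correction is applied to the pairwise table, matching the reporting style
this package emulates.

## Two-level classifier (`metacad.classifier`)

Level one: a feed-forward network with one hidden layer of 5 logistic
units on standardized (mean area, mean intensity, SD of region distance).
Cross-entropy is minimized with full-batch L-BFGS (max 2000 iterations,
L2 penalty 1e-2): at 200 rows and 3 inputs this converges reliably where
first-order methods with early stopping underfit. Five independently
initialized networks are averaged to damp initialization variance; the
training sample is class-balanced by oversampling the minority class,
because the minimum rule can lower but never raise a score — an
under-scored true positive is unrecoverable downstream. Everything is
deterministic given the seed.

Level two: the region count is min–max normalized against the training
data (clipped at inference; degenerate bounds map to a constant 0.5 with a
flag), and — for the same comparable-scale reason — the network output is
rank-calibrated by the empirical CDF of its training scores before fusion.
The fused score is the minimum of the two.

Evaluation uses stratified 5-fold cross-validation repeated 3 times with
different partitions, averaging the per-image out-of-fold scores (the mean
of minima never exceeds the minimum of means, so the fused-score dominance
invariant survives averaging). Resubstitution figures are reported
separately and labeled as such, since the emulated study does not state
which protocol produced its classifier figure.

## Workbench and determinism

`run_experiment` derives fixed per-stage seed offsets from the master seed,
so stages can be rerun in isolation and two runs of the same configuration
produce byte-identical CSV artifacts. The redundancy rule for the off-line
recommendation walks retained features in descending AUC and keeps a
feature only if its |Pearson r| with every already-kept feature is below
0.5.

## Problem sizes used in the test suite

The validation suite fits binormal models at n = 5000/class (against the
closed form) and n = 200/class (against the Mann–Whitney AUC), checks
DeLong's type-I error on 500 null replicates at the study's 67/133 design,
and runs the full synthetic experiment at its default 200-scene size, with
20 replicate seeds for the fusion-dominance property. Unit tests use
quarter-scale scenes with proportionally smaller objects.

## Known limitations

* The generator's realism gaps listed above; in particular real overlapped
  spreads produce both higher *and* lower counts than single spreads, and
  the generator reproduces this only through merging.
* The binormal fit is not a re-implementation of any particular legacy
  ROC program; on heavily tied or tiny samples the quantile categorization
  (not the likelihood) dominates estimation error.
* DeLong assumes fully paired designs; truly partially-paired data would
  need the bootstrap path.
* The ANN stage is a deliberately small model; with many more images a
  validation-based architecture search would be warranted.
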