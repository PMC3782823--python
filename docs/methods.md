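# Methods

This note documents the models, parameters and design choices behind
`mammogc`, and what the synthetic-phantom validation does and does not show.

## Pipeline overview

A mammogram passes through: breast-profile binarization → background/label
cleanup → crop to the region of interest → block-mean downsampling →
median enhancement → orientation normalization → pectoral-muscle removal →
seeded multi-label graph-cut segmentation → breast-density quantification.
Every stage is a pure function of its inputs and configuration; a full run
is bit-reproducible, and the orchestrator records crop offset, downsample
factor and flip state so results map back to source coordinates.

## Preprocessing

* **Binarization.** A global threshold followed by morphological opening
  (disk, radius 2) and largest-8-connected-component selection. The default
  threshold is the **triangle method**: mammogram histograms are dominated
  by a dark background peak with a long bright tissue tail, which is the
  regime the triangle construction targets. Otsu's criterion is also
  available but tends to place the cut between tissue classes rather than
  between background and breast when the foreground is strongly multimodal
  (on piecewise-constant phantoms it lands between the fat layers, cutting
  breast-profile overlap to ~0.89 Dice versus 1.0 for triangle). A fixed
  numeric threshold overrides both. Radio-opaque labels and markers are
  removed by the largest-component rule, since they are disconnected from
  the breast.
* **Cleanup and crop.** Everything outside the profile mask is set to 0;
  the crop is the mask's bounding box dilated by a 2 px margin.
* **Downsampling** is the mean over factor×factor blocks (partial edge
  blocks average the pixels present), rounded half-up; default factor 4.
  Cropping precedes downsampling so the margin is defined at full
  resolution.
* **Median filter**, 3×3 by default, edge replication at borders. Applied
  after downsampling, so the kernel's spatial support matches the grid the
  graph cut will see.

## Pectoral muscle

Images are normalized chest-wall-left (an exact column reversal, recorded
in a flag); the side is auto-detected from foreground counts along the two
vertical borders, ties to left. The muscle is grown breadth-first and
4-connected from the foreground pixel nearest the upper-left corner (inset
3 px), admitting a pixel when its intensity is within `tolerance` of the
running region mean (default 16 gray levels; 4-connectivity avoids leaks
across thin diagonal boundaries). Grown pixels are blanked to 0, which
simultaneously removes them from the graph-cut labels (they are
hard-seeded as background) and from the breast-area denominator.

## Graph-cut segmentation

* **Label models.** Per-label 256-bin histograms of the seed-pixel
  intensities, floored at `epsilon = 1e-6` and renormalized. The optional
  `model_sigma` applies a Parzen (Gaussian) kernel over the intensity axis
  before flooring; the pipeline default is 4 gray levels, because seed
  strokes of a few dozen pixels produce nearly-degenerate histograms that
  generalize poorly to noisy intensities, while a few gray levels of
  smoothing leaves the models peaked but nonvanishing in the seeds'
  neighborhoods. At the library level the default is 0 (raw histograms).
* **Boundary term.** `exp(−ΔI²/2σ²)/dist` with σ = 10 gray levels,
  8-neighborhood by default, diagonal pairs down-weighted by 1/√2.
* **Hard constraints** are large finite costs (`hard_cost = 1e9`), kept
  finite so all arithmetic stays well-defined; a validity check enforces
  that they dwarf any achievable regular energy.
* **Optimization.** Initial labeling is the per-pixel data-cost argmin
  (ties to the smallest label id); α-expansion sweeps the labels in
  ascending id order until a sweep yields no decrease (max 10 sweeps).
  Each move is solved exactly by a min cut on the standard expansion graph
  (auxiliary node per unequal-labeled neighbor pair). Max-flow is a
  numba-compiled Dinic on int64 capacities obtained by fixed-point scaling
  (2^40; costs ≥ 2^20 saturate at 2^60, which only hard constraints
  reach). Quantization error is ~1e-10 relative; a move is additionally
  accepted only if it strictly lowers the float energy, so monotonicity is
  exact. Edges are traversed in insertion order, making tie-breaking and
  hence the whole segmentation deterministic.
* 3–6 labels are the anatomically meaningful range (background, skin–air,
  uncompressed fat, compressed fat, glandular, mass); plain 2-label
  foreground/background problems are also accepted, where a single
  expansion is provably the global binary optimum — the property the
  enumeration-oracle tests exercise.
* λ and μ default to 10 and 20. Only their ratio affects the argmin;
  tests assert invariance under joint scaling.

## Density and BIRADS

`density % = 100 · dense / breast`, where `breast` counts every
non-background pixel of the label map — the skin–air interface and both
fat layers included, the removed pectoral excluded — and `dense` counts
glandular plus (by default) mass pixels, a mass being hyperdense tissue
embedded in the glandular region. Categories: ≤25 → 1, ≤50 → 2, ≤75 → 3,
else 4 (the printed category table leaves the integer boundaries
ambiguous; bins here are half-open upward). The linear estimate
`y = 1.327 + 0.040·x` is reported raw, with a separate convenience
rounding to an integer category clipped to [1, 4]; the linear model exists
because keeping the skin–air band enlarges the denominator and biases raw
percentages low relative to categorical BIRADS readings.

## Evaluation metrics

Completeness `TP/(TP+FN)`, correctness `TP/(TP+FP)`, quality
`TP/(TP+FP+FN)` over the binarized dense class, evaluated on the full
raster. Degenerate conventions: if prediction and truth are both empty all
three metrics are 1 (perfect-empty agreement); if exactly one denominator
is zero that metric is 0. For TP > 0 the identity
`ρ = CM·CR/(CM+CR−CM·CR)` holds and is asserted to 1e-12. Batch
evaluation reports unweighted per-group and overall means.

## The phantom, and what passing tests mean

The phantom emulates the gross radiographic geometry of an MLO view: a
half-elliptical breast on the chest wall wrapped in a 2–5 px skin–air band
and an uncompressed-fat band, a central glandular blob in the compressed
fat, an optional mass disk strictly inside the glandular region, a
pectoral triangle at the top chest-wall corner, an optional bright
background rectangle standing in for radio-opaque labels, and additive
Gaussian noise (clipped to [0, 255], rounded). Default region means
5/30/60/110/180/220 with pectoral 200 and artifact 230 — ordered in
radiographic density, as the validator enforces. Rasterization is by
pixel-center membership, later-drawn (inner) regions winning; mirroring the
laterality column-reverses the finished phantom, noise included, so the
left/right symmetry is exact.

The phantom is deliberately *not* anatomically textured: regions are
constant-intensity plus i.i.d. noise, boundaries are analytic curves, and
the fuzzy fat–glandular transition of real parenchyma is absent. Passing
the phantom suites therefore demonstrates the correctness of the
machinery — energy minimization, seed constraints, coordinate bookkeeping,
density arithmetic — not clinical-grade accuracy on real mammograms, which
additionally depends on seed placement quality and tissue heterogeneity.

## Validation protocols and problem sizes

* Binary-cut exactness: 100 random instances up to 4×4 against exhaustive
  enumeration of all labelings (tolerance 1e-9 relative — float noise,
  not a modeling slack).
* Energy monotonicity: 50 random 16×16 4-label instances, every move.
* Noiseless recovery: 20 six-region 96×80 phantoms, 3 truth-sampled seeds
  per region, pectoral removed by tolerance-0 growing (its pixels scored
  as background) — ≥ 99 % pixel agreement required, 100 % typical.
* Noisy recovery: 256×208 phantoms at noise SD 8 through the *full*
  pipeline with 25 truth-sampled seeds per region, pectoral tolerance 24
  (3× the noise SD) and model smoothing 4: density within ±5 points of
  truth (≤1 point typical) and mass centroid inside the true mass disk.
* Determinism: two complete runs compared by content hash.

These sizes keep the default suite fast while still exercising every code
path at realistic aspect ratios.

## Known limitations

* Region-growing uses a running mean with a fixed tolerance; it has no
  boundary model, so a very low-contrast pectoral edge can leak (the
  classic Hough/straight-line refinements are out of scope).
* Histogram data terms ignore spatial texture; two tissues with equal
  intensity distributions are separable only through seeds and smoothness.
* Downsampling by 4 makes the thin skin–air band sub-pixel; its label
  survives through seed evidence but its geometry is approximate at the
  segmentation resolution.
* The BIRADS linear model is evaluated, never refitted; correlation
  analysis against radiologist ground truth requires data this package
  does not ship.
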