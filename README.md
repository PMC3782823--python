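# mammogc

Seeded multi-label graph-cut segmentation of MLO-view mammograms, with
breast-density quantification, BIRADS categorization, and segmentation
evaluation — plus a synthetic-phantom generator so the whole chain can be
exercised and validated without clinical data.

## Who this is for

Researchers building computer-aided detection (CAD) tools for mammography who
need a reproducible, testable implementation of the classic pipeline:
separate the breast profile from the background, remove the pectoral muscle,
partition the breast into its anatomical regions (skin–air interface,
uncompressed fat, compressed fat, glandular tissue, and an optional
hyperdense mass), and quantify breast density as a cancer-risk indicator.

## The model

Segmentation minimizes a Potts-style energy over pixel labelings
`L = {L_p}`:

```
E(L) = λ · Σ_p D_p(L_p)  +  μ · Σ_{(p,q) ∈ N} V_pq · δ(L_p ≠ L_q)
```

* `D_p(ℓ) = −ln Pr(I_p | ℓ)` is the data term: the negative log-likelihood
  of pixel `p`'s intensity under label `ℓ`'s model, a 256-bin histogram
  estimated from user-marked seed pixels (optionally Parzen-smoothed).
  Seeds are hard constraints: their own label costs 0, every other label a
  large finite `hard_cost`.
* `V_pq = exp(−(I_p − I_q)² / 2σ²) / dist(p, q)` is the contrast-sensitive
  boundary term on a 4- or 8-connected grid, charged only across label
  discontinuities.
* Defaults `λ = 10`, `μ = 20`.

The energy is minimized by α-expansion: sweeps over the labels, each move an
exact minimum s–t cut (Dinic max-flow on fixed-point int64 capacities), so
the energy is non-increasing by construction and the result is deterministic.

Breast density is then

```
density % = 100 · glandular pixels / breast pixels
```

where the breast area counts all non-background labels (the skin–air band is
kept, the removed pectoral is excluded), mapped to BIRADS categories
1–4 at 25/50/75 % and to a continuous estimate `y = 1.327 + 0.040·x`.
Segmentations are scored against ground truth by completeness
`TP/(TP+FN)`, correctness `TP/(TP+FP)` and quality `TP/(TP+FP+FN)`.

## Worked example

```python
import numpy as np
from mammogc import (PhantomSpec, PipelineConfig, generate_phantom,
                     run_pipeline, sample_truth_seeds)

spec = PhantomSpec(height=256, width=208, noise_sd=8.0, has_mass=True,
                   has_artifact=True, rng_seed=0)
ph = generate_phantom(spec)                       # image + exact truth labels
seeds = sample_truth_seeds(ph, per_region=25, rng=0)
res = run_pipeline(ph.image, seeds, PipelineConfig(pectoral_tolerance=24.0))

print(f"truth density    : {ph.truth_density_percentage():.2f} %")
d = res.density
print(f"density          : {d.percentage:.2f} %")
print(f"BIRADS category  : {d.birads_category}")
print(f"BIRADS estimate  : {d.birads_estimate:.3f}")
print(f"mass pixels found: {int((res.label_map == 5).sum())}")
```

prints

```
truth density    : 26.51 %
density          : 27.51 %
BIRADS category  : 2
BIRADS estimate  : 2.427
mass pixels found: 52
```

i.e. on a noisy synthetic mammogram the full pipeline (binarize → clean →
crop → downsample by 4 → median filter → orient → pectoral removal →
6-label graph cut → density) recovers the true density within one
percentage point, assigns BIRADS 2 (fat with some fibroglandular tissue),
and localizes the embedded mass.

The same stages are available from a shell:

```
mammogc phantom --height 256 --width 208 --mass --noise-sd 8 --seed 0 --out-prefix ph
mammogc run --in ph_image.pgm --seeds seeds.csv --out-dir out/
mammogc density --labels out/labels.pgm
```

Images travel as 8-bit PGM (P2/P5) or PNG; label maps as PGM id rasters with
a JSON legend plus a color PNG; seeds as `row,col,label` CSV or JSON.

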