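# fundustda

Topological summary statistics of retinal fundus images for
diabetic-retinopathy (DR) screening.

DR alters the fine structure of the retina long before lesions are obvious,
and in very high-resolution fundus photographs that alteration is visible as
a loss of local homogeneity in the grayscale field. `fundustda` quantifies
this with persistent homology: the image is treated as a scalar field
*z(x, y)*, filtered by its sub-level sets *{z < ℓ}*, and the births and
deaths of connected components (dimension 0) and holes (dimension 1) are
recorded in persistence diagrams. Because diagrams with hundreds of
thousands of points cannot feasibly be compared pairwise (a single
bottleneck distance is already expensive, and 30 images in two dimensions
would need 2·C(30,2) = 870 of them), each diagram is reduced to
interpretable scalars that feed a classical classifier.

The package is aimed at researchers in topological data analysis and
medical-image screening who want a reproducible, fully tested reference for
this pipeline, including a synthetic data generator that makes end-to-end
validation possible without downloading any image database.

## Method

1. **Preprocessing** — crop the dark border, convert to grayscale
   (0.299 R + 0.587 G + 0.114 B), and apply a rank-based normal-scores
   transform (Blom offsets, Φ⁻¹((r − 3/8)/(n + 1/4))) standardized to mean 0
   and sd 1, so all images share the same marginal distribution.
2. **Persistence** — Freudenthal triangulation of the grid with lower-star
   filtration values (each simplex enters at the max of its vertices);
   dimension-0 pairs by elder-rule union-find, dimension-1 pairs by a dual
   union-find over triangles (Alexander duality), verified exactly against a
   GF(2) boundary-matrix reduction oracle on small grids.
3. **Summaries** — per diagram: point count; average lifetime *d − b*; area
   under the accumulative persistence function
   APF(t) = Σᵢ (dᵢ−bᵢ)·1{(dᵢ+bᵢ)/2 ≤ t}; and five shape descriptors
   (centroids C_x, C_y, area A, perimeter P, filamentarity
   F = (P² − 4πA)/(P² + 4πA)) for each of six polygons: the regions under
   the first three persistence landscapes λ₁, λ₂, λ₃ and the 99%, 95%, 90%
   convex peels of the diagram point cloud.
4. **Features** — 2 × (1 + 1 + 1 + 6 × 5) = 66 named statistics per image.
5. **Classification** — L1-penalised logistic regression (cross-validated
   penalty path; minimum-error or one-standard-error rule) selects
   variables; a linear SVM is re-trained in leave-k-out cross-validation
   (k = 1…5), reporting sensitivity (correct DR calls) and specificity
   (correct healthy calls).

## Worked example

```python
import numpy as np
from fundustda import (SyntheticConfig, generate_field, image_features,
                       build_lower_star_filtration, compute_persistence)

field = generate_field(SyntheticConfig(seed=1), "case_like", 0)   # 128 x 128
dgm0, dgm1 = compute_persistence(build_lower_star_filtration(field))
print(len(dgm0), len(dgm1))
vec = image_features(field)
print(vec[["components_count", "components_apf_area", "holes_peel99_Cy"]])
```

prints

```
2041 1940
components_count       2041.000000
components_apf_area    4108.838146
holes_peel99_Cy           1.382726
dtype: float64
```

i.e. this noisy "disease-like" field decomposes into 2041 component births
and 1940 holes; its summed, range-integrated persistence (APF area) and the
death-axis centroid of the holes' 99% peel are two of the discriminating
statistics. A matched "healthy-like" field (`"healthy_like"` group, same
seed) has only 64 components and APF area 242 — the same direction of
difference reported between DR and healthy retinas.

A full cohort analysis from the shell:

```bash
fundustda run-all --synthetic-seed 7 --model lasso-min --k 1 --out out/
# -> [{"k": 1, "sensitivity": 1.0, "specificity": 1.0, "n_folds": 30, "exhaustive": true}]
```

Real images work the same way (`--images dir/` with PNG/JPEG/TIFF files,
"healthy" in the filename marking controls). High-resolution fundus
databases such as HRF (2336 × 2604) are external downloads; running them
through `run-all` reproduces the full published protocol, but at desk scale
the package validates the method on synthetic cohorts only and asserts no
real-image accuracy values.

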