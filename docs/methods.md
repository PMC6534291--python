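# Methods

## Model and procedure

An image is analysed as a scalar field *z(x, y)* filtered by its strict
sub-level sets *{z < ℓ}*. The grid is triangulated with a uniform
Freudenthal split — every unit square is cut along its (i, j)–(i+1, j+1)
diagonal — giving V = HW vertices, E = H(W−1) + W(H−1) + (H−1)(W−1) edges
and T = 2(H−1)(W−1) triangles (Euler characteristic 1, a disk). Each
simplex enters the filtration at the maximum of its vertex values (the
lower-star rule), so components are born at local minima and holes are
filled at local maxima. Dimension-0 and dimension-1 persistence diagrams
record these events as (birth, death) field values.

Assumptions worth stating explicitly:

* **Triangulation choice matters mildly for H1.** The hole count of a tied
  or saddle-heavy field depends on which diagonal is inserted; the uniform
  Freudenthal split is fixed and documented rather than configurable.
* **Ties are resolved deterministically** by row-major vertex index
  (simulation of simplicity); simplices are ordered by
  (value, dimension, max vertex index, vertex tuple). There is no RNG
  anywhere in the topology code.
* **The essential class** (the one component that never dies) is reported
  with its death capped at the maximum field value and included in all
  summaries by default; a flag allows excluding it. Zero-persistence pairs
  (birth = death) are dropped — with distinct field values the number of
  finite dimension-0 pairs plus one then equals the number of local minima.

### Persistence engines

`compute_persistence` uses two union-finds: the elder rule directly for
dimension 0, and, for dimension 1, a union-find over the dual graph
(triangles plus the outer face) processed in decreasing filtration order.
On a planar disk complex a hole born at edge value *b* and filled at
triangle value *d* corresponds exactly to a dual component born at that
triangle and absorbed along that edge in the reversed filtration, so the
dual sweep reproduces the boundary-matrix pairing at near-linear cost.
`brute_force_persistence` is the independent oracle: textbook GF(2) column
reduction over the full total order, restricted to ≤ 2000 simplices. The
test suite requires exact diagram equality between the two engines on
random fields (including heavily tied integer fields) up to 8 × 8.

### Preprocessing

Cropping keeps the tight bounding box of pixels whose maximum channel
exceeds a threshold (default 10/255; the surrounding camera mask in fundus
photographs is near-black). Grayscale uses the ITU-R BT.601 luma weights
0.299/0.587/0.114. The normal-scores transform maps ranks to standard
normal quantiles at Blom plotting positions Φ⁻¹((r − 3/8)/(n + 1/4)),
averaging ranks over ties, then centres and scales to sample (n − 1) sd 1.
The transform is invariant to any strictly monotone re-expression of the
input, which is the property the pipeline actually relies on; the Blom
offset choice is conventional and immaterial to that invariance.

### Summary statistics and features

Per diagram: point count, mean lifetime, and the area of the accumulative
persistence function APF(t) = Σ (dᵢ−bᵢ)·1{(dᵢ+bᵢ)/2 ≤ t} integrated over
the value range of the standardized field that produced the diagram.
Because every field is normal-scored, that range is comparable across
images; the integration domain is a configuration choice, not data-driven.

Landscapes are computed exactly (piecewise linear, slopes in {−1, 0, +1})
by the sequential sweep over (b asc, d desc)-sorted tents, re-inserting
truncated remainders for deeper levels; tests verify the result against a
dense-grid k-th-largest-tent oracle to 1e−12. The polygon under λ_k is
closed by the t-axis; disconnected support is treated as a multipolygon
with additive area/perimeter and an area-weighted centroid. Landscape
polygons live in rotated coordinates ((d+b)/2, (d−b)/2) — hence a diagonal
diagram shift moves their C_x but not their C_y — while convex peels stay
in raw (birth, death) axes, where both centroid coordinates shift.

Convex peels repeatedly remove the hull vertices of the cloud while at
least ⌈proportion·n⌉ points would remain, then summarize the hull of the
retained points. Degenerate cases (fewer than 3 non-collinear points, a
landscape that is identically zero) produce all-zero descriptors with a
degeneracy flag so the feature vector keeps its fixed length of 66.

All polygon measures (shoelace area, boundary length, area-weighted
centroid) are delegated to shapely; hulls to scipy's Qhull wrapper.

### Classification

Variable selection: L1-penalised logistic regression over a 40-point
logarithmic penalty grid, scored by seeded stratified 10-fold CV error
(standardization refit inside every fold). Two rules are exposed: the
minimum-error penalty and the one-standard-error rule (the strongest
penalty within one SE of the minimum; never selects more variables). An
empty selection falls back to the single largest-coefficient feature. The
SVM is linear with cost 1 on standardized features — with ~30 samples and
a handful of variables a flexible kernel mostly adds variance; RBF is
available by configuration.

Leave-k-out CV enumerates all C(n, k) test sets up to `max_folds` (default
10⁵, which covers k ≤ 4 at n = 30 exhaustively; C(30,5) = 142 506 is
sampled) and pools correct calls: sensitivity over case rows, specificity
over healthy rows. By default selection runs once on the full table and
only the SVM is re-trained per fold, mirroring the published retinal
protocol; this leaks selection information into the folds, and
`selection_inside=True` (re-selecting within every training set) is the
recommended honest protocol whenever the selection itself is in question.

## Synthetic data

The generator emulates the statistical structure the analysis exploits,
not retinal anatomy. Healthy-like fields are stationary Gaussian random
fields (white noise filtered by a Gaussian kernel, periodic boundaries)
with correlation length 4 px at the default 128 × 128 desk scale.
Case-like fields use correlation length 3 px, add independent white noise
of sd 0.6 (in units of the smoothed field's sd) and 20 localized Gaussian
bumps (width 2 px, amplitude ±3) at seeded positions. Lower local
correlation multiplies local minima — more short-lived components, larger
accumulated persistence — and the bumps add extremal persistent points
that shift peel centroids; these are the directions in which diabetic
retinas differ from healthy ones in the published summary statistics. The
15 + 15 group size mirrors the study design. Every field is deterministic
in (seed, group, image index) via `SeedSequence`, and ends with the same
normal-scores standardization as real images.

What passing tests on this generator do **not** show: performance on real
fundus photographs. The synthetic groups are separated far more cleanly
than real cohorts (the default effect yields perfect leave-one-out
separation), real images have vessel structure, illumination gradients and
camera masks the generator omits, and full-resolution (2336 × 2604) images
produce diagrams three orders of magnitude larger. The pipeline accepts
such images unchanged, but published sensitivity/specificity tables for
real cohorts are not reproducible without the external image download and
are asserted nowhere in the test suite.

## Numerical choices and problem sizes

* Diagrams store float64 field values; engine-vs-oracle comparisons demand
  bit-exact equality, which the shared total order guarantees.
* The landscape sweep and APF area are exact (no discretization); test
  oracles use dense grids or closed forms.
* Null-cohort chance checks estimate accuracy as the mean over five
  independent seeded null cohorts classified on the fixed 66-feature set:
  a single 30-image leave-one-out run has sd ≈ 0.12 (small-sample
  anti-learning bias included), so averaging replicates is needed for a
  stable chance-band statistic.
* Test and acceptance runs use 128 × 128 cohorts (seconds per cohort) and
  ≤ 8 × 8 grids for the reduction oracle; these sizes are the package's
  validation scale, chosen so the whole suite stays interactive.

## Known limitations

* Dimension ≥ 2 homology, cubical complexes, upper-star filtrations and
  bottleneck/Wasserstein metrics are out of scope.
* The dual dimension-1 engine relies on planarity of the triangulated
  grid; it does not generalize to arbitrary complexes (the oracle does).
* LASSO selection at n = 30 with 66 features is unstable across seeds;
  the fixed published variable sets (`svm1`, `svm2`) are provided for
  reproducibility, and in-fold selection for honesty.
* The SVM kernel, cost and scaling of the original study are unreported;
  the defaults here are the package's own choices.
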