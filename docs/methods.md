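# Methods

## Scope and model

`moha` quantifies intratumor heterogeneity from spatially resolved
single-cell measurements, typically the per-cell tables produced by
segmenting multiplexed immunofluorescence (MxIF) images. The cell is the
atomic unit. Two families of metrics are computed per tissue sample:

* **Molecular** metrics depend only on the proportions of cells across
  discrete molecular states.
* **Spatial** metrics additionally depend on which cells touch which, via
  a neighbor graph.

### Molecular states

Each biomarker intensity, integrated per cell and subcellular compartment,
is discretized into one of *n* ordinal levels (default *n* = 3:
low/medium/high) by an *n*-state threshold model. Cutpoints are
percentiles of the intensities pooled over the whole study (defaults: the
33rd and 67th), computed per (marker, compartment) key by the nearest-rank
rule — the ⌈p·N/100⌉-th sorted value, no interpolation — so results are
bit-reproducible. A value equal to a cutpoint falls in the lower bin.
Upstream-binned ordinal data can be supplied directly, bypassing the
threshold model.

A pathway or gene set is an ordered list of *N_pn* measurable nodes, each
a (marker, compartment, optional phospho-form) triple. A cell's molecular
state is the concatenation of its node levels in that fixed order (e.g.
`2122202222211222` for a 16-node pathway). The order is arbitrary but must
be held constant; every metric here is invariant under reordering. Cells
missing any node level are left unassigned and excluded from state counts
— imputing a level would manufacture states that were never measured.

The maximum number of molecular states is
`N_m = min(n^N_pn, N_c)` with `N_c` the number of assigned cells;
`n^N_pn` is evaluated in exact integer arithmetic (3^16 = 43,046,721).

With state frequencies `P_i`:

* MolecularEntropy `= −Σ_i P_i ln P_i` (nats),
* MolecularHeterogeneity `= entropy / ln N_m` ∈ [0, 1] (0 when `N_m` = 1),
* MolecularDisparity `= Σ_{i<j} P_i P_j d(i,j)²` with
  `d(i,j)² = Σ_n (M_{n,i} − M_{n,j})²` over node levels. States with zero
  frequency contribute nothing, so the sum runs over observed states only
  (algebraically identical to the full enumeration).

### Neighbor graph

Two cells are neighbors when they touch. The **exact** method compares the
cells' boundary pixels from the segmentation mask: touching means some
pair of edge pixels lies within one pixel, taken as Chebyshev distance ≤ 1
(8-connectivity). The **approximate** method models cells as circles of
equivalent area, `r = sqrt(A/π)`, and declares touching when
`dist(centers) ≤ d_critical · (r_i + r_j)`; the default
`d_critical = 1.31` is the value that best reproduced pixel-exact contact
on segmented tissue. Ties at the threshold count as touching. Candidate
pairs come from a k-d tree queried at radius `d_critical · 2 r_max`, which
cannot miss a qualifying pair, so the graph equals the all-pairs scan
(verified against an O(N²) oracle). Edges never cross sample boundaries.

### Spatial metrics

Computed on the graph restricted to assigned cells (a cell of unknown
state can neither match nor mismatch, so its edges are dropped):

* **Coordination number entropy**: Shannon entropy of the distribution of
  per-cell degrees `Z_j`; purely spatial, reported unnormalized.
* **Cell family**: per cell, the count `k` of neighbors in the *same*
  state (0 is valid); entropy of the distribution of `k` over cells,
  heterogeneity normalized by `ln(Z_max + 1)`. The worked example's "group
  size of two" phrasing corresponds to `k = 1` plus the cell itself; the
  implementation stores `k`.
* **Cell neighbor**: per cell, one observation per distinct molecular
  state present among its neighbors, the observation being the count of
  neighbors in that state; observations pooled over cells. Isolated cells
  emit nothing. The maximum state count for normalization is not defined
  in the literature for this metric; `ln(Z_max + 1)` is this package's
  documented choice (counts range over 1..Z_max).
* **Cell social**: maximal connected groups of touching same-state cells
  (singletons included); the distribution is over group *sizes* with one
  observation per group, matching the worked example's enumeration
  ("6 monomers, 4 dimers, 1 pentamer"). Normalization uses the largest
  number of distinct group sizes `N_s` that `N_c` cells can exhibit,
  `N_s(N_s+1)/2 ≤ N_c`, i.e. `N_s = ⌊(√(8 N_c + 1) − 1)/2⌋` (integer
  square root, overflow-safe).

### Null models

To separate molecular composition from tissue topology, state labels are
permuted uniformly over cell positions (the multiset, hence every
molecular metric, is preserved exactly) and spatial metrics recomputed;
default 120 permutations, reported as mean, SD and z-score of the observed
value. The ensemble is evaluated by a vectorized integer-coded engine that
the tests prove exactly equivalent to permuting the assignment objects.

For the family metric only, an analytic expectation exists: the number of
configurations with family state `k` is

```
N_sk = Σ_j Σ_i C(Z_j, k) (1 − P_mi)^(Z_j − k) P_mi^(k+1)
```

normalized over `k = 0..Z_max`; entropy/heterogeneity follow as above
(emitted as "Cell Family Het. (Probability Based)"). Binomial coefficients
are computed in log space. The formula treats neighbor states as
independent draws from `P_m`, i.e. it is the infinite-population limit of
the permutation null. At finite cell counts the two differ by O(1/N_c):
at ~1300 cells per sample the offset is a few 1e-3 of heterogeneity —
negligible in absolute terms but several Monte-Carlo standard errors at
R = 1000. The test suite asserts both the convergence (the gap shrinks
with N and is < 0.005 at a couple thousand cells) and, separately, the
strict 3-standard-error cross-validation, which fails for exactly this
finite-population reason and documents it.

## Quality filters

Defaults follow the processing of tumor-core imaging data:

| parameter | default | meaning |
|---|---|---|
| min/max area | 1.4 / 140 µm² | bounds on nuclear and cytosol areas (whole-cell area when those columns are absent) |
| nuclei | {1, 2} | allowed nuclei count |
| edge margin | 2 µm | centroid distance to field bounds (bounds default to the centroid bounding box) |
| min cells | 100 | samples below this after filtering are excluded |
| QC round threshold | 0.8 | per-round staining-quality score below which a marker's intensity becomes missing (the cell is kept) |
| epithelial only | true | keep cells inside the epithelial mask |

Morphology and QC filters commute on the surviving (cell, marker) pairs.
Thresholds are fitted after morphological filtering by default.

## Synthetic tissues

The generator emulates the input contract, not microscopy: packed
non-overlapping circular cells on a bounded field (jittered hexagonal grid
at touching spacing, or random sequential addition of disks), per-cell
multi-marker intensities, and optional QC failures.

* **Cell count**: default 1300 per tissue, the average tumor-core yield of
  a cohort-scale study (~10⁶ segmented cells over ~750 cores).
* **Geometry**: radius 3 ± 0.3 µm (epithelial scale); hex spacing bounds
  the radii so disks never overlap; interior cells have coordination
  number 6.
* **States**: a set of prototype level-vectors (default 6) built balanced
  per marker so each ordinal level holds about a third of the pooled
  intensities; cells draw a prototype iid (`cluster_size = 1`) or via
  seeded region growth on the touching graph into patches of about
  `cluster_size` cells.
* **Intensities**: level-conditional Gaussians separated by 10 SD, so
  study-wide percentile thresholding recovers the generating levels with
  < 5% error when level marginals are balanced; with strongly skewed
  state probabilities the percentile cutpoints shift and recovery
  degrades — a property of percentile thresholding itself.
* **Rasterization**: disks grown slightly (default ×1.15) with contested
  pixels going to the nearest center, yielding abutting cell regions like
  real space-filling epithelium (segmented cells meet along borders, not
  at tangency points); used to exercise the pixel-exact method. Default
  pixel size 0.5 µm (20× magnification scale).

What the generator does **not** emulate: staining chemistry, optics,
segmentation errors beyond QC flags, cell-shape anisotropy, or realistic
pathway covariance between markers. Passing tests demonstrate the
correctness and internal consistency of the metrics, not biological
validity on real tissue.

A note on the clustering response: whether spatial clustering of states
pushes the family heterogeneity above or below its permutation-null mean
depends on the molecular frequencies. With many rare states the null
family distribution concentrates at k = 0 and clustering *raises* the
entropy; with a few frequent states the null is broad and clustering
*lowers* it, monotonically once patches exceed the neighborhood scale.
The monotonicity experiment therefore uses two equiprobable states
(a dominant-clone dichotomy) and cluster sizes 2–60.

## Numerical choices

* Entropies in nats throughout; `0 ln 0 = 0` by omission of zero-frequency
  states.
* Heterogeneity defined as 0 whenever the maximum state count is 1.
* Percentiles: nearest-rank, ties to the lower bin.
* Binomials via `gammaln`; `(1 − p)⁰ = 1` even at `p = 1`.
* Per-sample null-model seeds derive from the run seed and the sample id
  (CRC32), so per-sample results are independent of cohort composition
  and byte-identical across reruns.

## Problem sizes used in the checked experiments

Oracle equivalence uses 200 random tissues of ≤ 50 cells (exhaustive
O(N²)/O(k²) references); the null-model cross-validation uses 20 tissues
at the default 1300 cells with 1000 permutations; concordance uses one
600-cell rasterized packing; the clustering experiment uses 20 seeds per
cluster size at 60 permutations. These sizes are the package's own choice
of smallest scales at which each property is informative.

## Known limitations

* Pathway connectivity and interaction directionality are ignored; only
  the node-level composition enters the state.
* The cell-neighbor metric's normalization constant is a package choice
  (see above); comparisons across tools should use the entropy.
* The analytic family null is an infinite-population approximation (see
  above).
* The approximate neighbor method inherits the equivalent-circle
  assumption; on elongated cells its error grows, and `d_critical` may
  warrant re-tuning per segmentation pipeline.
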