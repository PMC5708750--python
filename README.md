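# moha

Molecular and spatial diversity metrics for spatially resolved single-cell
tissue data.

Tumor tissues are heterogeneous in two coupled ways: in the molecular
states their cells express, and in how those states are arranged in
space. Multiplexed immunofluorescence (MxIF) and similar technologies
yield, after segmentation, a table with one row per cell — centroid,
areas, and dozens of biomarker intensities per subcellular compartment.
`moha` turns such tables into per-sample heterogeneity metrics suitable
for downstream association with clinical variables (stage, grade,
recurrence). It is aimed at computational pathology and tissue-imaging
groups who already have segmented single-cell tables and want robust,
reproducible diversity statistics.

## The metrics

Each biomarker is discretized into *n* ordinal levels (default 3, via the
33rd/67th percentiles of the study-pooled intensities). A cell's
**molecular state** is the ordered concatenation of its levels over the
measurable nodes of a chosen pathway or gene set (e.g. a 16-node pathway
under 3 levels allows 3¹⁶ = 43,046,721 states). With state frequencies
P_i and the maximum attainable state count N_m = min(nᴺᵖⁿ, N_c):

- MolecularEntropy = −Σ P_i ln P_i
- MolecularHeterogeneity = entropy / ln N_m ∈ [0, 1]
- MolecularDisparity = Σ_{i<j} P_i P_j d(i,j)², d² the squared node-level
  distance between states

Cells touch when their boundary pixels meet (exact method) or when the
center distance is at most d_critical = 1.31 times the sum of their
equivalent-circle radii r = √(A/π) (approximate method). On this graph:

- **Coordination number entropy** — entropy of the degree distribution
  (purely spatial)
- **Cell family** — per cell, the number of same-state neighbors
  (k = 0..Z_max); heterogeneity normalized by ln(Z_max + 1)
- **Cell neighbor** — one state per distinct molecular state in a cell's
  neighborhood (its neighbor count), pooled over cells
- **Cell social** — sizes of connected groups of touching same-state
  cells; normalized by ln N_s, N_s = ⌊(√(8 N_c + 1) − 1)/2⌋

Permutation null models (default 120 shuffles of state labels over
positions) and an analytic expected family distribution decouple the
molecular composition from tissue topology. See `docs/methods.md` for the
full model description and numerical choices.

## Worked example

Generate a synthetic 1300-cell tissue and run the full pipeline:

```sh
moha simulate --seed 11 --out tissue.tsv
moha run --cells tissue.tsv --pathway panel.json \
    --permutations 120 --seed 17 --out out/
```

where `panel.json` lists the four synthetic markers in order:

```json
{"name": "panel", "nodes": [
  {"marker": "M00", "compartment": "cell"},
  {"marker": "M01", "compartment": "cell"},
  {"marker": "M02", "compartment": "cell"},
  {"marker": "M03", "compartment": "cell"}]}
```

Selected columns of `out/metrics.tsv`:

```
   sample_id  n_cells  Zmax  MolecularEntropy  MolecularHeterogeneity  CellFamilyHeterogeneity  CellFamilyHet.(ProbabilityBased)  CellFamilyHeterogeneity_null_mean  CellFamilyHeterogeneity_z
synthetic-11     1224     6            2.1191                  0.4822                   0.6249                            0.6068                             0.6022                     1.4995
```

Reading: 1224 of 1300 cells survive the morphology filters (the rest sit
in the 2 µm edge margin); the hexagonal packing caps the coordination
number at 6. The tissue draws its states iid from six equiprobable
prototypes, so molecular entropy ≈ ln 6 ≈ 1.79 plus sampling spread over
the 3⁴ = 81 possible 4-marker states, and the observed family
heterogeneity (0.6249) sits within the permutation null band (mean
0.6022, z ≈ 1.5): no spatial organization, as expected for an iid tissue.
The analytic expectation (0.6068) agrees with the permutation mean to
~0.005.

The packaged 19-cell worked example, with three molecular states arranged
into 6 monomers, 4 dimers and 1 pentamer:

```
$ moha fig2-check
social groups by size: {1: 6, 2: 4, 5: 1}
family state of 'center': 1
CellSocialEntropy = 0.9165
CellSocialHeterogeneity = 0.5694
```

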