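# braingraph

Graph-theory analysis of brain connectivity for neuroimaging research.

The brain can be modelled as a network (a *connectome*): regions of a brain
atlas are the nodes, and statistical associations between regional measures
are the edges. `braingraph` covers the whole analysis chain for such
networks:

* **atlas & cohort I/O** — region definitions (label, name, x/y/z) in
  text/XLSX/XML dialects; structural cohorts (one scalar per region per
  subject, e.g. cortical thickness or PET uptake) and functional cohorts
  (regional time series, e.g. resting-state fMRI), with covariates and
  linear nuisance regression (residuals substitute the raw values);
* **connectivity** — Pearson / Spearman / Kendall tau-b / partial
  correlation matrices, zero diagonal, with a configurable rule for
  negative coefficients (keep, absolute value, or zero);
* **graph construction** — weighted undirected (WU) graphs, symmetrization
  rules for directed input, and binarization at a fixed threshold (BUT) or
  fixed density (BUD, the *m* = round(d·R(R−1)/2) strongest edges);
* **measures** — degree, strength, shortest-path distances (length = 1/w on
  weighted graphs), characteristic path length, closeness, betweenness
  (Brandes), global/local efficiency, clustering (Onnela for WU),
  transitivity, and small-worldness σ = (C/C_rand)/(L/L_rand);
* **modules** — seeded Louvain partitions with Newman–Girvan modularity
  Q = (1/2m)Σ_ij [A_ij − k_i k_j/2m] δ(c_i,c_j), within-module degree
  z-score and participation coefficient P_v = 1 − Σ_m (κ_vm/k_v)²;
* **null models** — Maslov–Sneppen degree-preserving rewiring (plus exact
  weight-multiset preservation for WU graphs) and measure normalisation
  against random ensembles;
* **statistics** — non-parametric permutation tests for group differences
  (cross-sectional and longitudinal/paired), permutation percentile bands,
  and Benjamini–Hochberg FDR across nodes;
* **workflows** — two end-to-end recipes with a Model/Results API, a
  synthetic-cohort generator with planted modular structure and group
  effects, and a small CLI (`braingraph --help`).

## Worked example

```python
import numpy as np
from braingraph import (
    AnalysisConfig, StructuralNetworkAnalysis, generate_structural_cohort,
)

# synthetic cohort: 10 regions, 12 subjects per group, two exchangeable groups
cohort = generate_structural_cohort(R=10, n_per_group=12, seed=4)

config = AnalysisConfig(
    densities=(0.15, 0.25),                 # full recipe grid: 0.05..0.25 step 0.005
    global_measures=("char_path_length", "clustering"),
    nodal_measures=("degree",),
    n_permutations=60,
    seed=5,
)
results = StructuralNetworkAnalysis(cohort, config).fit()
print(results.summary())
```

prints

```
StructuralResults
=================
groups: A, B
measures table: 48 rows; comparisons: 24 rows (1 significant at alpha=0.05)
permutations per comparison: 60
significant comparisons (FDR-corrected where nodal):
  A vs B clustering [GLOBAL] param=0.15: diff=-0.3833 p=0.0328
```

48 measure rows = 2 groups × 2 densities × (2 global measures + 10 nodal
degree values); 24 comparison rows = 2 densities × (2 global + 10 nodal
tests) for the one group pair. The two groups are drawn from the same
distribution, so the lone nominally significant global comparison out of 24
tests is the expected false-positive behaviour at α = 0.05 (global measures
are deliberately reported uncorrected; nodal ones are FDR-corrected).
`results.comparisons` holds the
observed difference, one- and two-tailed permutation p-values, the 2.5–97.5
percentile band of the permutation null, and FDR-adjusted p-values for nodal
measures; `results.plot_global_sweep("char_path_length", "A vs B")` draws
the difference against the density grid inside the null band, and
`results.save("out/")` archives everything as CSVs plus the config and log.

The same API runs the functional recipe (`FunctionalNetworkAnalysis`):
per-subject weighted graphs, group comparison of the average degree, seeded
modularity partitions per group matched by node overlap, and per-module
degree comparisons with FDR.

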