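# Methods

This note documents the models, conventions and numerical choices behind
`braingraph`, and what the synthetic-data tests do and do not establish
about real neuroimaging data.

## Data model

An analysis is anchored to a **brain atlas**: an ordered list of regions
(label, name, x/y/z coordinates). The order is the node order of every
matrix; all user-facing output uses labels. Two cohort modes exist.
*Structural* mode holds one scalar per region per subject (cortical
thickness, volume, PET uptake): edges are associations **across subjects**,
so each group yields a single group-level network. *Functional* mode holds
a timepoints × regions series per subject (fMRI, EEG): edges are
associations **across time**, so each subject yields their own network and
group statements average over subjects. Non-finite values are rejected at
load time rather than imputed — one NaN silently corrupts an entire
correlation matrix, and failing fast is the only safe default. Categorical
covariates must arrive numerically coded; the package does not invent dummy
coding.

Nuisance regression (structural mode) fits, per region, ordinary least
squares of the regional values on an intercept plus the named covariates
across the union of subjects, and substitutes the residuals for the raw
values. Residuals are mean-zero and orthogonal to every covariate column by
construction; a rank-deficient design (e.g. a constant covariate) is an
error rather than a silent pseudo-inverse.

## Edges

Supported associations: Pearson, Spearman, Kendall (tau-b, the
tie-corrected variant), and Pearson/Spearman partial correlation. Partial
correlation for a pair conditions on **all remaining regions**, computed
from the inverse of the correlation matrix (equivalent to correlating the
OLS residuals on the other regions); this requires more observations than
regions and the builders enforce n > R + 2 with a clear error. The diagonal
is always zero. Negative coefficients follow one of three rules — keep,
absolute value, or set to zero (the default recipe uses zero). An
"s-transform" option sometimes mentioned in this literature has no published
formula, so it is rejected with an explanatory error rather than guessed.
Zero-variance inputs (a constant region) are hard errors naming the region,
never silent zeros.

## Graphs and binarization

Graphs carry a square zero-diagonal adjacency plus weighted/directed flags
(WU/BU/WD/BD). Directed matrices can be symmetrized entrywise by sum,
absolute difference, min, or max. Binarization is either by **threshold**
(BUT: keep weights strictly above t) or by **density** (BUD: keep the m
strongest edges, m = round(d·R(R−1)/2)). Fixing density equalises edge
counts across groups, which is why density grids dominate group comparisons;
the default grid is 5%–25% in 0.5% steps (41 levels).

Conventions the field leaves unstated are fixed deterministically and
loudly: threshold comparison is strict; the density edge count rounds half
up with a floor of one edge; density ties are broken by weight descending
then (row, col) ascending; negative weights, if kept, are ranked on their
signed values (−0.2 ranks below +0.1) — prefer the abs/zero rules before
binarizing if that is not what you want.

## Measures

On weighted graphs a stronger edge is a shorter connection: edge length is
1/w (the proportionality constant is irrelevant wherever ratios are taken,
and is documented as 1). Distances are breadth-first (binary) or Dijkstra
(weighted) shortest paths; unreachable pairs are +inf. Infinite distances
are **excluded** from the nodal means of characteristic path length and
closeness (an isolated node has closeness 0, and a completely edgeless
graph has no defined path length); the efficiency measures absorb them
naturally as 1/inf = 0. Betweenness follows Brandes' algorithm and is
reported by default as the fraction of the (R−1)(R−2)/2 node pairs a node
mediates (the raw count is available). Clustering on weighted graphs uses
the Onnela geometric-mean formulation with weights normalised by the
maximum weight, and transitivity uses the same triangle weighting.
Transitivity is the standard orientation 3·triangles / #2-paths, bounded in
[0, 1]. Small-worldness is σ = (C/⟨C_rand⟩)/(L/⟨L_rand⟩) against a
degree-matched random ensemble; σ > 1 means near-random path length with
excess clustering.

## Modules

Modularity Q is the Newman–Girvan form (weighted generalisation on WU
graphs). Partitions come from Louvain as implemented in networkx, run with
10 restarts whose seeds derive from the user seed, keeping the best-Q
assignment; Louvain is greedy and its sweep order matters on small graphs,
and the restarts keep results bit-reproducible while staying within 5% of
the exhaustive-search optimum on every small graph tested. Module
statistics (within-module z-score with population standard deviation,
participation coefficient, module average degree) use degree on binary
graphs and strength on weighted ones, following the graph's flag. When two
groups' partitions are compared, modules are matched greedily by maximum
node overlap — a deliberate, documented artifact convention, since no
standard exists.

## Null models

Binary graphs are randomised by Maslov–Sneppen pairwise edge rewiring
(default 10 successful swaps per edge, the Brain Connectivity Toolbox
convention); proposals creating self-loops or duplicate edges are rejected,
and after 10× the requested swap count in failed proposals the remainder is
skipped (relevant only for dense or tiny graphs — a triangle admits no
valid swap and returns a copy). Degree sequences are therefore preserved
exactly. Weighted graphs rewire the topology the same way and then
reassign the original weight multiset to the new edges in random order:
degrees and the weight distribution are exact, node strengths vary under
the null, as intended. Connectedness is not enforced.

## Permutation statistics

Group differences are tested non-parametrically: subjects are pooled and
randomly reassigned to groups of the original sizes M times (default 1000;
10000 for publication-grade p-values). In structural mode the **entire
pipeline** — group matrix, binarization, measure — is rebuilt per
permutation, because the group matrix is not a per-subject quantity; in
functional mode the per-subject measures are permuted directly. Longitudinal
designs swap (or not) each subject's two timepoints independently, so a
permuted group never contains two observations of one subject, nor mixes
subjects.

p-values use the inclusive estimator (k+1)/(M+1), which is a valid test and
never returns 0; the raw fraction k/M is retained alongside for comparison
with exhaustive enumeration. The reported 95% interval is the 2.5–97.5
percentile band of the permutation null of the difference. Nodal
comparisons share one stream of permutations across nodes and are corrected
across nodes with Benjamini–Hochberg FDR, per density level (not pooled
across the grid — the correction targets the number of regions tested).
Global measures are reported uncorrected across the density sweep, as is
conventional; judge them by the consistency of the effect across densities,
not by a single level.

## Synthetic cohorts

The generator emulates the two data kinds with a latent block-factor model:
x = √b·g + √w·f_block + √(1−w−b)·ε, giving within-block correlation w and
background correlation b (defaults 0.5/0.1 structural, 0.45/0.08
functional, chosen as mid-range values for cortical-thickness and
resting-state correlation structure). Group effects are a mean shift on
chosen regions and/or a multiplicative weakening of the couplings
(`coupling_scale`), the latter being what correlation networks actually
detect. It does **not** emulate spatial autocorrelation, site effects,
heavy-tailed motion artefacts, or hub-concentrated topology; passing tests
establish the correctness and calibration of the machinery, not robustness
to those real-data pathologies.

## Verification sizes and limits

The verification battery uses desk-scale problems chosen to exercise every
code path: measure-oracle agreement on 200 random graphs of 4–8 nodes
(binary quantities exact, weighted within 1e-12; ratio-valued binary
measures differ from the enumeration oracle only by float rounding,
~1e-16); type-I calibration with 500 replicate null cohorts of 8 regions
and 10 subjects per group at M = 200 permutations; planted-module recovery
on 30 regions, 3 blocks, 20 seeds. Known limitations: directed measures are
not implemented (undirected analyses only); no shrinkage/precision
estimators for connectivity; no consensus clustering across Louvain runs;
no dynamic (sliding-window) connectivity.
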