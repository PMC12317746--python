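# Methods

## Model and procedure

The pipeline treats spatial domain detection across S samples as community
detection on two graphs built in sequence.

**Null-residual embedding.** Counts are modelled under a null
multinomial/Poisson model with expectation `μ_ij = n_i π_j`, where `n_i` is
unit i's total count and `π_j` gene j's share of the grand total. Residuals
(deviance by default in stage 1, Pearson in stage 2) approximate GLM-PCA
while staying a closed-form transformation; the Pearson form in particular
damps additive sample-level shifts, which is why it is the stage-2 default.
Residuals are clipped at ±√M to bound the leverage of extreme units
(`clip_residuals=False` disables this). All-zero units are dropped with a
warning, never imputed. PCA is computed by full SVD on the centred residual
matrix; each component's sign is fixed so its largest-magnitude loading is
positive, making the embedding bit-reproducible. An alternative route
(`reduction_method="hvg_pca"`) selects the 2000 most variable genes on
log1p counts-per-10k and applies standard PCA.

**Spatial graph.** Each unit is connected to its k = 6 spatial nearest
neighbours (Euclidean distance; ties broken by distance then unit index),
and the directed relation is symmetrized by union so every unit keeps all k
of its own neighbours. Edge weights default to the smoothed form: for edge
(u, v) with spatial q-neighbourhoods V_u and V_v (q defaults to k), shared
neighbours V_u ∩ V_v are removed from both sides, the endpoint itself is
added back, and the weight is the Pearson correlation between the
component-wise means of the embedding over the two sets. Removing the
shared neighbours matters at tissue boundaries: without it, both averages
absorb the same mixed-neighbourhood signal and boundary edges are smoothed
away instead of cut. With q = 0 the weight reduces exactly to the pairwise
endpoint correlation. Edges with weight below 0.6 are pruned (kept iff
weight ≥ threshold); the pruning report includes a 20-bin weight histogram
so a data-driven threshold can be chosen instead.

**Niches.** Louvain (igraph's multilevel algorithm, which supports the
Reichardt–Bornholdt resolution parameter) at resolution 10 partitions the
pruned graph into small niches; on a ~5000-unit sample this lands at
100–200 niches. Negative retained weights (possible only with permissive
thresholds) are clamped to 0 for modularity. Niches below 5 units are
dissolved member-by-member into the modal niche among each member's
neighbours *in the unpruned spatial graph* — pruning isolates some units
entirely, and using the pruned graph would leave them as permanent
singleton niches (in early testing ~25% of niches), polluting the pseudobulk
profiles; "nearby" is a physical notion. Ties break toward the larger
niche, then the smaller label id; rounds repeat until stable, and an
undersized niche whose members have no outside neighbours keeps its label
and is flagged. Counts are then summed per niche (sums, not means, so
totals are conserved exactly; mean aggregation is available).

**MNN graph and domains.** All niches are embedded jointly: pseudobulk rows
are stacked on the sorted intersection of gene ids across samples (a joint
fit, not per-pair), transformed to Pearson residuals and reduced to 30 PCs.
For each niche and each *other* sample, the k_mnn nearest niches of that
sample are found by Euclidean distance; a pair is connected iff each lies
in the other's list. Edges are unweighted — mutuality is binary. Louvain at
resolution 1 yields the domains, renumbered by descending niche count. A
niche isolated in the MNN graph inherits the domain of its nearest labelled
niche in embedding space (or stays at −1 with `keep_unassigned`). Every
unit receives its niche's domain.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_pcs` | 30 | PCs kept in both stages |
| `k_spatial` | 6 | spatial kNN degree; raise for dense platforms |
| `prune_threshold` | 0.6 | minimum retained edge weight (correlation scale) |
| `q_smooth` | = k | neighbourhood size for edge smoothing |
| `resolution_stage1` | 10 | niche granularity; calibrated to 100–200 niches per ~5k units |
| `min_niche_size` | 5 | niches below this are dissolved |
| `k_mnn` | 15 | per-sample nearest-niche list length in stage 2 |
| `resolution_stage2` | 1 | domain granularity |

`k_mnn` deserves a note. With ~120 niches per sample, mutual lists of
length 5 give the MNN graph a mean degree around 7; modularity at
resolution 1 then fractures each true domain block into several communities
even when >99% of edges join same-domain niches. Lists of length 15 make
the blocks dense enough that resolution ≈ 1 recovers them as single
communities, and the setting is insensitive between roughly 12 and 30. The
default is therefore 15; users integrating many more niches per sample can
scale it with niche count.

Determinism: igraph's Louvain is randomized, so the implementation re-seeds
igraph's RNG immediately before every call. Stage-1 seeds derive from the
global seed and a CRC32 of the sample's counts and coordinates — not its
name — so identical measurements yield identical partitions regardless of
labelling, ordering, or worker count; stage 2 sorts niches by sample id
before building its graph for the same reason. The pipeline output is
bytewise reproducible for a given seed, at any `n_workers`.

## The simulator

The generator emulates multi-sample SRT benchmarks: units on a 64×78 grid
(4992 units), four tissue regions in one of four geometries (horizontal
layers, diagonal layers, rings, quadrants), a row-stochastic 4×4
tissue-by-cell-type mixture table, 200 marker genes per type (800 markers,
plus 10% noisy genes → 889 genes total), and expression

`X_ij = (1/N_i) Σ_k δ(L_k, L_g)·E_g + E_s + ε, ε ~ N(0, σ² + σ_s²)`

with marker level E_g = 10 and base variance σ² = 1. Cell-based data uses
one cell per unit (N_i = 1); a spot-based preset draws N_i uniformly from
{1..6}. Noisy genes carry `U(0, E_g/2)` expression independent of cell
type — loud enough to matter, never dominant. Per-sample batch factors are
`E_s = batch_shift_frac · E_g · U(0,1)` and
`σ_s² = batch_var_frac · σ² · U(0,1)`; the extreme preset
(`batch_shift_frac=5.0`, `batch_var_frac=1.25`) allows shifts up to 500% of
the marker level and 125% extra variance. Negative draws are clipped at 0
so outputs behave as counts (the unclipped matrix is retained when
`clip_negative=False`).

What the simulator does *not* emulate: count-distribution realism (no
negative binomial overdispersion, no zero-inflation/dropout), within-region
spatial expression gradients, segmentation errors, or platform-specific
geometry (hexagonal Visium lattices, variable spot spacing). Passing tests
therefore demonstrate correctness of the algorithm under Gaussian
marker-mixture signal with additive batch effects — not performance on any
real platform's noise process.

## Numerical choices and degenerate inputs

- Correlation of a constant vector is undefined; such edge weights are set
  to 0 with a warning (they then fall below any sensible threshold).
- kNN distance ties are resolved by (rounded distance, index) lexsort, so
  lattice geometries are reproducible across BLAS/tree backends.
- Deviance inside the square root is floored at 0 against floating-point
  cancellation; genes with zero total count get residual 0.
- Rank-deficient inputs yield fewer PCs than requested, flagged on the
  result rather than erroring.
- Pruning keeps edges with weight exactly equal to the threshold.
- The SNN weight uses self-inclusive neighbour sets, so identical
  profiles score exactly 1 and far-separated clusters exactly 0.

## Problem sizes used in the shipped checks

The test suite exercises full-size single samples (4992 × 889) for the
simulator, stage-1, and composition checks, and 4-sample full-size runs for
clean and extreme-batch domain recovery; graph-algebra oracles run on 30–80
node fixtures where brute force is exact. The acceptance script simulates
one default sample and runs stage 1 on it.

## Known limitations

- Coordinates are treated as plain 2D Euclidean points; no correction for
  hexagonal array offsets or 3D stacks.
- Modularity-based Louvain inherits the resolution limit; very small true
  domains may be absorbed unless `resolution_stage2` is raised.
- The niche-count operating band was calibrated on ~5k-unit samples;
  much larger or sparser samples may need `resolution_stage1` adjusted.
- Stage 2 assumes a non-empty gene intersection across samples and a
  shared signal subspace; panels with disjoint gene sets are out of scope.
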