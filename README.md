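# spatialmnn

Integration of multiple spatially resolved transcriptomics (SRT) samples and
joint detection of spatial domains, built on mutual nearest neighbours (MNN)
over spatially coherent niches.

## The problem

SRT platforms (Visium, Slide-seq, MERFISH, STARmap, Xenium, ...) measure
gene expression together with each spot's or cell's 2D position. As studies
grow to tens or hundreds of tissue sections, the analyst needs spatial
domains — regions with a characteristic expression distribution — that are
*consistent across samples*, despite technical batch effects, and without
per-sample clustering followed by manual cluster matching. Classic MNN batch
correction solves cross-sample matching for dissociated single-cell data but
ignores the spatial coordinates; this package brings the MNN idea to tissue
space.

## The algorithm

**Stage 1 (per sample, trivially parallel).** For each sample with counts
`X` (M units × G genes):

1. Compute residuals of `X` under the null model `μ_ij = n_i π_j`
   (deviance residuals by default) and take the top `N` PCs, giving
   `Y ∈ ℝ^{M×N}` (default N = 30).
2. Build a k-nearest-neighbour graph `G = ⟨V, E⟩` on the spatial
   coordinates (Euclidean distance, default k = 6).
3. Weight each edge `e = (u, v)` by the correlation of
   neighbourhood-averaged embeddings,

   `W_e = Corr( Avg(Y[{V_u − V_u∩V_v, u}]), Avg(Y[{V_v − V_u∩V_v, v}]) )`,

   where `V_u`, `V_v` are the q spatially nearest neighbours of the two
   endpoints; shared neighbours are excluded from both sides so that the
   weight stays sharp at genuine tissue boundaries. (Plain pairwise Pearson
   or shared-nearest-neighbour weights are available.)
4. Prune edges with `W_e < 0.6` (default), then partition the graph with
   Louvain at high resolution (γ ≈ 10) into 100–200 small niches; dissolve
   niches smaller than 5 units into the neighbouring niche their members'
   spatial neighbours mostly belong to; sum ("pseudobulk") counts per niche.

**Stage 2 (across samples).** Stack all niches' pseudobulk profiles on the
common gene set, embed them jointly (Pearson residuals → PCA), and for each
niche find its k nearest niches *in every other sample* (default k = 15).
Niches `u`, `v` from different samples are connected iff `u ∈ V_v` and
`v ∈ V_u` — the mutuality condition. Louvain at low resolution (γ ≈ 1) on
this MNN graph yields domains shared across all samples, which are assigned
to every unit of every niche. Restricting candidates to other samples
prevents batch effects from over-connecting within-sample niches; an
`include_self_sample` option adds within-sample candidates when
sample-specific domains are expected.

The package also ships the matching multi-sample simulator (tissue patterns
× cell-type mixture table × marker-gene expression with batch effects) and
the evaluation metrics (ARI, NMI, landmark co-localization index).

## Worked example

```python
import spatialmnn as sm

# four samples with strong sample-wise batch effects
sims = sm.simulate_dataset(sm.SimConfig(
    n_samples=4, seed=23, batch_shift_frac=5.0, batch_var_frac=1.25))
out = sm.run_pipeline([x.sample for x in sims], sm.RunConfig(seed=23))

for sim in sims:
    p = next(q for q in out.partitions if q.sample_id == sim.sample.sample_id)
    print(p.sample_id, p.n_niches,
          sm.ari(sim.regions[p.kept_units], out.unit_domain[p.sample_id]))
```

prints (see `examples/integrate_and_detect_domains.py`):

```
per-sample batch shifts: [34.7, 32.1, 6.4, 5.7]
detected 5 shared domains (simulation has 4 regions)
  sim_1: 115 niches, ARI 0.900, NMI 0.868
  sim_2: 119 niches, ARI 0.936, NMI 0.917
  sim_3: 125 niches, ARI 0.837, NMI 0.843
  sim_4: 122 niches, ARI 0.827, NMI 0.806
```

Each sample of 4992 units is reduced to ~120 niches; the shared domain
labels recover the four simulated tissue regions with ARI 0.83–0.94 even
though the samples differ by additive shifts of up to ~35 expression units
(the marker level itself is 10). The `examples/` directory holds one short
script per capability: simulation, stage-1 niches, full integration, and
landmark co-localization.

## Command line

```bash
spatialmnn simulate --n-samples 4 --pattern rings --seed 7 --out data/
spatialmnn run --input manifest.csv --out results/ --k 6 --threshold 0.6
spatialmnn benchmark --pred results/domains.csv --truth data/truth.csv
```

`manifest.csv` lists `sample_id,path,format` with format one of `h5`,
`csv_pair`, `mtx_dir`.

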