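"""Stage 1: partition each pruned spatial graph into niches.

High-resolution Louvain clustering on the pruned spatial graph yields small,
spatially coherent niches (typically 100-200 per sample of a few thousand
units). Niches act as anchor points and as a data reduction: counts are
pseudobulked (summed) per niche before the cross-sample stage. Undersized
niches are dissolved into the neighbouring niche their members' spatial
neighbours mostly belong to.
"""

from __future__ import annotations

import random
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional

import igraph
import numpy as np

from .graph import (SpatialGraph, build_spatial_knn, compute_edge_weights,
                    prune_edges, smoothed_edge_weights)
from .io import RunConfig, SRTSample
from .reduction import drop_empty_units, reduce_sample

__all__ = [
    "NichePartition",
    "louvain_partition",
    "merge_small_niches",
    "pseudobulk_niches",
    "run_stage1",
    "sample_seed",
]


@dataclass
class NichePartition:
    """Spot-to-niche map plus per-niche pseudobulk profiles for one sample."""

    sample_id: str
    niche_of: np.ndarray            # unit index -> niche id (0..n_niches-1)
    niche_ids: np.ndarray
    pseudobulk: np.ndarray          # [n_niches, n_genes] summed counts
    niche_sizes: np.ndarray
    niche_centroids: np.ndarray     # [n_niches, 2]
    gene_ids: list
    unit_ids: list
    kept_units: np.ndarray = field(default=None)  # indices into original sample
    undersized_flagged: list = field(default_factory=list)
    report: dict = field(default_factory=dict)

    @property
    def n_niches(self) -> int:
        return len(self.niche_ids)


def sample_seed(global_seed: int, sample: SRTSample) -> int:
    """Stable per-sample seed, independent of processing order/worker count.

    Derived from the sample's *content* (counts + coords), not its id, so
    two samples with identical measurements get identical stage-1 results
    (exchangeability) and the seed survives renaming.
    """
    h = zlib.crc32(np.ascontiguousarray(sample.counts).tobytes())
    h = zlib.crc32(np.ascontiguousarray(sample.coords).tobytes(), h)
    return (int(global_seed) * 1_000_003 + h) % (2**31)


def _louvain_igraph(n_nodes, edges, weights, resolution, seed):
    g = igraph.Graph(n=n_nodes, edges=[tuple(e) for e in edges])
    igraph.set_random_number_generator(random.Random(int(seed) % (2**31)))
    kw = {"resolution": float(resolution)}
    if weights is not None:
        kw["weights"] = list(np.asarray(weights, dtype=float))
    part = g.community_multilevel(**kw)
    return np.asarray(part.membership, dtype=int)


def louvain_partition(graph: SpatialGraph, resolution: float,
                      seed: int = 0) -> np.ndarray:
    """Louvain community labels on the (weighted) spatial graph.

    Modularity assumes non-negative weights; any negative weight (possible
    only with permissive pruning thresholds) is clamped to 0 for community
    detection. Isolated nodes become singleton communities. Deterministic
    given the seed.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    w = None
    if graph.weights is not None and graph.n_edges:
        w = np.maximum(np.asarray(graph.weights, dtype=float), 0.0)
    return _louvain_igraph(graph.n_nodes, graph.edges, w, resolution, seed)


def merge_small_niches(labels, graph: SpatialGraph, min_size: int,
                       max_rounds: int = 100):
    """Dissolve niches smaller than ``min_size`` into neighbouring niches.

    Each member of an undersized niche is reassigned to the modal label
    among its spatial-graph neighbours, excluding the dissolving niche's own
    label (ties break toward the larger niche, then the smaller label id).
    Rounds repeat until no niche is undersized or no reassignment is
    possible; undersized niches whose members have no outside neighbours
    (isolated components) keep their label and are flagged.

    Returns (labels, flagged_labels).
    """
    labels = np.asarray(labels, dtype=int).copy()
    adj = graph.neighbor_lists()
    flagged = []
    for _ in range(max_rounds):
        ids, sizes = np.unique(labels, return_counts=True)
        size_of = dict(zip(ids.tolist(), sizes.tolist()))
        small = sorted([i for i, s in size_of.items() if s < min_size],
                       key=lambda i: (size_of[i], i))
        small = [s for s in small if s not in flagged]
        if not small:
            break
        changed = False
        for niche in small:
            members = np.flatnonzero(labels == niche)
            new = labels.copy()
            moved_any = False
            for m in members:
                cand = labels[adj[m]]
                cand = cand[cand != niche]
                if len(cand) == 0:
                    continue
                vals, cnts = np.unique(cand, return_counts=True)
                # modal label; ties -> larger niche, then smaller label id
                best = sorted(
                    zip(vals.tolist(), cnts.tolist()),
                    key=lambda t: (-t[1], -size_of.get(t[0], 0), t[0]))[0][0]
                new[m] = best
                moved_any = True
            if moved_any:
                labels = new
                changed = True
            else:
                flagged.append(niche)
        if not changed:
            break
    ids, sizes = np.unique(labels, return_counts=True)
    leftover = [int(i) for i, s in zip(ids, sizes)
                if s < min_size and i not in flagged]
    flagged = sorted(set(flagged + leftover) & set(ids.tolist()))
    if flagged:
        warnings.warn(f"{len(flagged)} undersized niches could not be merged "
                      "(isolated components); kept and flagged")
    return labels, flagged


def pseudobulk_niches(sample: SRTSample, labels,
                      sample_id: Optional[str] = None,
                      agg: str = "sum") -> NichePartition:
    """Aggregate counts per niche (sum by default, conserving totals)."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) != sample.n_units:
        raise ValueError("labels do not cover all units")
    niche_ids, dense = np.unique(labels, return_inverse=True)
    n_niches = len(niche_ids)
    pb = np.zeros((n_niches, sample.n_genes))
    np.add.at(pb, dense, sample.counts)
    sizes = np.bincount(dense, minlength=n_niches)
    cent = np.zeros((n_niches, 2))
    np.add.at(cent, dense, sample.coords)
    cent /= sizes[:, None]
    if agg == "mean":
        pb = pb / sizes[:, None]
    elif agg != "sum":
        raise ValueError(f"unknown aggregation {agg!r}")
    return NichePartition(
        sample_id=sample_id or sample.sample_id,
        niche_of=dense, niche_ids=np.arange(n_niches),
        pseudobulk=pb, niche_sizes=sizes, niche_centroids=cent,
        gene_ids=list(sample.gene_ids), unit_ids=list(sample.unit_ids))


def run_stage1(sample: SRTSample, config: RunConfig) -> NichePartition:
    """Full per-sample stage: reduce, graph, weight, prune, cluster, merge,
    pseudobulk. Deterministic given the config seed; independent per sample,
    so samples can be processed concurrently without changing the result."""
    sample.validate()
    filtered, kept = drop_empty_units(sample)
    reduced = reduce_sample(filtered, config)
    graph = build_spatial_knn(filtered.coords, config.k_spatial,
                              sample_id=filtered.sample_id)
    if config.prune_mode == "smoothed":
        w = smoothed_edge_weights(graph, reduced, config.q_smooth)
    else:
        graph = compute_edge_weights(graph, reduced, mode=config.weight_mode,
                                     k_snn=config.k_snn)
        w = graph.weights
    pruned, prune_report = prune_edges(graph, w, config.prune_threshold)
    seed = sample_seed(config.seed, filtered)
    labels = louvain_partition(pruned, config.resolution_stage1, seed=seed)
    # merge walks the unpruned spatial graph: a niche isolated by pruning is
    # still spatially surrounded, and "nearby" means physical neighbours
    labels, flagged = merge_small_niches(labels, graph, config.min_niche_size)
    part = pseudobulk_niches(filtered, labels)
    part.kept_units = kept
    # flagged labels -> dense niche ids used by the partition
    uniq = np.unique(labels).tolist()
    part.undersized_flagged = [uniq.index(f) for f in flagged]
    part.report = {
        "sample_id": filtered.sample_id,
        "n_units": filtered.n_units,
        "n_niches": part.n_niches,
        "seed": seed,
        "pruning": prune_report,
    }
    return part
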