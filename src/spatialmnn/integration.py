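"""Stage 2: mutual-nearest-neighbour integration across samples.

All niches from all samples are embedded jointly (Pearson residuals of the
pseudobulk matrix on the common gene set, then PCA). For each niche and each
other sample, the k nearest niches of that sample are found in the joint PC
space; a pair is connected only if each lies in the other's list (the
mutuality condition). Louvain at low resolution on this MNN graph yields
spatial domains shared across samples, which are finally propagated to every
unit of every niche. Restricting candidate neighbours to *other* samples is
what prevents batch effects from over-connecting within-sample niches.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .io import RunConfig, SRTSample
from .niches import NichePartition, run_stage1, _louvain_igraph
from .reduction import null_residuals, pca

__all__ = [
    "MNNGraph",
    "DomainAssignment",
    "joint_embed_niches",
    "build_mnn_graph",
    "cluster_mnn_graph",
    "propagate_labels",
    "run_pipeline",
]


@dataclass
class MNNGraph:
    """Cross-sample mutual-kNN graph over niches."""

    nodes: list                     # list of (sample_id, niche_id)
    embedding: np.ndarray           # [n_total_niches, n_pcs]
    edges: np.ndarray               # (E, 2) int, u < v, indices into nodes
    knn_sets: dict                  # (node_index, target_sample) -> ndarray
    include_self_sample: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class DomainAssignment:
    """Shared domain labels: per niche and propagated per unit."""

    niche_domain: dict              # (sample_id, niche_id) -> domain id
    unit_domain: dict               # sample_id -> ndarray of domain per unit
    n_domains: int
    unassigned: list = field(default_factory=list)
    report: dict = field(default_factory=dict)
    partitions: list = field(default_factory=list)


def joint_embed_niches(partitions, n_pcs: int, residual_kind: str = "pearson"):
    """Embed all niches of all samples in one PC space.

    Pseudobulk rows are stacked on the sorted intersection of gene ids
    across samples, converted to null-model residuals, and reduced by PCA.
    Returns (embedding, nodes) where nodes[i] = (sample_id, niche_id).
    """
    if not partitions:
        raise ValueError("no partitions")
    common = set(partitions[0].gene_ids)
    for p in partitions[1:]:
        common &= set(p.gene_ids)
    if not common:
        raise ValueError("empty gene intersection across samples")
    genes = sorted(common)
    blocks, nodes = [], []
    for p in partitions:
        col = {g: j for j, g in enumerate(p.gene_ids)}
        idx = np.array([col[g] for g in genes])
        blocks.append(p.pseudobulk[:, idx])
        nodes.extend((p.sample_id, int(n)) for n in p.niche_ids)
    stacked = np.vstack(blocks)
    resid = null_residuals(stacked, kind=residual_kind)
    k = min(n_pcs, min(stacked.shape) - 1)
    scores, _, _ = pca(resid, k)
    return scores, nodes


def build_mnn_graph(embedding, nodes, k_mnn: int,
                    include_self_sample: bool = False) -> MNNGraph:
    """Mutual-kNN graph: edge (u, v) iff each is in the other's per-sample
    k-nearest list (Euclidean distance in the joint embedding).

    With ``include_self_sample``, the same rule additionally applies within
    a niche's own sample (excluding the niche itself), enabling detection of
    sample-specific domains. If a target sample has fewer than ``k_mnn``
    niches its whole set is used.
    """
    embedding = np.asarray(embedding, dtype=float)
    if k_mnn < 1:
        raise ValueError("k_mnn must be >= 1")
    sample_ids = [s for s, _ in nodes]
    samples = sorted(set(sample_ids))
    if len(samples) < 2 and not include_self_sample:
        raise ValueError("no cross-sample pairs: need >= 2 samples "
                         "(or include_self_sample=True)")
    idx_of = {s: np.array([i for i, sid in enumerate(sample_ids) if sid == s])
              for s in samples}
    knn_sets = {}
    for target in samples:
        rows = idx_of[target]
        nn = NearestNeighbors(n_neighbors=min(k_mnn + 1, len(rows)))
        nn.fit(embedding[rows])
        _, neigh = nn.kneighbors(embedding)
        for i in range(len(nodes)):
            cand = rows[neigh[i]]
            if sample_ids[i] == target:
                if not include_self_sample:
                    continue
                cand = cand[cand != i]
            knn_sets[(i, target)] = cand[:k_mnn]
    edge_set = set()
    for (i, target), cand in knn_sets.items():
        for j in cand:
            j = int(j)
            back = knn_sets.get((j, sample_ids[i]))
            if back is not None and i in back:
                edge_set.add((min(i, j), max(i, j)))
    edges = (np.array(sorted(edge_set), dtype=int)
             if edge_set else np.empty((0, 2), dtype=int))
    return MNNGraph(nodes=list(nodes), embedding=embedding, edges=edges,
                    knn_sets=knn_sets, include_self_sample=include_self_sample)


def cluster_mnn_graph(graph: MNNGraph, resolution: float = 1.0, seed: int = 0,
                      keep_unassigned: bool = False):
    """Louvain communities of the MNN graph -> niche domain map.

    Edges are unweighted (mutuality is binary). Domain ids are renumbered by
    descending niche count (ties by first appearance). Niches isolated in
    the MNN graph inherit the domain of the nearest labelled niche in
    embedding space, or stay at -1 with ``keep_unassigned``.

    Returns (niche_domain dict, unassigned node list).
    """
    if graph.n_nodes == 0:
        raise ValueError("empty MNN graph")
    membership = _louvain_igraph(graph.n_nodes, graph.edges, None,
                                 resolution, seed)
    degree = np.zeros(graph.n_nodes, dtype=int)
    for u, v in graph.edges:
        degree[u] += 1
        degree[v] += 1
    isolated = np.flatnonzero(degree == 0)
    labelled = np.flatnonzero(degree > 0)
    unassigned = [graph.nodes[i] for i in isolated]
    if len(labelled) == 0:
        labelled = np.arange(graph.n_nodes)
        isolated = np.array([], dtype=int)
        unassigned = []
    if len(isolated) and not keep_unassigned:
        nn = NearestNeighbors(n_neighbors=1).fit(graph.embedding[labelled])
        _, j = nn.kneighbors(graph.embedding[isolated])
        membership[isolated] = membership[labelled[j[:, 0]]]
    # renumber by descending community size
    ids, counts = np.unique(membership[membership >= 0] if keep_unassigned
                            else membership, return_counts=True)
    order = ids[np.argsort(-counts, kind="mergesort")]
    remap = {int(old): new for new, old in enumerate(order)}
    niche_domain = {}
    for i, node in enumerate(graph.nodes):
        if keep_unassigned and i in set(isolated.tolist()):
            niche_domain[node] = -1
        else:
            niche_domain[node] = remap[int(membership[i])]
    return niche_domain, unassigned


def propagate_labels(partitions, niche_domain) -> DomainAssignment:
    """Assign every unit the domain of its niche."""
    unit_domain = {}
    for p in partitions:
        doms = np.empty(len(p.niche_ids), dtype=int)
        for j, nid in enumerate(p.niche_ids):
            key = (p.sample_id, int(nid))
            if key not in niche_domain:
                raise ValueError(f"niche {key} has no domain")
            doms[j] = niche_domain[key]
        unit_domain[p.sample_id] = doms[p.niche_of]
    n_domains = len({d for d in niche_domain.values() if d >= 0})
    return DomainAssignment(niche_domain=dict(niche_domain),
                            unit_domain=unit_domain, n_domains=n_domains)


def _stage1_job(sample, config):
    return run_stage1(sample, config)


def run_pipeline(samples, config: RunConfig | None = None) -> DomainAssignment:
    """Two-stage pipeline over a list of samples.

    Stage 1 runs independently per sample (optionally in parallel with
    ``config.n_workers``; the result is identical for any worker count since
    every per-sample seed derives only from the global seed and the sample
    id). Stage 2 embeds all niches jointly, builds the MNN graph, clusters
    it at low resolution, and propagates labels to units.
    """
    if config is None:
        config = RunConfig()
    if not samples:
        raise ValueError("no samples")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    if len(samples) == 1 and not config.include_self_sample:
        raise ValueError("no cross-sample pairs: need >= 2 samples "
                         "(or include_self_sample=True)")
    if config.n_workers > 1 and len(samples) > 1:
        from joblib import Parallel, delayed
        partitions = Parallel(n_jobs=config.n_workers)(
            delayed(_stage1_job)(s, config) for s in samples)
    else:
        partitions = [run_stage1(s, config) for s in samples]
    # canonical order: stage-2 output must not depend on input sample order
    partitions = sorted(partitions, key=lambda p: p.sample_id)
    embedding, nodes = joint_embed_niches(
        partitions, config.n_pcs, residual_kind=config.residual_kind_stage2)
    mnn = build_mnn_graph(embedding, nodes, config.k_mnn,
                          include_self_sample=config.include_self_sample)
    stage2_seed = (int(config.seed) * 1_000_003 +
                   zlib.crc32(b"stage2")) % (2**31)
    niche_domain, unassigned = cluster_mnn_graph(
        mnn, resolution=config.resolution_stage2, seed=stage2_seed,
        keep_unassigned=config.keep_unassigned)
    assignment = propagate_labels(partitions, niche_domain)
    assignment.unassigned = unassigned
    assignment.report = {
        "config": {k: v for k, v in vars(config).items()},
        "stage1": [p.report for p in partitions],
        "niche_counts": {p.sample_id: p.n_niches for p in partitions},
        "n_mnn_edges": int(mnn.n_nodes and len(mnn.edges)),
        "n_domains": assignment.n_domains,
        "n_unassigned": len(unassigned),
        "stage2_seed": stage2_seed,
    }
    assignment.partitions = partitions
    return assignment
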