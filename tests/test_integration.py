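import numpy as np
import pytest

from spatialmnn import (NichePartition, RunConfig, joint_embed_niches,
                        build_mnn_graph, cluster_mnn_graph, propagate_labels,
                        run_pipeline, ari)
from spatialmnn.integration import MNNGraph
from conftest import small_sim


def fake_partition(sample_id, pseudobulk, gene_ids=None, niche_of=None):
    pseudobulk = np.asarray(pseudobulk, float)
    n = pseudobulk.shape[0]
    niche_of = (np.arange(n) if niche_of is None
                else np.asarray(niche_of, int))
    sizes = np.bincount(niche_of, minlength=n)
    return NichePartition(
        sample_id=sample_id, niche_of=niche_of, niche_ids=np.arange(n),
        pseudobulk=pseudobulk, niche_sizes=sizes,
        niche_centroids=np.zeros((n, 2)),
        gene_ids=gene_ids or [f"g{j}" for j in range(pseudobulk.shape[1])],
        unit_ids=[f"{sample_id}_u{i}" for i in range(len(niche_of))])


class TestJointEmbed:
    def test_identical_samples_give_identical_rows(self, rng):
        pb = rng.poisson(20, size=(6, 10)).astype(float) + 1
        p1 = fake_partition("a", pb)
        p2 = fake_partition("b", pb)
        emb, nodes = joint_embed_niches([p1, p2], n_pcs=4)
        np.testing.assert_allclose(emb[:6], emb[6:], atol=1e-9)
        assert nodes[0] == ("a", 0) and nodes[6] == ("b", 0)

    def test_gene_intersection_sorted(self, rng):
        pb = rng.poisson(20, size=(4, 3)).astype(float) + 1
        p1 = fake_partition("a", pb, gene_ids=["gC", "gA", "gB"])
        p2 = fake_partition("b", pb[:, ::-1], gene_ids=["gB", "gA", "gC"])
        emb, _ = joint_embed_niches([p1, p2], n_pcs=2)
        assert np.all(np.isfinite(emb))

    def test_empty_intersection_raises(self, rng):
        pb = rng.poisson(20, size=(3, 2)).astype(float) + 1
        p1 = fake_partition("a", pb, gene_ids=["g1", "g2"])
        p2 = fake_partition("b", pb, gene_ids=["h1", "h2"])
        with pytest.raises(ValueError, match="intersection"):
            joint_embed_niches([p1, p2], n_pcs=2)

    def test_pcs_match_eigen_oracle(self, rng):
        """Embedding variances equal covariance eigenvalues of the residuals."""
        from spatialmnn import null_residuals, pca
        pb = rng.poisson(30, size=(10, 8)).astype(float) + 1
        p1 = fake_partition("a", pb[:5])
        p2 = fake_partition("b", pb[5:])
        emb, _ = joint_embed_niches([p1, p2], n_pcs=4)
        resid = null_residuals(pb, kind="pearson")
        eig = np.sort(np.linalg.eigvalsh(np.cov(resid, rowvar=False)))[::-1]
        np.testing.assert_allclose(emb.var(axis=0, ddof=1), eig[:emb.shape[1]],
                                   rtol=1e-8)


class TestBuildMnnGraph:
    def test_two_singleton_samples_forced_mutuality(self):
        emb = np.array([[0.0, 0], [1, 0]])
        nodes = [("a", 0), ("b", 0)]
        g = build_mnn_graph(emb, nodes, k_mnn=1)
        assert [tuple(e) for e in g.edges] == [(0, 1)]

    def test_far_outlier_is_isolated(self, rng):
        emb = np.vstack([rng.normal(size=(4, 2)),
                         rng.normal(size=(4, 2)),
                         [[1e6, 1e6]]])
        nodes = ([("a", i) for i in range(4)] + [("b", i) for i in range(4)]
                 + [("b", 4)])
        g = build_mnn_graph(emb, nodes, k_mnn=2)
        deg = np.zeros(9, int)
        for u, v in g.edges:
            deg[u] += 1
            deg[v] += 1
        assert deg[8] == 0

    def test_no_within_sample_edges_by_default(self, rng):
        emb = rng.normal(size=(12, 3))
        nodes = [("a", i) for i in range(6)] + [("b", i) for i in range(6)]
        g = build_mnn_graph(emb, nodes, k_mnn=3)
        for u, v in g.edges:
            assert nodes[u][0] != nodes[v][0]

    def test_matches_brute_force_mutuality(self, rng):
        """Edge set equals brute-force mutual-kNN over all cross-sample
        pairs on a 3-sample, 15-niche fixture."""
        emb = rng.normal(size=(15, 4))
        nodes = [(s, i) for s in "abc" for i in range(5)]
        k = 2
        g = build_mnn_graph(emb, nodes, k_mnn=k)
        d = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
        def knn_in(u, target):
            cand = [j for j in range(15) if nodes[j][0] == target]
            return set(sorted(cand, key=lambda j: d[u, j])[:k])
        expected = set()
        for u in range(15):
            for v in range(15):
                su, sv = nodes[u][0], nodes[v][0]
                if su == sv or u >= v:
                    continue
                if v in knn_in(u, sv) and u in knn_in(v, su):
                    expected.add((u, v))
        assert {tuple(e) for e in g.edges} == expected

    def test_single_sample_without_self_raises(self, rng):
        emb = rng.normal(size=(4, 2))
        nodes = [("a", i) for i in range(4)]
        with pytest.raises(ValueError, match="cross-sample"):
            build_mnn_graph(emb, nodes, k_mnn=2)
        g = build_mnn_graph(emb, nodes, k_mnn=2, include_self_sample=True)
        assert g.n_nodes == 4 and len(g.edges) > 0


class TestClusterMnnGraph:
    def _graph(self, emb, nodes, edges):
        return MNNGraph(nodes=nodes, embedding=np.asarray(emb, float),
                        edges=np.array(edges, int).reshape(-1, 2),
                        knn_sets={})

    def test_two_components_two_domains(self):
        nodes = [("a", i) for i in range(3)] + [("b", i) for i in range(3)]
        emb = np.arange(12.).reshape(6, 2)
        edges = [(0, 3), (0, 4), (1, 3), (1, 4), (2, 5)]
        nd, _ = cluster_mnn_graph(self._graph(emb, nodes, edges), 1.0, seed=0)
        assert len(set(nd.values())) == 2
        assert nd[("a", 0)] == nd[("b", 0)]
        assert nd[("a", 2)] == nd[("b", 2)]

    def test_single_clique_single_domain(self):
        import itertools
        nodes = [("a", 0), ("a", 1), ("b", 0), ("b", 1)]
        edges = list(itertools.combinations(range(4), 2))
        nd, _ = cluster_mnn_graph(self._graph(np.zeros((4, 2)), nodes, edges),
                                  1.0, seed=0)
        assert len(set(nd.values())) == 1

    def test_isolated_niche_inherits_nearest_domain(self):
        nodes = [("a", 0), ("b", 0), ("a", 1)]
        emb = np.array([[0., 0], [1, 0], [1.4, 0]])
        nd, unassigned = cluster_mnn_graph(self._graph(emb, nodes, [(0, 1)]),
                                           1.0, seed=0)
        assert unassigned == [("a", 1)]
        assert nd[("a", 1)] == nd[("b", 0)]

    def test_keep_unassigned_labels_minus_one(self):
        nodes = [("a", 0), ("b", 0), ("a", 1)]
        emb = np.array([[0., 0], [1, 0], [5, 0]])
        nd, _ = cluster_mnn_graph(self._graph(emb, nodes, [(0, 1)]), 1.0,
                                  seed=0, keep_unassigned=True)
        assert nd[("a", 1)] == -1

    def test_domains_numbered_by_descending_size(self):
        import itertools
        nodes = [("a", i) for i in range(5)] + [("b", i) for i in range(5)]
        big = list(itertools.combinations([0, 1, 2, 5, 6, 7], 2))
        smallc = list(itertools.combinations([3, 4, 8, 9], 2))
        nd, _ = cluster_mnn_graph(
            self._graph(np.zeros((10, 2)), nodes, big + smallc), 1.0, seed=0)
        assert nd[("a", 0)] == 0 and nd[("a", 3)] == 1


class TestPropagateLabels:
    def test_single_niche_single_domain(self, rng):
        pb = rng.poisson(9, size=(1, 4)).astype(float)
        p = fake_partition("a", pb, niche_of=np.zeros(7, int))
        out = propagate_labels([p], {("a", 0): 3})
        assert set(out.unit_domain["a"]) == {3}

    def test_counts_per_domain_conserved(self, rng):
        niche_of = np.array([0, 0, 1, 1, 1, 2])
        pb = rng.poisson(9, size=(3, 4)).astype(float)
        p = fake_partition("a", pb, niche_of=niche_of)
        out = propagate_labels([p], {("a", 0): 0, ("a", 1): 1, ("a", 2): 0})
        assert (out.unit_domain["a"] == 0).sum() == 3
        assert (out.unit_domain["a"] == 1).sum() == 3

    def test_lookup_composition_by_hand(self, rng):
        niche_of = np.array([2, 0, 1, 1, 0])
        pb = rng.poisson(9, size=(3, 4)).astype(float)
        p = fake_partition("a", pb, niche_of=niche_of)
        nd = {("a", 0): 5, ("a", 1): 6, ("a", 2): 7}
        out = propagate_labels([p], nd)
        np.testing.assert_array_equal(out.unit_domain["a"], [7, 5, 6, 6, 5])

    def test_missing_domain_raises(self, rng):
        p = fake_partition("a", rng.poisson(9, size=(2, 3)).astype(float))
        with pytest.raises(ValueError, match="no domain"):
            propagate_labels([p], {("a", 0): 1})


class TestRunPipeline:
    CFG = dict(n_pcs=10, k_mnn=8, seed=0)

    def test_identical_copies_get_identical_domains(self):
        """Exchangeability: two samples with identical measurements receive
        identical per-unit domain labels."""
        sim = small_sim(n_samples=1, seed=6)[0]
        import copy
        s1 = copy.deepcopy(sim.sample)
        s2 = copy.deepcopy(sim.sample)
        s2.sample_id = "copy"
        s2.unit_ids = [f"copy_{u}" for u in s2.unit_ids]
        out = run_pipeline([s1, s2], RunConfig(**self.CFG))
        np.testing.assert_array_equal(out.unit_domain[s1.sample_id],
                                      out.unit_domain["copy"])

    def test_sample_order_invariance(self):
        sims = small_sim(n_samples=3, seed=7)
        samples = [x.sample for x in sims]
        out1 = run_pipeline(samples, RunConfig(**self.CFG))
        out2 = run_pipeline(samples[::-1], RunConfig(**self.CFG))
        for s in samples:
            np.testing.assert_array_equal(out1.unit_domain[s.sample_id],
                                          out2.unit_domain[s.sample_id])

    def test_worker_count_invariance(self):
        sims = small_sim(n_samples=3, seed=8)
        samples = [x.sample for x in sims]
        out1 = run_pipeline(samples, RunConfig(**self.CFG, n_workers=1))
        out2 = run_pipeline(samples, RunConfig(**self.CFG, n_workers=2))
        assert out1.niche_domain == out2.niche_domain
        for s in samples:
            np.testing.assert_array_equal(out1.unit_domain[s.sample_id],
                                          out2.unit_domain[s.sample_id])

    def test_domain_recovery_on_small_clean_simulation(self):
        sims = small_sim(n_samples=3, seed=10)
        out = run_pipeline([x.sample for x in sims], RunConfig(**self.CFG))
        scores = [ari(sim.regions[p.kept_units],
                      out.unit_domain[sim.sample.sample_id])
                  for sim, p in zip(sims, sorted(out.partitions,
                                                 key=lambda p: p.sample_id))]
        assert min(scores) > 0.5

    def test_duplicate_sample_ids_rejected(self):
        sim = small_sim(n_samples=1, seed=1)[0]
        with pytest.raises(ValueError, match="duplicate"):
            run_pipeline([sim.sample, sim.sample], RunConfig(**self.CFG))
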