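"""Hypergeometric enrichment, the spanning score, ranking and BH-FDR."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import hypergeom_tail_exact
from mirspan import (Clustering, Interactome, MirnaFamily, SeedNetwork,
                     ValidationError, bh_fdr, hallmark_enrichment,
                     hypergeom_upper_tail, mirna_enrichment_profile,
                     rank_families, spanning_score)
from mirspan.io import GeneSetCollection


class TestHypergeomUpperTail:
    def test_zero_overlap_is_one(self):
        assert hypergeom_upper_tail(10, 4, 5, 0) == 1.0

    def test_worked_example(self):
        assert hypergeom_upper_tail(10, 4, 5, 3) == pytest.approx(66 / 252,
                                                                  abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_exact_enumeration(self, data):
        N = data.draw(st.integers(1, 20))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        assert hypergeom_upper_tail(N, K, n, k) == pytest.approx(
            hypergeom_tail_exact(N, K, n, k), abs=1e-12)

    def test_pmf_normalizes(self):
        for N, K, n in [(10, 4, 5), (15, 7, 9), (20, 20, 3)]:
            total = sum(hypergeom_tail_exact(N, K, n, k)
                        - hypergeom_tail_exact(N, K, n, k + 1)
                        for k in range(min(K, n) + 1))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_monotone_nonincreasing_in_k(self):
        ps = [hypergeom_upper_tail(30, 10, 12, k) for k in range(11)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("args", [(10, 11, 5, 0), (10, 4, 11, 0),
                                      (10, 4, 5, 5), (10, 4, 3, 4),
                                      (10, -1, 5, 0)])
    def test_bound_violations_fatal(self, args):
        with pytest.raises(ValidationError):
            hypergeom_upper_tail(*args)


def _fixture_profile():
    """12-gene interactome, 8-node network split into 2 modules of 4, family
    targeting {G1,G2,G5,G6,G9}."""
    genes = [f"G{i}" for i in range(1, 13)]
    g = nx.Graph()
    g.add_nodes_from(genes)
    g.add_edges_from(zip(genes, genes[1:]))
    inter = Interactome(graph=g, source_counts={})
    net_nodes = [f"G{i}" for i in range(1, 9)]
    sub = g.subgraph(net_nodes).copy()
    net = SeedNetwork(graph=sub, seeds=frozenset(net_nodes), parent=inter)
    modules = [[f"G{i}" for i in range(1, 5)], [f"G{i}" for i in range(5, 9)]]
    clustering = Clustering(assignment={v: c for c, mm in enumerate(modules)
                                        for v in mm},
                            n_modules=2, modularity=0.0, modules=modules)
    family = MirnaFamily("fam", ["fam"], {"G1", "G2", "G5", "G6", "G9"})
    return family, inter, net, clustering


class TestEnrichmentProfile:
    def test_network_and_module_worked_values(self):
        family, inter, net, clustering = _fixture_profile()
        network, per_cluster = mirna_enrichment_profile(family, inter, net,
                                                        clustering)
        assert (network.N, network.K, network.n, network.k) == (12, 5, 8, 4)
        assert network.p_value == pytest.approx(210 / 495, abs=1e-12)
        assert per_cluster[0].k == 2
        assert per_cluster[0].p_value == pytest.approx(285 / 495, abs=1e-12)

    def test_empty_target_family_is_valid_with_p_one(self):
        family, inter, net, clustering = _fixture_profile()
        family = MirnaFamily("none", ["none"], {"NOTPRESENT"})
        network, per_cluster = mirna_enrichment_profile(family, inter, net,
                                                        clustering)
        assert network.K == 0 and network.p_value == 1.0
        assert all(r.p_value == 1.0 for r in per_cluster)
        result = spanning_score("none", (network, per_cluster))
        assert result.enriched_cluster_count == 0
        assert result.spanning_score == pytest.approx(0.0)

    def test_module_overlaps_sum_to_network_overlap(self, small_scenario):
        from mirspan import build_seed_network, map_seeds, spectral_partition

        sc = small_scenario
        net = build_seed_network(sc.interactome, map_seeds(sc.interactome,
                                                           sc.seeds))
        clustering = spectral_partition(net)
        for fam in sc.families[:6]:
            network, per_cluster = mirna_enrichment_profile(
                fam, sc.interactome, net, clustering)
            assert sum(r.k for r in per_cluster) == network.k


class TestSpanningScore:
    def test_direct_arithmetic(self):
        net = _enr(p=0.01, k=5)
        clusters = [_enr(p=0.01, k=2), _enr(p=0.2, k=2), _enr(p=0.03, k=1)]
        r = spanning_score("f", (net, clusters), alpha=0.05)
        assert r.enriched_cluster_count == 2
        assert r.clusters_with_targets == 3
        assert r.spanning_score == pytest.approx(2.99)

    def test_score_bounds(self):
        net = _enr(p=1.0, k=0)
        clusters = [_enr(p=1.0, k=0)] * 4
        r = spanning_score("f", (net, clusters))
        assert r.spanning_score == 0.0
        assert 0 <= r.spanning_score < len(clusters) + 1

    def test_invalid_alpha(self):
        with pytest.raises(ValidationError):
            spanning_score("f", (_enr(p=0.5, k=1), []), alpha=0.0)


def _enr(p, k, N=100, K=10, n=20):
    from mirspan import EnrichmentResult

    return EnrichmentResult(N=N, K=K, n=n, k=k, p_value=p)


class TestRankFamilies:
    def test_sorts_descending(self):
        rs = [spanning_score(f"f{i}", (_enr(p=p, k=k), clusters))
              for i, (p, k, clusters) in enumerate([
                  (1.0, 0, []),
                  (0.01, 5, [_enr(p=0.01, k=3), _enr(p=0.01, k=2)]),
                  (0.5, 2, [_enr(p=0.02, k=2)]),
              ])]
        ranked = rank_families(rs)
        assert [r.family_id for r in ranked] == ["f1", "f2", "f0"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_tie_broken_by_larger_network_overlap(self):
        a = spanning_score("abig", (_enr(p=0.2, k=10), []))
        b = spanning_score("bsmall", (_enr(p=0.2, k=4), []))
        ranked = rank_families([b, a])
        assert ranked[0].family_id == "abig"

    def test_permutation_invariance(self, small_scenario):
        from mirspan import build_seed_network, map_seeds, spectral_partition

        sc = small_scenario
        net = build_seed_network(sc.interactome, map_seeds(sc.interactome,
                                                           sc.seeds))
        clustering = spectral_partition(net)
        scored = [spanning_score(
            f.family_id, mirna_enrichment_profile(f, sc.interactome, net,
                                                  clustering))
            for f in sc.families]
        order_a = [r.family_id for r in rank_families(scored)]
        order_b = [r.family_id for r in rank_families(scored[::-1])]
        assert order_a == order_b


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == [pytest.approx(0.03)]

    def test_step_up_arithmetic(self):
        assert bh_fdr([0.01, 0.04]) == [pytest.approx(0.02),
                                        pytest.approx(0.04)]

    def test_equal_spacing_collapses(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_adjusted_at_least_raw_and_monotone(self):
        raw = [0.001, 0.01, 0.02, 0.2, 0.6, 1.0]
        adj = bh_fdr(raw)
        assert all(a >= r for a, r in zip(adj, raw))
        assert adj == sorted(adj)

    def test_out_of_range_fatal(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 0.0])
        with pytest.raises(ValidationError):
            bh_fdr([1.5])


class TestHallmarkEnrichment:
    def _collection(self):
        return GeneSetCollection(sets={
            "MATCH": ("d", {"A", "B", "C"}),
            "DISJOINT": ("d", {"X", "Y"}),
            "PARTIAL": ("d", {"A", "X"}),
        })

    def test_identical_set_is_most_significant(self):
        universe = {"A", "B", "C", "X", "Y", "Z"}
        table = hallmark_enrichment({"A", "B", "C"}, self._collection(),
                                    universe)
        assert table.iloc[0]["set_name"] == "MATCH"
        assert (table["fdr_adjusted_p"] >= table["p_value"] - 1e-15).all()
        assert np.allclose(table["neg_log10_p"],
                           -np.log10(table["p_value"]))

    def test_disjoint_set_last_with_p_one(self):
        universe = {"A", "B", "C", "X", "Y", "Z"}
        table = hallmark_enrichment({"A", "B", "C"}, self._collection(),
                                    universe)
        assert table.iloc[-1]["set_name"] == "DISJOINT"
        assert table.iloc[-1]["p_value"] == 1.0

    def test_out_of_universe_query_dropped_with_count(self):
        table = hallmark_enrichment({"A", "NOTHERE"}, self._collection(),
                                    {"A", "B", "X"})
        assert table.attrs["n_query_dropped"] == 1

    def test_empty_universe_fatal(self):
        with pytest.raises(ValidationError):
            hallmark_enrichment({"A"}, self._collection(), set())
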