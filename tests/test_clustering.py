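"""Subsequence extraction, similarity graph and Markov clustering."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrrcensus.annotation_io import DomainHit, ProteinRecord, ValidationError
from lrrcensus.lrr_clustering import (
    ClusterSet,
    SimilarityEdge,
    build_graph,
    cluster_stats,
    extract_subsequences,
    mcl,
    read_edges,
    write_clusters,
    write_edges,
)
from lrrcensus.synthetic_data import generate_similarity_graph

from _oracles import dense_mcl_partition


class TestExtractSubsequences:
    def test_slicing_is_one_based_inclusive(self):
        protein = ProteinRecord("p1", "s1", 9, sequence="MKLRRAAAA")
        hit = DomainHit("p1", "PF00560", 3, 5)
        [sub] = extract_subsequences([protein], [hit])
        assert sub.residues == "LRR"
        assert sub.id == "p1/3-5"

    def test_non_lrr_hits_ignored(self):
        protein = ProteinRecord("p1", "s1", 9, sequence="MKLRRAAAA")
        hit = DomainHit("p1", "PF00069", 3, 5)
        assert extract_subsequences([protein], [hit]) == []

    def test_two_hits_two_distinct_ids(self):
        protein = ProteinRecord("p1", "s1", 12, sequence="MKLRRAAAALRR")
        hits = [DomainHit("p1", "PF00560", 3, 5), DomainHit("p1", "PF00560", 10, 12)]
        subs = extract_subsequences([protein], hits)
        assert [s.id for s in subs] == ["p1/3-5", "p1/10-12"]

    def test_out_of_range_hit_is_error(self):
        protein = ProteinRecord("p1", "s1", 5, sequence="MKLRR")
        with pytest.raises(ValidationError):
            extract_subsequences([protein], [DomainHit("p1", "PF00560", 3, 9)])


class TestBuildGraph:
    def test_weight_is_negative_log10(self):
        g = build_graph([SimilarityEdge("a", "b", 1e-20)])
        assert g["a"]["b"]["weight"] == pytest.approx(20.0)

    def test_cutoff_excludes_weak_edges(self):
        g = build_graph([SimilarityEdge("a", "b", 1e-10)], e_cutoff=1e-15)
        assert not g.has_edge("a", "b")
        assert set(g.nodes()) == {"a", "b"}  # nodes survive as singleton material

    def test_zero_evalue_capped(self):
        g = build_graph([SimilarityEdge("a", "b", 0.0)])
        assert g["a"]["b"]["weight"] == pytest.approx(200.0)


class TestMCL:
    def test_disjoint_cliques_never_merge(self):
        edges = []
        for grp in ("x", "y"):
            for i in range(4):
                for j in range(i + 1, 4):
                    edges.append(SimilarityEdge(f"{grp}{i}", f"{grp}{j}", 1e-30))
        for inflation in (1.2, 1.5, 2.0, 4.0):
            cs = mcl(build_graph(edges), inflation=inflation)
            assert sorted(len(c) for c in cs.clusters) == [4, 4]
            assert not cs.singletons

    def test_single_node_is_singleton(self):
        g = build_graph([], nodes=["lonely"])
        cs = mcl(g)
        assert cs.clusters == () and cs.singletons == {"lonely"}

    def test_barbell_graph_matches_dense_oracle_frozen_result(self):
        """Two 6-cliques (within e=1e-30) joined by one weak passing edge
        (e=1e-16): at inflation 1.5 MCL cuts the bridge, giving the two
        cliques. Expected assignment computed with the independent dense
        oracle and frozen here."""
        edges = []
        for grp in ("a", "b"):
            for i in range(6):
                for j in range(i + 1, 6):
                    edges.append(SimilarityEdge(f"{grp}{i}", f"{grp}{j}", 1e-30))
        edges.append(SimilarityEdge("a0", "b0", 1e-16))
        cs = mcl(build_graph(edges), inflation=1.5)
        expected = (
            tuple(f"a{i}" for i in range(6)),
            tuple(f"b{i}" for i in range(6)),
        )
        assert cs.clusters == expected and not cs.singletons
        oracle_clusters, oracle_singles = dense_mcl_partition(
            [n for c in expected for n in c],
            [(e.a, e.b, -math.log10(e.e_value)) for e in edges],
            inflation=1.5,
        )
        assert frozenset(cs.clusters) == oracle_clusters and not oracle_singles

    def test_column_stochastic_every_iteration(self):
        edges, _ = generate_similarity_graph([6, 6, 6], seed=9)
        cs = mcl(build_graph(edges), inflation=1.5)
        assert cs.max_colsum_deviation <= 1e-9

    def test_permutation_equivariance(self):
        edges, _ = generate_similarity_graph([5, 4, 3], seed=3, between_density=0.5)
        mapping = {}
        for e in edges:
            for node in (e.a, e.b):
                mapping.setdefault(node, f"z{len(mapping):03d}")
        relabeled = [
            SimilarityEdge(mapping[e.a], mapping[e.b], e.e_value) for e in edges
        ]
        base = mcl(build_graph(edges), inflation=2.0)
        perm = mcl(build_graph(relabeled), inflation=2.0)
        expected = frozenset(
            tuple(sorted(mapping[n] for n in c)) for c in base.clusters
        )
        assert frozenset(perm.clusters) == expected
        assert perm.singletons == frozenset(mapping[n] for n in base.singletons)

    def test_clusters_stay_within_connected_components(self):
        rng = np.random.default_rng(12)
        import networkx as nx

        for trial in range(5):
            n = int(rng.integers(10, 40))
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.1:
                        edges.append(
                            SimilarityEdge(f"n{i:02d}", f"n{j:02d}",
                                           10.0 ** -float(rng.uniform(16, 60)))
                        )
            g = build_graph(edges, nodes=[f"n{i:02d}" for i in range(n)])
            comp_of = {}
            for ci, comp in enumerate(nx.connected_components(g)):
                for node in comp:
                    comp_of[node] = ci
            cs = mcl(g, inflation=2.0)
            for cluster in cs.clusters:
                assert len({comp_of[node] for node in cluster}) == 1

    def test_higher_inflation_gives_finer_clusters(self):
        edges, _ = generate_similarity_graph(
            [8, 8], seed=21, within_e=(-40.0, -16.0), between_e=(-15.9, -15.5),
            separable=False, between_density=0.4,
        )
        g = build_graph(edges, e_cutoff=1e-15)
        sizes = []
        for inflation in (1.2, 1.5, 2.0, 4.0, 6.0):
            cs = mcl(g, inflation=inflation)
            sizes.append(max((len(c) for c in cs.clusters), default=1))
        assert sizes == sorted(sizes, reverse=True)

    @settings(deadline=None, max_examples=100)
    @given(data=st.data())
    def test_sparse_agrees_with_dense_oracle_on_random_graphs(self, data):
        """Sparse MCL and the independently coded dense-matrix oracle produce
        identical partitions on random graphs of up to 50 nodes."""
        n = data.draw(st.integers(2, 50))
        density = data.draw(st.floats(0.05, 0.5))
        inflation = data.draw(st.sampled_from([1.5, 2.0, 4.0]))
        seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(seed)
        nodes = [f"n{i:02d}" for i in range(n)]
        edges, weighted = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < density:
                    w = float(rng.uniform(5, 60))
                    edges.append(SimilarityEdge(nodes[i], nodes[j], 10.0 ** -w))
                    weighted.append((nodes[i], nodes[j], w))
        cs = mcl(build_graph(edges, e_cutoff=1.0, nodes=nodes), inflation=inflation)
        oracle_clusters, oracle_singles = dense_mcl_partition(
            nodes, weighted, inflation=inflation
        )
        assert frozenset(cs.clusters) == oracle_clusters
        assert cs.singletons == oracle_singles


class TestClusterSetAndStats:
    def test_stats_arithmetic(self):
        cs = ClusterSet(
            clusters=(("a", "b", "c", "d"), ("e", "f", "g", "h")),
            singletons=frozenset({"z"}),
        )
        assert cluster_stats(cs) == {
            "n_clusters": 2, "n_singletons": 1, "n_sequences": 9
        }

    def test_empty_input(self):
        cs = ClusterSet(clusters=(), singletons=frozenset())
        assert cluster_stats(cs) == {
            "n_clusters": 0, "n_singletons": 0, "n_sequences": 0
        }

    def test_partition_violations_rejected(self):
        with pytest.raises(ValidationError):
            ClusterSet(clusters=(("a", "b"), ("b", "c")), singletons=frozenset())
        with pytest.raises(ValidationError):
            ClusterSet(clusters=(("a", "b"),), singletons=frozenset({"a"}))
        with pytest.raises(ValidationError):
            ClusterSet(clusters=(("a",),), singletons=frozenset())


def test_edge_list_round_trip_and_cluster_output():
    edges = [SimilarityEdge("a", "b", 1e-20), SimilarityEdge("b", "c", 0.0)]
    buf = io.StringIO()
    write_edges(edges, buf)
    assert read_edges(io.StringIO(buf.getvalue())) == edges

    cs = ClusterSet(clusters=(("a", "b", "c"),), singletons=frozenset({"z"}))
    out = io.StringIO()
    write_clusters(cs, out)
    assert out.getvalue() == "a\tb\tc\nz\n"
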