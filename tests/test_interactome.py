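import math
from collections import Counter

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugprox.interactome import (
    DegreeBins,
    FormatError,
    Interactome,
    NodeModule,
    SamplingExhaustedError,
    build_degree_bins,
    load_interactome,
    sample_degree_matched,
    shortest_path_lengths,
    write_interactome,
)

from .conftest import make_interactome


def _write_edges(tmp_path, lines, name="net.tsv"):
    p = tmp_path / name
    p.write_text("".join(line + "\n" for line in lines))
    return p


class TestLoadInteractome:
    def test_drops_self_loops_and_duplicates(self, tmp_path):
        p = _write_edges(tmp_path, ["A\tB", "B\tC", "B\tB", "A\tB"])
        g = load_interactome(p)
        assert g.nodes == {"A", "B", "C"}
        assert set(map(frozenset, g.graph.edges)) == {
            frozenset({"A", "B"}), frozenset({"B", "C"})}
        assert g.degree == {"A": 1, "B": 2, "C": 1}

    def test_component_tie_broken_lexicographically(self, tmp_path):
        # two disjoint triangles of equal size: keep the one with the
        # lexicographically smallest node set
        p = _write_edges(
            tmp_path, ["D\tE", "E\tF", "F\tD", "A\tB", "B\tC", "C\tA"])
        g = load_interactome(p, keep_largest_component=True)
        assert g.nodes == {"A", "B", "C"}

    def test_keep_all_components_option(self, tmp_path):
        p = _write_edges(tmp_path, ["A\tB", "X\tY"])
        g = load_interactome(p, keep_largest_component=False)
        assert g.nodes == {"A", "B", "X", "Y"}

    def test_comments_and_extra_columns_ignored(self, tmp_path):
        p = _write_edges(tmp_path, ["# header", "A\tB\t0.9\tpubmed", "", "B\tC"])
        g = load_interactome(p)
        assert g.nodes == {"A", "B", "C"}

    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(11)
        g_nx = nx.gnp_random_graph(50, 0.12, seed=42)
        g_nx = nx.relabel_nodes(g_nx, {i: f"g{i}" for i in g_nx.nodes})
        p = tmp_path / "rand.tsv"
        with open(p, "w") as fh:
            edges = list(g_nx.edges)
            rng.shuffle(edges)
            for u, v in edges:
                fh.write(f"{u}\t{v}\n")
        g1 = load_interactome(p, keep_largest_component=False)
        assert g1.nodes == set(g_nx.nodes)
        assert set(map(frozenset, g1.graph.edges)) == set(map(frozenset, g_nx.edges))
        # loading the serialized output reproduces the same graph (idempotence)
        p2 = tmp_path / "rewrite.tsv"
        write_interactome(g1, p2)
        g2 = load_interactome(p2, keep_largest_component=False)
        assert g2.nodes == g1.nodes
        assert set(map(frozenset, g2.graph.edges)) == set(map(frozenset, g1.graph.edges))

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(OSError):
            load_interactome(tmp_path / "absent.tsv")

    def test_zero_valid_edges_raises(self, tmp_path):
        p = _write_edges(tmp_path, ["# only comments", "A\tA"])
        with pytest.raises(FormatError):
            load_interactome(p)

    def test_short_line_raises(self, tmp_path):
        p = _write_edges(tmp_path, ["A\tB", "lonely"])
        with pytest.raises(FormatError):
            load_interactome(p)


class TestShortestPathLengths:
    def test_path_graph_distances(self, path_graph):
        d = shortest_path_lengths(path_graph, {"A"})
        assert d[("A", "A")] == 0
        assert d[("A", "B")] == 1
        assert d[("A", "C")] == 2
        assert d[("A", "D")] == 3

    def test_unreachable_pair_absent(self):
        g = make_interactome([("A", "B"), ("E", "F")])
        d = shortest_path_lengths(g, {"A"})
        assert ("A", "E") not in d and ("A", "F") not in d

    def test_unknown_source_named_in_error(self, path_graph):
        with pytest.raises(KeyError, match="ZZZ"):
            shortest_path_lengths(path_graph, {"ZZZ"})

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_floyd_warshall_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 41))
        g_nx = nx.gnp_random_graph(n, 0.15, seed=seed)
        g_nx = nx.relabel_nodes(g_nx, {i: f"v{i:02d}" for i in g_nx.nodes})
        if g_nx.number_of_edges() == 0:
            g_nx.add_edge("v00", "v01")
        g = Interactome(g_nx)
        # independent oracle: textbook Floyd-Warshall over the full matrix
        nodes = sorted(g_nx.nodes)
        idx = {v: i for i, v in enumerate(nodes)}
        dist = np.full((n, n), np.inf)
        np.fill_diagonal(dist, 0)
        for u, v in g_nx.edges:
            dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1
        for k in range(n):
            dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
        sources = set(rng.choice(nodes, size=min(4, n), replace=False))
        got = shortest_path_lengths(g, sources)
        for s in sources:
            for v in nodes:
                expected = dist[idx[s], idx[v]]
                if math.isinf(expected):
                    assert (s, v) not in got
                else:
                    assert got[(s, v)] == expected

    def test_min_hop_distances_matches_per_source(self, path_graph):
        dist = path_graph.min_hop_distances({"A", "E"})
        order = path_graph.node_order
        per_source = shortest_path_lengths(path_graph, {"A", "E"})
        for i, v in enumerate(order):
            assert dist[i] == min(per_source[("A", v)], per_source[("E", v)])


def _graph_with_degree_classes():
    """Petersen (10 nodes of degree 3) + C3 (3 of degree 2) + 2 disjoint
    edges (4 of degree 1)."""
    g = nx.relabel_nodes(nx.petersen_graph(), {i: f"p{i}" for i in range(10)})
    g.add_edges_from([("c0", "c1"), ("c1", "c2"), ("c2", "c0")])
    g.add_edges_from([("e0", "e1"), ("e2", "e3")])
    return Interactome(g)


class TestDegreeBins:
    def test_no_merging_when_classes_large_enough(self):
        # 5 disjoint edges (10 nodes of degree 1) + a 10-cycle (degree 2)
        g_nx = nx.Graph()
        g_nx.add_edges_from([(f"a{i}", f"b{i}") for i in range(5)])
        g_nx.add_edges_from(nx.cycle_graph([f"c{i}" for i in range(10)]).edges)
        bins = build_degree_bins(Interactome(g_nx), min_bin_size=10)
        assert [len(b) for b in bins.bins] == [10, 10]
        assert bins.degree_ranges == ((1, 1), (2, 2))

    def test_greedy_merge_of_small_classes(self):
        # degree classes {1: 4, 2: 3, 3: 10}: the two small low-degree
        # classes merge to reach the minimum, the degree-3 class stands alone
        bins = build_degree_bins(_graph_with_degree_classes(), min_bin_size=5)
        assert [len(b) for b in bins.bins] == [7, 10]
        assert bins.degree_ranges == ((1, 2), (3, 3))

    def test_trailing_undersized_bin_merges_backward(self):
        # 5 disjoint edges (10 deg-1 nodes) + C4 (4 deg-2 nodes), min 5:
        # deg-1 closes at 10, the deg-2 tail (4 < 5) folds back into it
        g_nx = nx.Graph()
        g_nx.add_edges_from([(f"a{i}", f"b{i}") for i in range(5)])
        g_nx.add_edges_from(nx.cycle_graph([f"c{i}" for i in range(4)]).edges)
        bins = build_degree_bins(Interactome(g_nx), min_bin_size=5)
        assert [len(b) for b in bins.bins] == [14]
        assert bins.degree_ranges == ((1, 2),)

    def test_graph_smaller_than_min_bin_size(self, path_graph):
        bins = build_degree_bins(path_graph, min_bin_size=100)
        assert [len(b) for b in bins.bins] == [5]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), min_bin=st.integers(1, 15))
    def test_bins_partition_the_node_set(self, seed, min_bin):
        g_nx = nx.gnp_random_graph(30, 0.1, seed=seed)
        g_nx = nx.relabel_nodes(g_nx, {i: f"v{i}" for i in g_nx.nodes})
        g = Interactome(g_nx)
        bins = build_degree_bins(g, min_bin_size=min_bin)
        all_nodes = [n for b in bins.bins for n in b]
        assert len(all_nodes) == len(set(all_nodes))  # pairwise disjoint
        assert set(all_nodes) == g.nodes
        assert all(bins.bin_of[n] == i for i, b in enumerate(bins.bins) for n in b)
        # all but possibly a lone bin respect the minimum size
        if len(bins.bins) > 1:
            assert all(len(b) >= min_bin for b in bins.bins)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            build_degree_bins(Interactome(nx.Graph()), 1)


class TestSampleDegreeMatched:
    def test_full_node_template_is_forced(self, k10):
        bins = build_degree_bins(k10, min_bin_size=10)
        out = sample_degree_matched(k10, bins, k10.nodes, rng=0)
        assert out == k10.nodes

    def test_same_seed_same_sample(self):
        g = _graph_with_degree_classes()
        bins = build_degree_bins(g, min_bin_size=3)
        template = {"p0", "p5", "c0", "e0"}
        a = sample_degree_matched(g, bins, template, rng=123)
        b = sample_degree_matched(g, bins, template, rng=123)
        assert a == b
        assert len(a) == len(template)

    def test_single_node_template_samples_uniformly_within_bin(self):
        g = _graph_with_degree_classes()
        bins = build_degree_bins(g, min_bin_size=3)
        b = bins.bin_of["c0"]
        pool = bins.bins[b]
        rng = np.random.default_rng(7)
        counts = Counter()
        n_draws = 10_000
        for _ in range(n_draws):
            (node,) = sample_degree_matched(g, bins, {"c0"}, rng)
            counts[node] += 1
        assert set(counts) <= set(pool)
        p = 1 / len(pool)
        se = math.sqrt(p * (1 - p) / n_draws)
        for node in pool:
            assert abs(counts[node] / n_draws - p) < 3 * se + 1e-12

    def test_mean_degree_converges_to_template(self):
        # heavy-tailed graph; the template is large enough that no single
        # hub dominates its mean, and bins are fine enough to resolve the
        # degree profile
        g_nx = nx.barabasi_albert_graph(2000, 3, seed=9)
        g = Interactome(nx.relabel_nodes(g_nx, {i: f"g{i}" for i in g_nx.nodes}))
        bins = build_degree_bins(g, min_bin_size=10)
        rng = np.random.default_rng(5)
        deg = g.degree
        template = set(rng.choice(sorted(g.nodes), size=200, replace=False))
        template_mean = np.mean([deg[n] for n in template])
        draws = [
            np.mean([deg[n] for n in sample_degree_matched(g, bins, template, rng)])
            for _ in range(2000)
        ]
        assert abs(np.mean(draws) - template_mean) / template_mean < 0.10

    def test_exhausted_bin_raises(self, path_graph):
        # hand-built inconsistent bins: two template nodes mapped to a
        # one-node pool (the caller-should-raise-min_bin_size path)
        bad = DegreeBins(
            bins=(("A",),), bin_of={"A": 0, "B": 0},
            min_bin_size=1, degree_ranges=((1, 1),),
        )
        with pytest.raises(SamplingExhaustedError, match="min_bin_size"):
            sample_degree_matched(path_graph, bad, {"A", "B"}, rng=0)

    def test_exclusion_respected(self, k10):
        bins = build_degree_bins(k10, min_bin_size=10)
        rng = np.random.default_rng(3)
        for _ in range(50):
            first = sample_degree_matched(k10, bins, {"n0", "n1", "n2"}, rng)
            second = sample_degree_matched(
                k10, bins, {"n3", "n4"}, rng, exclude=first)
            assert not first & second

    def test_empty_template_rejected(self, k10):
        bins = build_degree_bins(k10, min_bin_size=10)
        with pytest.raises(ValueError):
            sample_degree_matched(k10, bins, set(), rng=0)


class TestNodeModule:
    def test_members_dropped_disjointness_enforced(self):
        with pytest.raises(ValueError):
            NodeModule("m", frozenset({"A"}), frozenset({"A", "B"}))
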