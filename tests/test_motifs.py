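"""Motif identifiers, census, null model and significance."""

from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pytest

from micronet import motifs as mo


class TestEncoding:
    @pytest.mark.parametrize(
        "edges,mask",
        [
            ([(2, 1), (3, 1)], 36),  # convergence onto node 1
            ([(1, 3), (3, 2), (2, 1)], 98),  # cycle in this labeling
            ([(2, 1), (3, 1), (3, 2)], 38),  # feed-forward
        ],
    )
    def test_bitmask_values(self, edges, mask):
        assert mo.motif_id_encode(3, edges) == mask

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            mo.motif_id_encode(3, [(1, 1)])

    def test_decode_inverts_encode(self):
        rng = np.random.default_rng(0)
        for n in (3, 4):
            for _ in range(50):
                pairs = [(i, j) for i in range(1, n + 1) for j in range(1, n + 1) if i != j]
                chosen = [p for p in pairs if rng.random() < 0.4]
                mask = mo.motif_id_encode(n, chosen)
                assert sorted(mo.motif_id_decode(n, mask)) == sorted(chosen)

    def test_decode_rejects_diagonal_bits(self):
        diag_bit = 1 << (9 - 1)  # bit for edge 1->1
        with pytest.raises(ValueError, match="diagonal"):
            mo.motif_id_decode(3, diag_bit)


class TestCanonical:
    def test_any_relabeling_of_cycle_gives_98(self):
        for perm in permutations((1, 2, 3)):
            cyc = list(zip(perm, perm[1:] + perm[:1]))
            assert mo.motif_id_canonical(3, cyc) == 98

    def test_reciprocal_hub_is_78(self):
        assert mo.motif_id_canonical(3, [(1, 3), (3, 1), (2, 3), (3, 2)]) == 78

    def test_dyad_plus_in_edge_is_74(self):
        assert mo.motif_id_canonical(3, [(2, 3), (3, 2), (1, 3)]) == 74

    def test_named_three_node_classes(self):
        # convergence, divergence, chain, feed-forward, cycle
        assert mo.motif_id_canonical(3, [(2, 1), (3, 1)]) == 36
        assert mo.motif_id_canonical(3, [(3, 1), (3, 2)]) == 6
        assert mo.motif_id_canonical(3, [(2, 3), (3, 1)]) == 12
        assert mo.motif_id_canonical(3, [(2, 1), (3, 1), (3, 2)]) == 38

    def test_canonical_is_fixed_point_of_decode(self):
        for n in (3, 4):
            for cid in mo.all_canonical_classes(n):
                edges = mo.motif_id_decode(n, cid)
                assert mo.motif_id_canonical(n, edges) == cid

    def test_connected_class_counts(self):
        assert len(mo.all_canonical_classes(3)) == 13
        assert len(mo.all_canonical_classes(4)) == 199


def _brute_census(g, n):
    from collections import Counter

    nodes = list(g.nodes)
    counts = Counter()
    for subset in combinations(nodes, n):
        sub = g.subgraph(subset)
        if not nx.is_weakly_connected(sub):
            continue
        order = list(subset)
        edges = [
            (order.index(u) + 1, order.index(v) + 1) for u, v in sub.edges()
        ]
        counts[mo.motif_id_canonical(n, edges)] += 1
    return dict(counts)


class TestCensus:
    def test_cycle_graph_counts_itself(self):
        g = nx.DiGraph([(1, 2), (2, 3), (3, 1)])
        assert mo.census(g, 3) == {98: 1}

    def test_edgeless_graph_empty(self):
        g = nx.empty_graph(5, create_using=nx.DiGraph)
        assert mo.census(g, 3) == {}
        assert mo.census(g, 4) == {}

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n_nodes = int(rng.integers(6, 13))
            g = nx.gnp_random_graph(
                n_nodes, 0.15, seed=int(rng.integers(2**31)), directed=True
            )
            for n in (3, 4):
                assert mo.census(g, n) == _brute_census(g, n)

    def test_counts_sum_to_connected_subset_count(self):
        g = nx.gnp_random_graph(10, 0.2, seed=5, directed=True)
        und = g.to_undirected()
        expected = sum(
            1
            for subset in combinations(g.nodes, 3)
            if nx.is_connected(und.subgraph(subset))
            or nx.is_weakly_connected(g.subgraph(subset))
        )
        n_connected = sum(
            1
            for subset in combinations(g.nodes, 3)
            if nx.is_weakly_connected(g.subgraph(subset))
        )
        assert sum(mo.census(g, 3).values()) == n_connected == expected

    def test_instances_agree_with_counts(self):
        g = nx.gnp_random_graph(9, 0.25, seed=8, directed=True)
        counts = mo.census(g, 4)
        inst = mo.census_instances(g, 4)
        assert {k: len(v) for k, v in inst.items()} == counts


class TestRandomize:
    def _degrees_and_mutual(self, g):
        ins = sorted(d for _, d in g.in_degree())
        outs = sorted(d for _, d in g.out_degree())
        mut = sum(1 for u, v in g.edges if g.has_edge(v, u)) // 2
        return ins, outs, mut

    def test_preserves_degrees_and_mutual_count(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(2**31)),
                                    directed=True)
            r = mo.randomize_network(g, seed=int(rng.integers(2**31)))
            assert r.number_of_edges() == g.number_of_edges()
            # per-node degree preservation, not just the sorted sequence
            assert dict(g.in_degree()) == dict(r.in_degree())
            assert dict(g.out_degree()) == dict(r.out_degree())
            assert self._degrees_and_mutual(g)[2] == self._degrees_and_mutual(r)[2]

    def test_actually_rewires_something(self):
        g = nx.gnp_random_graph(15, 0.3, seed=1, directed=True)
        r = mo.randomize_network(g, seed=2)
        assert set(r.edges) != set(g.edges)

    def test_single_edge_graph_unchanged(self):
        g = nx.DiGraph([(1, 2)])
        r = mo.randomize_network(g, seed=0)
        assert set(r.edges) == {(1, 2)}


class TestSignificance:
    def test_count_equal_to_null_mean_gives_zero_z(self):
        # a graph whose census the null reproduces exactly: z must be 0
        g = nx.DiGraph([(1, 2), (3, 4)])  # no 3-node motif at all
        recs = mo.motif_significance(g, 3, n_random=5, seed=0)
        assert all(r.z == 0 and not r.significant for r in recs)

    def test_z_matches_direct_formula(self):
        g = nx.gnp_random_graph(12, 0.25, seed=9, directed=True)
        n_random, seed = 20, 4
        recs = mo.motif_significance(g, 3, n_random=n_random, seed=seed)
        # recompute the ensemble exactly as the implementation seeds it
        real = mo.census(g, 3)
        seeds = np.random.SeedSequence(seed).spawn(n_random)
        samples = [mo.census(mo.randomize_network(g, seed=s), 3) for s in seeds]
        for r in recs:
            counts = np.array([s.get(r.canonical_id, 0) for s in samples], float)
            if counts.std(ddof=1) > 0:
                z = (real.get(r.canonical_id, 0) - counts.mean()) / counts.std(ddof=1)
                assert r.z == pytest.approx(z)

    def test_min_count_rule(self):
        g = nx.gnp_random_graph(12, 0.25, seed=11, directed=True)
        recs = mo.motif_significance(g, 3, n_random=10, seed=2, min_count=4)
        for r in recs:
            if r.significant:
                assert r.count_real >= 4 and r.z >= 2.0


class TestRepresentative:
    def _rec(self, cid, sig):
        return mo.MotifRecord(4, cid, 10, 5.0, 1.0, 5.0 if sig else 0.0, sig)

    @pytest.mark.parametrize("n_sig,expected", [(4, True), (3, True), (2, False)])
    def test_three_of_four_rule(self, n_sig, expected):
        records = {
            level: [self._rec(404, i < n_sig)]
            for i, level in enumerate((500, 1000, 1500, 2000))
        }
        rep = mo.representative_motifs(records)
        assert (404 in rep) is expected


class TestContainment:
    def test_404_contains_74(self):
        assert 74 in mo.submotif_census(404)

    def test_directed_four_cycle_contains_only_chains(self):
        cid = mo.motif_id_canonical(4, [(1, 2), (2, 3), (3, 4), (4, 1)])
        assert mo.submotif_census(cid) == {12: 4}

    def test_reciprocal_edge_propagates_to_submotifs(self):
        # any connected 4-node type with a mutual dyad embeds a 3-node type
        # with a mutual dyad, when some connected triple includes that dyad
        mutual3 = {
            cid for cid in mo.all_canonical_classes(3)
            if any(
                (j, i) in mo.motif_id_decode(3, cid)
                for i, j in mo.motif_id_decode(3, cid)
            )
        }
        for cid in mo.all_canonical_classes(4):
            edges = mo.motif_id_decode(4, cid)
            dyads = [(i, j) for i, j in edges if (j, i) in edges and i < j]
            if not dyads:
                continue
            subs = mo.submotif_census(cid)
            g = nx.DiGraph()
            g.add_nodes_from(range(1, 5))
            g.add_edges_from(edges)
            dyad_in_connected_triple = any(
                nx.is_weakly_connected(g.subgraph(t))
                for t in combinations(range(1, 5), 3)
                if any(a in t and b in t for a, b in dyads)
            )
            if dyad_in_connected_triple:
                assert set(subs) & mutual3


class TestCorrelatedFeedback:
    def _graph_with_cycles(self):
        g = nx.DiGraph()
        # two labeled 4-node instances, each containing a 3-cycle
        g.add_edges_from([("a", "b"), ("b", "c"), ("c", "a"), ("a", "d")])
        g.add_edges_from([("e", "f"), ("f", "g"), ("g", "e"), ("e", "h")])
        return g

    def test_empty_correlated_set_gives_zero(self):
        g = self._graph_with_cycles()
        cid = mo.motif_id_canonical(4, [(1, 2), (2, 3), (3, 1), (1, 4)])
        assert mo.correlated_feedback_fraction(g, cid, set()) == 0.0

    def test_all_correlated_gives_hundred(self):
        g = self._graph_with_cycles()
        cid = mo.motif_id_canonical(4, [(1, 2), (2, 3), (3, 1), (1, 4)])
        assert mo.correlated_feedback_fraction(g, cid, set(g.nodes)) == 100.0

    def test_absent_motif_returns_none(self):
        g = nx.DiGraph([(1, 2)])
        assert mo.correlated_feedback_fraction(g, 404, {1, 2}) is None

    def test_matches_brute_force_instance_scan(self):
        rng = np.random.default_rng(55)
        g = nx.gnp_random_graph(11, 0.3, seed=7, directed=True)
        correlated = {v for v in g.nodes if rng.random() < 0.5}
        inst = mo.census_instances(g, 4)
        for cid, quads in inst.items():
            expected_hits = 0
            for quad in quads:
                hit = False
                for triple in combinations(quad, 3):
                    sub = g.subgraph(triple)
                    if not nx.is_weakly_connected(sub):
                        continue
                    order = list(triple)
                    edges = [
                        (order.index(u) + 1, order.index(v) + 1)
                        for u, v in sub.edges()
                    ]
                    if mo.motif_id_canonical(3, edges) == 98 and all(
                        t in correlated for t in triple
                    ):
                        hit = True
                expected_hits += hit
            expected = 100.0 * expected_hits / len(quads)
            got = mo.correlated_feedback_fraction(g, cid, correlated)
            assert got == pytest.approx(expected)
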