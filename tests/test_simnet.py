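import math
import random

import numpy as np
import pytest

from cress_evolve import simnet, synth
from cress_evolve.seqio import PROTEIN, NUCLEOTIDE, SequenceRecord, SequenceError
from cress_evolve.simnet import (
    PairwiseHit,
    ScoringParams,
    all_vs_all,
    attraction_from_pvalue,
    build_network,
    evalue_to_pvalue,
    extract_clusters,
    layout_network,
    score_pair,
)


def prot(rid, seq):
    return SequenceRecord(rid, rid, seq, PROTEIN)


def make_hit(u, v, pvalue):
    evalue = -math.log1p(-pvalue)
    return PairwiseHit(u, v, 100.0, evalue, pvalue, attraction_from_pvalue(pvalue))


PARAMS = ScoringParams.default()


class TestScorePair:
    def test_poly_ala_self_alignment(self):
        # BLOSUM45 A<->A scores 5, so 100 A's against itself scores 500
        a = prot("a", "A" * 100)
        hit = score_pair(a, a, PARAMS)
        assert hit.raw_score == 500

    def test_all_negative_substitutions_no_hit(self):
        # W vs P is negative under BLOSUM45; the empty local alignment wins
        assert score_pair(prot("a", "W" * 40), prot("b", "P" * 40), PARAMS) is None

    def test_evalue_closed_form(self):
        a = prot("a", "A" * 100)
        hit = score_pair(a, a, PARAMS)
        expected = PARAMS.karlin_k * 100 * 100 * math.exp(-PARAMS.karlin_lambda * 500)
        assert hit.evalue == pytest.approx(expected, rel=1e-12)
        assert hit.pvalue == pytest.approx(1 - math.exp(-expected), rel=1e-9)

    def test_nucleotide_input_rejected(self):
        a = prot("a", "MKV" * 20)
        b = SequenceRecord("b", "b", "ATG" * 20, NUCLEOTIDE)
        with pytest.raises(SequenceError):
            score_pair(a, b, PARAMS)

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            ScoringParams(gap_open=-1)
        with pytest.raises(ValueError):
            ScoringParams(karlin_lambda=0)


class TestEvalueToPvalue:
    @pytest.mark.parametrize(
        "evalue,expected,tol",
        [(0.0, 0.0, 0.0), (0.01, 0.00995, 1e-5), (10.0, 0.9999546, 1e-6)],
    )
    def test_values(self, evalue, expected, tol):
        assert evalue_to_pvalue(evalue) == pytest.approx(expected, abs=tol)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            evalue_to_pvalue(-0.1)

    def test_monotone(self):
        es = np.linspace(0, 20, 50)
        ps = [evalue_to_pvalue(e) for e in es]
        assert all(p1 < p2 for p1, p2 in zip(ps, ps[1:]))
        assert all(0 <= p < 1 for p in ps)


class TestBuildNetwork:
    def test_threshold_rule(self):
        hits = [make_hit("a", "b", 1e-5), make_hit("b", "c", 0.5)]
        net = build_network(hits, ["a", "b", "c"], 1e-2)
        assert set(map(frozenset, net.graph.edges)) == {frozenset({"a", "b"})}
        assert "c" in net.graph  # isolated node retained

    def test_reciprocal_merge_keeps_min_pvalue(self):
        hits = [make_hit("a", "b", 0.3), make_hit("b", "a", 0.001)]
        net = build_network(hits, ["a", "b"], 1e-2)
        assert net.graph.edges["a", "b"]["hit"].pvalue == 0.001

    def test_empty_hit_list(self):
        net = build_network([], ["a", "b", "c"], 1e-2)
        assert net.graph.number_of_edges() == 0
        assert set(net.graph.nodes) == {"a", "b", "c"}

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError, match="not in node list"):
            build_network([make_hit("a", "z", 1e-5)], ["a", "b"], 1e-2)

    def test_edge_set_invariant_under_hit_order(self):
        rng = random.Random(5)
        hits = [make_hit("a", "b", 0.004), make_hit("b", "a", 0.0001),
                make_hit("b", "c", 0.009), make_hit("a", "c", 0.5)]
        reference = None
        for _ in range(5):
            rng.shuffle(hits)
            net = build_network(hits, ["a", "b", "c"], 1e-2)
            edges = {
                frozenset(e): net.graph.edges[e]["hit"].pvalue
                for e in net.graph.edges
            }
            if reference is None:
                reference = edges
            assert edges == reference

    def test_raising_threshold_never_shrinks_components(self):
        import networkx as nx

        rng = random.Random(7)
        ids = [f"n{i}" for i in range(12)]
        hits = [
            make_hit(u, v, 10 ** rng.uniform(-6, 0))
            for i, u in enumerate(ids)
            for v in ids[i + 1 :]
            if rng.random() < 0.4
        ]
        sizes = []
        for thr in (1e-4, 1e-3, 1e-2, 1e-1):
            net = build_network(hits, ids, thr)
            comp_of = {}
            for comp in nx.connected_components(net.graph):
                for n in comp:
                    comp_of[n] = len(comp)
            sizes.append(comp_of)
        for lo, hi in zip(sizes, sizes[1:]):
            assert all(hi[n] >= lo[n] for n in ids)


class TestLayout:
    def test_deterministic_for_fixed_seed(self):
        hits = [make_hit("a", "b", 1e-8)]
        net = build_network(hits, ["a", "b"], 1e-2)
        l1 = layout_network(net, dims=2, rounds=1000, seed=7)
        l2 = layout_network(net, dims=2, rounds=1000, seed=7)
        assert np.array_equal(l1.coords, l2.coords)

    def test_bad_dims_rejected(self):
        net = build_network([], ["a", "b"], 1e-2)
        with pytest.raises(ValueError):
            layout_network(net, dims=4, rounds=10, seed=0)

    def test_pure_repulsion_separates(self):
        net = build_network([], ["a", "b"], 1e-2)
        dists = []
        for rounds in (1, 10, 50, 200):
            layout = layout_network(net, dims=2, rounds=rounds, seed=3)
            dists.append(np.linalg.norm(layout.coords[0] - layout.coords[1]))
        assert all(d2 >= d1 - 1e-12 for d1, d2 in zip(dists, dists[1:]))

    def test_planted_families_separate_in_layout(self):
        records, truth = synth.gen_protein_families(3, 5, 100, 0.1, seed=21)
        hits = all_vs_all(records, PARAMS)
        net = build_network(hits, [r.id for r in records], 1e-2)
        layout = layout_network(net, dims=2, rounds=2000, seed=5)
        pos = layout.as_dict()
        within, between = [], []
        ids = [r.id for r in records]
        for i, u in enumerate(ids):
            for v in ids[i + 1 :]:
                d = np.linalg.norm(pos[u] - pos[v])
                (within if truth.labels[u] == truth.labels[v] else between).append(d)
        assert np.mean(within) < np.mean(between)


def clique_hits(ids, pvalue=1e-30):
    return [
        make_hit(u, v, pvalue) for i, u in enumerate(ids) for v in ids[i + 1 :]
    ]


class TestExtractClusters:
    def test_min_size_rule_routes_small_clique_to_unclustered(self):
        big = [f"b{i:02d}" for i in range(10)]
        small = [f"s{i:02d}" for i in range(9)]
        net = build_network(clique_hits(big) + clique_hits(small), big + small, 1e-2)
        result = extract_clusters(net, min_size=10)
        assert list(result.clusters.values()) == [sorted(big)]
        assert result.unclustered == sorted(small)

    def test_fully_connected_single_cluster(self):
        ids = [f"n{i}" for i in range(12)]
        net = build_network(clique_hits(ids), ids, 1e-2)
        result = extract_clusters(net, min_size=2)
        assert list(result.clusters.values()) == [sorted(ids)]

    def test_unknown_method_rejected(self):
        net = build_network([], ["a"], 1e-2)
        with pytest.raises(ValueError, match="unknown clustering method"):
            extract_clusters(net, method="banana")

    def test_planted_families_recovered_exactly(self, small_families):
        from sklearn.metrics import adjusted_rand_score

        records, truth = small_families
        hits = all_vs_all(records, PARAMS)
        net = build_network(hits, [r.id for r in records], 1e-2)
        result = extract_clusters(net, min_size=2)
        labels = result.labels()
        ids = sorted(labels)
        ari = adjusted_rand_score(
            [truth.labels[i] for i in ids], [labels[i] for i in ids]
        )
        assert ari == 1.0
        assert not result.unclustered

    def test_partition_exactness(self, small_families):
        records, truth = small_families
        hits = all_vs_all(records, PARAMS)
        net = build_network(hits, [r.id for r in records], 1e-2)
        result = extract_clusters(net, min_size=7)  # force some unclustered
        members = [m for ms in result.clusters.values() for m in ms]
        assert len(members) + len(result.unclustered) == len(records)
        assert set(members) | set(result.unclustered) == {r.id for r in records}
        assert len(set(members)) == len(members)

    def test_components_match_brute_force_union_find(self, small_families):
        records, truth = small_families
        ids = [r.id for r in records]
        hits = all_vs_all(records, PARAMS)
        net = build_network(hits, ids, 1e-2)
        result = extract_clusters(net, min_size=1)

        # oracle: exhaustive pair enumeration + union-find on thresholded pairs
        parent = {i: i for i in ids}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for h in hits:
            if h.pvalue <= 1e-2:
                parent[find(h.query_id)] = find(h.subject_id)
        oracle = {}
        for i in ids:
            oracle.setdefault(find(i), set()).add(i)
        got = {frozenset(ms) for ms in result.clusters.values()}
        assert got == {frozenset(s) for s in oracle.values()}

    def test_network_offset_agrees_on_clean_cliques(self):
        a = [f"a{i}" for i in range(10)]
        b = [f"b{i}" for i in range(10)]
        net = build_network(clique_hits(a) + clique_hits(b), a + b, 1e-2)
        by_comp = extract_clusters(net, method="components", min_size=2)
        by_offset = extract_clusters(net, method="network_offset", min_size=2)
        assert {frozenset(m) for m in by_comp.clusters.values()} == {
            frozenset(m) for m in by_offset.clusters.values()
        }
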