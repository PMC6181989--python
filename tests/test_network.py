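"""Interaction graph: anchor merging, hubs, degree bookkeeping."""

import numpy as np
import pytest

from loopforest.core import GenomicInterval, LoopRecord
from loopforest.network import (
    build_graph,
    degree_distribution,
    hub_conservation,
    identify_hubs,
)


def _loop(s1, s2, chrom="chr1", width=500):
    return LoopRecord(
        GenomicInterval(chrom, max(0, s1 - width), s1 + width),
        GenomicInterval(chrom, s2 - width, s2 + width),
        summit1=s1,
        summit2=s2,
    )


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        self.parent[self.find(i)] = self.find(j)


def _oracle(loops):
    """Brute-force union-find over anchor overlaps -> (n_nodes, degree multiset)."""
    anchors = [a for lp in loops for a in (lp.anchor1, lp.anchor2)]
    uf = _UnionFind(len(anchors))
    for i in range(len(anchors)):
        for j in range(i + 1, len(anchors)):
            if anchors[i].overlaps(anchors[j]):
                uf.union(i, j)
    comp = {}
    for i in range(len(anchors)):
        comp.setdefault(uf.find(i), len(comp))
    edges = set()
    for k, lp in enumerate(loops):
        u = comp[uf.find(2 * k)]
        v = comp[uf.find(2 * k + 1)]
        if u != v:
            edges.add((min(u, v), max(u, v)))
    degree = {c: 0 for c in comp.values()}
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1
    return len(comp), sorted(degree.values())


class TestBuildGraph:
    def test_shared_anchor(self):
        loops = [_loop(100_000, 300_000), _loop(300_000, 500_000)]
        g = build_graph(loops)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
        degs = sorted(d for _, d in g.degree)
        assert degs == [1, 1, 2]

    def test_chain(self):
        k = 6
        loops = [_loop(100_000 + i * 200_000, 100_000 + (i + 1) * 200_000) for i in range(k)]
        g = build_graph(loops)
        assert g.number_of_nodes() == k + 1
        assert g.number_of_edges() == k

    def test_parallel_edges_collapse_with_multiplicity(self):
        loops = [_loop(100_000, 300_000), _loop(100_100, 300_100)]
        g = build_graph(loops)
        assert g.number_of_edges() == 1
        (u, v, d), = g.edges(data=True)
        assert d["multiplicity"] == 2

    def test_matches_union_find_oracle_on_random_sets(self):
        rng = np.random.default_rng(77)
        for trial in range(100):
            n = int(rng.integers(3, 25))
            loops = []
            for _ in range(n):
                s1 = int(rng.integers(5_000, 900_000))
                s2 = s1 + int(rng.integers(11_000, 500_000))
                loops.append(_loop(s1, s2, width=int(rng.integers(300, 2_000))))
            g = build_graph(loops)
            n_nodes, degs = _oracle(loops)
            assert g.number_of_nodes() == n_nodes, f"trial {trial}"
            assert sorted(d for _, d in g.degree) == degs, f"trial {trial}"


class TestHubs:
    @staticmethod
    def _star_graph():
        # hub anchor at 1 Mb connected to 20 leaves; intensities distinct
        loops = [_loop(1_000_000, 1_000_000 + 15_000 * (k + 1)) for k in range(20)]
        intensities = {}

        def intensity_of(iv):
            return float(iv.start % 997) / 100.0

        return build_graph(loops, intensity_of=intensity_of)

    def test_top_decile_by_degree(self):
        g = self._star_graph()
        hubs, non_hubs = identify_hubs(g)
        assert len(hubs) == len(non_hubs) == 2
        # the star centre has degree 20 and must rank first
        top = hubs[0]
        assert g.degree(top) == 20
        assert not set(hubs) & set(non_hubs)

    def test_intensity_tie_break_matches_hand_ranking(self):
        loops = [
            _loop(100_000, 300_000),
            _loop(500_000, 700_000),
            *[_loop(1_000_000 + i * 300_000, 1_150_000 + i * 300_000) for i in range(8)],
        ]
        intensity = {100_000 - 500: 9.0, 300_000 - 500: 1.0, 500_000 - 500: 5.0}

        def intensity_of(iv):
            return intensity.get(iv.start, 0.5)

        g = build_graph(loops, intensity_of=intensity_of)
        hubs, non_hubs = identify_hubs(g, top_frac=0.10)
        # all degrees are 1: the decile cut is decided purely by intensity
        assert g.nodes[hubs[0]]["intensity"] == 9.0
        assert g.nodes[non_hubs[-1]]["intensity"] == 0.5

    def test_too_few_nodes_error(self):
        g = build_graph([_loop(100_000, 300_000)])
        with pytest.raises(ValueError, match=">= 10"):
            identify_hubs(g)


class TestDegreeDistribution:
    def test_isolated_and_star(self):
        assert degree_distribution(build_graph([_loop(100_000, 300_000)])) == {1: 2}
        star = build_graph([_loop(1_000_000, 1_000_000 + 20_000 * (k + 1)) for k in range(5)])
        assert degree_distribution(star) == {1: 5, 5: 1}

    def test_total_equals_node_count(self, small_fixture):
        g = build_graph(small_fixture.truth)
        dist = degree_distribution(g)
        assert sum(dist.values()) == g.number_of_nodes()


class TestHubConservation:
    def test_identical_and_disjoint(self):
        a = [GenomicInterval("chr1", 1_000, 2_000), GenomicInterval("chr1", 5_000, 6_000)]
        b = [GenomicInterval("chr1", 1_500, 2_500), GenomicInterval("chr1", 5_100, 5_900)]
        c = [GenomicInterval("chr2", 1_000, 2_000)]
        df = hub_conservation({"A": a, "B": b})
        assert (df["fraction"] == 1.0).all()
        df2 = hub_conservation({"A": a, "C": c})
        assert (df2["fraction"] == 0.0).all()

    def test_planted_shared_hubs_more_conserved(self):
        rng = np.random.default_rng(5)
        shared = [GenomicInterval("chr1", int(p), int(p) + 1_000) for p in rng.integers(10_000, 5_000_000, 15) * 1]
        only_a = [GenomicInterval("chr2", int(p), int(p) + 1_000) for p in np.arange(15) * 50_000 + 10_000]
        only_b = [GenomicInterval("chr2", int(p), int(p) + 1_000) for p in np.arange(15) * 50_000 + 30_000]
        hubs = hub_conservation({"A": shared + only_a[:2], "B": shared + only_b[:2]})
        non_hubs = hub_conservation({"A": only_a, "B": only_b})
        assert hubs["fraction"].mean() > non_hubs["fraction"].mean()
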