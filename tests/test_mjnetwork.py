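"""Median-joining networks, star contraction and distance analyses."""

from itertools import product

import networkx as nx
import numpy as np
import pytest

from sexlinkscan.mjnetwork import (
    anova_distance_vs_factor,
    h_to_m_distances,
    median_joining,
    mutational_distance,
    star_contraction,
)


class TestStarContraction:
    def test_canonical_star_merges_into_center(self):
        center = "AAAAA"
        sats = ["TAAAA", "ATAAA", "AATAA", "AAATA"]
        haps = {center: 1, **{s: 1 for s in sats}}
        contracted, mapping = star_contraction(haps, delta=1)
        assert contracted == {center: 5}
        assert all(mapping[s] == center for s in sats)

    def test_distant_pair_unchanged(self):
        haps = {"AAA": 2, "TTT": 3}
        contracted, mapping = star_contraction(haps, delta=1)
        assert contracted == haps

    def test_equal_rank_pair_not_collapsed(self):
        haps = {"AAA": 1, "AAT": 1}
        contracted, _ = star_contraction(haps, delta=1)
        assert len(contracted) == 2

    def test_chain_contracts_deterministically(self):
        haps = {"AAA": 1, "AAT": 1, "ATT": 1}
        c1, m1 = star_contraction(haps, delta=1)
        c2, m2 = star_contraction(dict(reversed(list(haps.items()))), delta=1)
        assert c1 == c2 and m1 == m2
        assert sum(c1.values()) == 3
        assert "AAT" in c1  # the middle node is the center, never a satellite

    def test_multiplicity_preserved_and_nodes_nonincreasing(self, rng):
        for _ in range(20):
            haps = {"".join(rng.choice(list("AT"), 4)): int(rng.integers(1, 5))
                    for _ in range(rng.integers(2, 8))}
            contracted, mapping = star_contraction(haps, delta=1)
            assert sum(contracted.values()) == sum(haps.values())
            assert len(contracted) <= len(haps)
            assert set(mapping) == set(haps)


class TestMedianJoining:
    def test_path_data_yields_path_without_medians(self):
        net = median_joining(["000", "001", "011"])
        assert net.medians == set()
        assert sorted(net.graph.edges) == [("000", "001"), ("001", "011")]

    def test_triangle_adds_exactly_the_steiner_median(self):
        net = median_joining(["110", "101", "011"])
        assert net.medians == {"111"}
        assert net.graph.degree("111") == 3
        assert all(net.graph["111"][x]["weight"] == 1
                   for x in ("110", "101", "011"))

        # exhaustive Steiner check: 111 is the unique single added node
        # minimizing total spanning cost
        def mst_cost(nodes):
            g = nx.Graph()
            for a in nodes:
                for b in nodes:
                    if a < b:
                        d = sum(x != y for x, y in zip(a, b))
                        g.add_edge(a, b, weight=d)
            return sum(d["weight"] for *_, d in
                       nx.minimum_spanning_tree(g).edges(data=True))

        base = {"110", "101", "011"}
        costs = {"".join(bits): mst_cost(base | {"".join(bits)})
                 for bits in product("01", repeat=3)}
        best = min(costs.values())
        winners = {h for h, c in costs.items() if c == best and h not in base}
        assert winners == {"111"}

    def test_single_haplotype(self):
        net = median_joining(["ACGT"])
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0

    def test_perfect_phylogeny_recovered_exactly(self, rng):
        """Haplotypes generated on a mutation tree (one new column per
        node, all nodes observed) come back as exactly that tree."""
        for _ in range(10):
            n = int(rng.integers(4, 12))
            L = n - 1
            haps = ["0" * L]
            edges = set()
            for k in range(1, n):
                parent = haps[int(rng.integers(0, k))]
                child = parent[:k - 1] + "1" + parent[k:]
                haps.append(child)
                edges.add(tuple(sorted((parent, child))))
            net = median_joining(haps)
            got = {tuple(sorted(e)) for e in net.graph.edges}
            assert got == edges
            assert net.medians == set()

    def test_observed_nodes_connected(self, default_dataset):
        ds = default_dataset
        haps = {}
        for gid, g in ds.truth["genotypes"].items():
            for hap, lab in zip(g["haplotypes"]["AMP4"], g["labels"]["AMP4"]):
                haps[hap] = haps.get(hap, 0) + 1
        net = median_joining(haps)
        assert nx.is_connected(net.graph)
        assert set(haps) <= set(net.graph.nodes)


class TestDistances:
    def test_distance_identities(self):
        net = median_joining(["110", "101", "011"])
        assert mutational_distance(net, "110", "110") == 0
        assert mutational_distance(net, "110", "101") == 2  # via the median

    def test_h_to_m_distance_equals_private_mutation_count(self):
        m = "AAAAAAAA"
        h = "AAAAATTT"       # M plus 3 private mutations
        f = "TTTTTAAA"
        net = median_joining([m, h, f])
        d = h_to_m_distances(net, {m: "M", h: "H", f: "F"})
        assert d == {h: 3}

    def test_two_origin_h_groups_give_bimodal_distances(self):
        m = "AAAAAAAAAA"
        h_near = "AAAAAAAAAT"
        h_far = "TTTTTAAAAA"
        net = median_joining([m, h_near, h_far])
        d = h_to_m_distances(net, {m: "M", h_near: "H", h_far: "H"})
        assert sorted(d.values()) == [1, 5]

    def test_no_m_nodes_is_an_error(self):
        net = median_joining(["AA", "AT"])
        with pytest.raises(ValueError, match="no M nodes"):
            h_to_m_distances(net, {"AA": "H", "AT": "F"})


class TestAnova:
    def test_disjoint_groups_r2_one(self):
        r2, p = anova_distance_vs_factor([1, 1, 5, 5], ["a", "a", "b", "b"])
        assert r2 == pytest.approx(1.0)
        assert p < 0.05

    def test_equal_values_r2_zero(self):
        r2, p = anova_distance_vs_factor([2, 2, 2, 2], ["a", "a", "b", "b"])
        assert r2 == 0.0 and p == 1.0

    def test_small_level_dropped(self):
        with pytest.raises(ValueError):
            anova_distance_vs_factor([1, 2, 3], ["a", "a", "b"])

    def test_power_for_unit_shift(self, rng):
        hits = 0
        for _ in range(200):
            a = rng.normal(2.0, 1.0, 20)
            b = rng.normal(3.0, 1.0, 20)
            _, p = anova_distance_vs_factor(
                np.concatenate([a, b]), ["a"] * 20 + ["b"] * 20)
            hits += p < 0.05
        assert hits / 200 > 0.5
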