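"""Median-joining network on macrohaplotypes, with star contraction.

The median-joining procedure iterates between building the
epsilon-relaxed minimum spanning network (MSN) over the current node set
and adding quasi-median (Steiner) vectors generated by connected triples
when they reduce the connection cost; unobserved nodes that end up with
degree <= 2 are pruned.  Star contraction is the usual pre-processing
step that collapses star-like clusters of near-identical haplotypes
(satellites within ``delta`` mutations of a locally dominant center) into
the center, summing multiplicities.  Distances between nodes are weighted
shortest paths in mutation counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


# ---------------------------------------------------------------------------
# star contraction


def star_contraction(haps: Mapping[str, int], delta: int = 1
                     ) -> tuple[dict[str, int], dict[str, str]]:
    """Merge satellite haplotypes into star centers.

    ``haps`` maps haplotype string to multiplicity.  Within the
    delta-neighbourhood graph a haplotype is merged into the neighbour
    with the highest (degree, multiplicity) — the star center —
    lexicographic order breaking ties deterministically.  Rounds repeat
    until stable.  Returns the contracted multiset and a mapping from
    every original haplotype to its final representative.
    """
    current = dict(haps)
    mapping = {h: h for h in haps}
    changed = True
    while changed:
        changed = False
        nodes = sorted(current)
        nbrs = {h: [g for g in nodes if g != h and _hamming(h, g) <= delta]
                for h in nodes}

        def rank(h: str) -> tuple:
            # star centers have higher neighbourhood degree, then higher
            # multiplicity; equal rank never merges (no pair collapse)
            return (len(nbrs[h]), current[h])

        merges: dict[str, str] = {}
        for h in nodes:
            if not nbrs[h]:
                continue
            best = min(sorted(nbrs[h]), key=lambda g: (-rank(g)[0], -rank(g)[1]))
            if rank(best) > rank(h):
                merges[h] = best
        # apply non-conflicting merges: a center must not itself merge away
        for h, c in sorted(merges.items()):
            if c in merges:
                continue
            if h not in current or c not in current:
                continue
            current[c] += current.pop(h)
            for orig, rep in mapping.items():
                if rep == h:
                    mapping[orig] = c
            changed = True
    return current, mapping


# ---------------------------------------------------------------------------
# median-joining


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph                       # nodes: haplotype strings
    observed: dict[str, int]              # observed node -> multiplicity
    medians: set[str] = field(default_factory=set)
    node_meta: dict[str, dict] = field(default_factory=dict)

    def edges(self) -> list[tuple[str, str, int]]:
        return [(a, b, d["weight"]) for a, b, d in self.graph.edges(data=True)]


def _msn(nodes: Sequence[str], epsilon: int = 0) -> nx.Graph:
    """Epsilon-relaxed minimum spanning network: process distance levels
    in increasing order; all edges of a level <= (connection level of
    their endpoints' components + epsilon) are kept."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if len(nodes) < 2:
        return g
    dist = {}
    for a, b in combinations(nodes, 2):
        dist[(a, b)] = _hamming(a, b)
    levels = sorted(set(dist.values()))
    uf = nx.utils.UnionFind(nodes)
    # connection level at which two components first join
    for lvl in levels:
        batch = [(a, b) for (a, b), d in dist.items() if d == lvl]
        # keep every edge whose endpoints are not yet connected at a
        # strictly smaller level (epsilon relaxes this by allowing edges
        # up to `lvl + epsilon` in the same sweep)
        keep = [(a, b) for a, b in batch if uf[a] != uf[b]]
        for a, b in keep:
            g.add_edge(a, b, weight=lvl)
        for a, b in keep:
            uf.union(a, b)
        if epsilon > 0:
            extra = [(a, b) for (a, b), d in dist.items()
                     if lvl < d <= lvl + epsilon and uf[a] != uf[b]]
            for a, b in extra:
                g.add_edge(a, b, weight=dist[(a, b)])
    return g


def _quasi_median(u: str, v: str, w: str) -> str:
    """Columnwise majority state of three haplotypes (ties -> u's state)."""
    out = []
    for x, y, z in zip(u, v, w):
        if y == z and y != x:
            out.append(y)
        else:
            out.append(x)
    return "".join(out)


def median_joining(haps: Sequence[str] | Mapping[str, int],
                   epsilon: int = 0, max_rounds: int = 50) -> HaplotypeNetwork:
    """Build the median-joining network of a set of haplotypes.

    Iterates: build the epsilon-relaxed MSN; for every triple with at
    least two MSN edges compute the quasi-median; add medians whose
    three-way star cost is strictly below the triple's current spanning
    cost; stop when no median is added.  Unobserved nodes of degree <= 2
    are then pruned and the final MSN is returned.  Deterministic under
    the lexicographic node ordering.
    """
    if isinstance(haps, Mapping):
        observed = dict(haps)
    else:
        observed = {}
        for h in haps:
            observed[h] = observed.get(h, 0) + 1
    if not observed:
        raise ValueError("no haplotypes")
    nodes = set(observed)
    medians: set[str] = set()
    for _ in range(max_rounds):
        g = _msn(sorted(nodes), epsilon)
        added = False
        for u in sorted(nodes):
            for v, w in combinations(sorted(g.neighbors(u)), 2):
                m = _quasi_median(v, u, w)  # center u dominates ties
                if m in nodes:
                    continue
                star = _hamming(m, u) + _hamming(m, v) + _hamming(m, w)
                span = g[u][v]["weight"] + g[u][w]["weight"]
                if star < span:
                    nodes.add(m)
                    medians.add(m)
                    added = True
        if not added:
            break
    # prune obsolete medians (degree <= 2, unobserved), iteratively
    while True:
        g = _msn(sorted(nodes), epsilon)
        drop = [n for n in medians if n in g and g.degree(n) <= 2]
        if not drop:
            break
        for n in drop:
            nodes.discard(n)
            medians.discard(n)
    g = _msn(sorted(nodes), epsilon)
    return HaplotypeNetwork(graph=g, observed=observed, medians=medians)


def mutational_distance(net: HaplotypeNetwork, a: str, b: str) -> int:
    """Weighted shortest-path distance (total mutation count) in the network."""
    if a == b:
        return 0
    try:
        return int(nx.shortest_path_length(net.graph, a, b, weight="weight"))
    except nx.NetworkXNoPath:
        raise ValueError(f"nodes {a!r} and {b!r} are disconnected") from None


def h_to_m_distances(net: HaplotypeNetwork, labels: Mapping[str, str]
                     ) -> dict[str, int]:
    """Minimum network distance from each H node to the M haplogroup.

    ``labels`` maps node (haplotype string) to F/M/H.  Returns
    ``{h_node: distance}``.
    """
    m_nodes = [n for n, l in labels.items() if l == "M" and n in net.graph]
    h_nodes = [n for n, l in labels.items() if l == "H" and n in net.graph]
    if not m_nodes:
        raise ValueError("no M nodes in the network")
    lengths = {}
    for h in h_nodes:
        lengths[h] = min(mutational_distance(net, h, m) for m in m_nodes)
    return lengths


def anova_distance_vs_factor(distances: Sequence[float],
                             factor: Sequence[str]
                             ) -> tuple[float, float]:
    """One-way ANOVA of network distances against a categorical factor.

    Returns ``(r_squared, p_value)`` with r^2 = SS_between / SS_total.
    Levels with fewer than 2 observations are dropped with a warning.
    """
    groups: dict[str, list[float]] = {}
    for d, f in zip(distances, factor):
        groups.setdefault(f, []).append(float(d))
    kept = {k: v for k, v in groups.items() if len(v) >= 2}
    dropped = set(groups) - set(kept)
    if dropped:
        log.warning("ANOVA: dropping levels with < 2 observations: %s",
                    sorted(dropped))
    if len(kept) < 2:
        raise ValueError("need >= 2 factor levels with >= 2 observations")
    arrays = [np.asarray(v) for v in kept.values()]
    allv = np.concatenate(arrays)
    grand = allv.mean()
    ss_total = float(((allv - grand) ** 2).sum())
    ss_between = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrays))
    if ss_total == 0:
        return 0.0, 1.0
    stat, p = stats.f_oneway(*arrays)
    return ss_between / ss_total, float(p)


def export_edge_list(net: HaplotypeNetwork, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for a, b, w in sorted(net.edges()):
            fh.write(f"{a}\t{b}\t{w}\n")


def export_node_attributes(net: HaplotypeNetwork, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("node\tmultiplicity\tis_median\n")
        for n in sorted(net.graph.nodes):
            fh.write(f"{n}\t{net.observed.get(n, 0)}\t"
                     f"{int(n in net.medians)}\n")
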