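"""Neutral coalescent simulator conditioned on a fixed number of
segregating sites.

The standard Kingman coalescent for a panmictic, non-recombining locus:
while ``k`` lineages remain, an exponential waiting time with rate
``k(k-1)/2`` elapses and a uniformly chosen pair merges.  Mutations are
dropped on branches proportionally to branch length under the
infinite-sites model.  Conditioning on the observed number of segregating
sites ``S`` (rather than on a mutation rate) removes the nuisance
dependence on theta and is the null used by the joint D/H (``DH``) test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Genealogy:
    """A coalescent tree for ``n`` leaves.

    Nodes ``0..n-1`` are leaves; internal nodes are appended in coalescence
    order; node ``2n-2`` is the root.  ``parent[i]`` is -1 for the root;
    ``length[i]`` is the branch above node ``i`` (0 for the root);
    ``leafset[i]`` is a frozenset of the leaves below node ``i``.
    """

    n: int
    parent: np.ndarray
    length: np.ndarray
    leafset: list[frozenset[int]]

    @property
    def total_length(self) -> float:
        return float(self.length.sum())


def sample_genealogy(n: int, rng: np.random.Generator | int) -> Genealogy:
    """Draw one Kingman coalescent genealogy for ``n`` leaves."""
    if n < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(rng)
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    leafset: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        leafset.append(leafset[a] | leafset[b])
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    length = np.zeros(n_nodes)
    nonroot = parent >= 0
    length[nonroot] = node_time[parent[nonroot]] - node_time[nonroot]
    return Genealogy(n=n, parent=parent, length=length, leafset=leafset)


def drop_fixed_s_mutations(g: Genealogy, s: int,
                           rng: np.random.Generator | int) -> np.ndarray:
    """Place ``s`` infinite-sites mutations on the genealogy.

    Each mutation lands on a branch chosen proportionally to branch length;
    the derived allele is carried by the leaves below that branch.  Returns
    an ``(n, s)`` binary matrix (1 = derived).
    """
    if s < 0:
        raise ValueError("S must be >= 0")
    rng = np.random.default_rng(rng)
    out = np.zeros((g.n, s), dtype=np.int8)
    if s == 0:
        return out
    probs = g.length / g.length.sum()
    branches = rng.choice(len(g.length), size=s, p=probs)
    for col, b in enumerate(branches):
        out[sorted(g.leafset[b]), col] = 1
    return out


def simulate_fixed_s(n: int, s: int, rng: np.random.Generator | int) -> np.ndarray:
    """Convenience: one fixed-S replicate as an (n, s) derived-allele matrix."""
    rng = np.random.default_rng(rng)
    return drop_fixed_s_mutations(sample_genealogy(n, rng), s, rng)


def mutate_theta(g: Genealogy, theta: float,
                 rng: np.random.Generator | int) -> np.ndarray:
    """Drop Poisson(theta/2 * total length) infinite-sites mutations.

    Used by the synthetic-data generator where diversity level, not S, is
    the controlled quantity.
    """
    rng = np.random.default_rng(rng)
    s = rng.poisson(theta / 2.0 * g.total_length)
    return drop_fixed_s_mutations(g, int(s), rng)
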