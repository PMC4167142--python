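"""F/M/H haplogroup assignment and macrohaplotype construction.

Under the three-allele model of grapevine sex (M > H > F dominance, XY
males), the haplogroup shared by female, male and hermaphrodite genotypes
is the female (X-like) F group; the alternate haplotypes of males and
hermaphrodites, absent from F, are the M and H groups respectively.  The
F set is seeded with every haplotype carried by a female genotype and
then absorbs haplotypes within a small mutational distance of the seed
set; dosage expectations (females FF, males MF, hermaphrodites HF or HH)
are recorded, never coerced.  Concatenating one genotype's per-amplicon
haplotypes in genomic order yields its two macrohaplotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .datamodel import Compartment, GenotypeRecord, Sex
from .phasing import HaplotypeSet

F, M, H, AMBIGUOUS = "F", "M", "H", "ambiguous"


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y and x != "N" and y != "N")


def build_nj_tree(haplotypes: Sequence[str]) -> TreeNode:
    """Neighbor-joining tree on pairwise Hamming distances (indels count 1).

    Input order is stabilised by sorting distinct haplotypes, so the tree
    is deterministic.  With fewer than 3 distinct haplotypes a degenerate
    star tree is returned with a warning.
    """
    distinct = sorted(set(haplotypes))
    if len(distinct) < 3:
        warnings.warn("fewer than 3 distinct haplotypes; returning star tree",
                      stacklevel=2)
        root = TreeNode(name=None)
        for h in distinct:
            root.append(TreeNode(name=h, length=0.0))
        return root
    n = len(distinct)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _hamming(distinct[i], distinct[j])
            dm[i, j] = dm[j, i] = d
    return nj(DistanceMatrix(dm, ids=distinct))


@dataclass
class HaplogroupAssignment:
    amplicon: str
    labels: dict[int, str]              # haplotype index -> F/M/H/ambiguous
    f_dosage: dict[str, int]            # genotype id -> 0/1/2
    flags: dict[str, str] = field(default_factory=dict)

    def label_of(self, hap_idx: int) -> str:
        return self.labels.get(hap_idx, AMBIGUOUS)


def assign_haplogroups(hs: HaplotypeSet, phenos: Sequence[GenotypeRecord],
                       max_link_dist: int = 1) -> HaplogroupAssignment:
    """Assign each phased haplotype of one amplicon to F, M or H.

    Seeds the F set with haplotypes carried by any non-outgroup female,
    absorbs haplotypes within ``max_link_dist`` mutations of a seed, then
    labels the remaining haplotypes M if carried by a male and H if
    carried (only) by a hermaphrodite.  Genotypes whose F dosage violates
    the XY expectation are flagged, not coerced.
    """
    by_id = {r.id: r for r in phenos}
    carriers: dict[int, set[str]] = {}
    for p in hs.phases:
        for hidx in (p.hap_a, p.hap_b):
            carriers.setdefault(hidx, set()).add(p.genotype_id)

    def sexes_of(hidx: int, outgroup: bool = False) -> set[Sex]:
        out = set()
        for gid in carriers.get(hidx, ()):
            r = by_id.get(gid)
            if r is None:
                continue
            if (r.compartment is Compartment.OUTGROUP) != outgroup:
                continue
            out.add(r.sex)
        return out

    # F side is seeded by every haplotype carried by a (non-outgroup)
    # female; the male (Y-like) side by the modal male-exclusive haplotype
    # (the shared M background) and its max_link_dist neighbourhood.
    f_seed = {hidx for hidx in carriers if Sex.FEMALE in sexes_of(hidx)}
    male_only = [hidx for hidx in carriers
                 if hidx not in f_seed and Sex.MALE in sexes_of(hidx)]
    m_seed: set[int] = set()
    if male_only:
        modal = max(male_only,
                    key=lambda h: (len(carriers[h]), hs.haplotypes[h]))
        m_seed = {h for h in male_only
                  if _hamming(hs.haplotypes[h],
                              hs.haplotypes[modal]) <= max_link_dist}
    side: dict[int, str] = {h: F for h in f_seed}
    side.update({h: M for h in m_seed})
    # competitive single-linkage growth: repeatedly attach the unassigned
    # haplotype nearest to either side (the tree-clade criterion for deep
    # M/F divergence); equidistant haplotypes are flagged ambiguous
    unassigned = sorted(set(carriers) - set(side))
    ambiguous_side: set[int] = set()
    while unassigned:
        best = None
        for h in unassigned:
            hap = hs.haplotypes[h]
            d_f = min((_hamming(hap, hs.haplotypes[s])
                       for s, lab in side.items() if lab == F), default=None)
            d_m = min((_hamming(hap, hs.haplotypes[s])
                       for s, lab in side.items() if lab == M), default=None)
            if d_f is None and d_m is None:
                continue
            d = min(x for x in (d_f, d_m) if x is not None)
            lab = F if (d_m is None or (d_f is not None and d_f < d_m)) else M
            tie = d_f is not None and d_m is not None and d_f == d_m
            cand = (d, hs.haplotypes[h], h, lab, tie)
            if best is None or cand[:2] < best[:2]:
                best = cand
        if best is None:
            break  # no seeds at all; fall through to carrier-sex labels
        _, _, h, lab, tie = best
        side[h] = lab
        if tie:
            ambiguous_side.add(h)
        unassigned.remove(h)

    labels: dict[int, str] = {}
    for hidx in carriers:
        sx = sexes_of(hidx) | sexes_of(hidx, outgroup=True)
        s = side.get(hidx)
        if hidx in ambiguous_side:
            labels[hidx] = AMBIGUOUS
        elif s == F:
            labels[hidx] = F
        elif s == M or s is None:
            if Sex.MALE in sx:
                labels[hidx] = M
            elif Sex.HERMAPHRODITE in sx:
                labels[hidx] = H
            elif Sex.FEMALE in sx:
                labels[hidx] = F  # outgroup-female-only haplotype
            else:
                labels[hidx] = AMBIGUOUS

    f_dosage: dict[str, int] = {}
    flags: dict[str, str] = {}
    for p in hs.phases:
        gid = p.genotype_id
        dose = sum(1 for hidx in (p.hap_a, p.hap_b) if labels.get(hidx) == F)
        f_dosage[gid] = dose
        r = by_id.get(gid)
        if r is None or r.compartment is Compartment.OUTGROUP:
            continue
        if r.sex is Sex.FEMALE and dose != 2:
            flags[gid] = f"female with F dosage {dose}"
        elif r.sex is Sex.MALE and dose != 1:
            flags[gid] = f"male with F dosage {dose}"
        elif r.sex is Sex.HERMAPHRODITE and dose == 2:
            flags[gid] = "hermaphrodite with 2 F haplotypes"
    return HaplogroupAssignment(amplicon=hs.amplicon, labels=labels,
                                f_dosage=f_dosage, flags=flags)


@dataclass
class Macrohaplotype:
    genotype_id: str
    copy: int                      # 1 or 2
    sequence: str                  # concatenated over amplicons, genomic order
    label: str                     # F, M, H (or ambiguous)
    recombinant: bool = False


def haplotypes_by_group(hs: HaplotypeSet, assignment: HaplogroupAssignment,
                        phenos: Sequence[GenotypeRecord],
                        compartment: Compartment | None = None,
                        sex: Sex | None = None) -> dict[str, list[str]]:
    """Collect haplotype copies per haplogroup label, optionally
    restricted to carriers of one compartment and/or sex."""
    by_id = {r.id: r for r in phenos}
    out: dict[str, list[str]] = {F: [], M: [], H: [], AMBIGUOUS: []}
    for p in hs.phases:
        r = by_id.get(p.genotype_id)
        if r is None:
            continue
        if compartment is not None and r.compartment is not compartment:
            continue
        if sex is not None and r.sex is not sex:
            continue
        for hidx in (p.hap_a, p.hap_b):
            out[assignment.label_of(hidx)].append(hs.haplotypes[hidx])
    return out


def build_macrohaplotypes(
    hap_sets: Mapping[str, HaplotypeSet],
    assignments: Mapping[str, HaplogroupAssignment],
    phenos: Sequence[GenotypeRecord],
    amplicon_order: Sequence[str],
) -> list[Macrohaplotype]:
    """Concatenate per-amplicon haplotypes into two macrohaplotypes per
    genotype.

    Within each genotype the F-labelled haplotypes concatenate into the F
    macrohaplotype and the non-F ones into the M/H macrohaplotype (label
    from the genotype's sex).  Genotypes with inconsistent per-amplicon
    labels (e.g. two F haplotypes at one amplicon in a male) are flagged
    recombinant; genotypes missing an amplicon are excluded.
    """
    by_id = {r.id: r for r in phenos}
    common = None
    for amp in amplicon_order:
        ids = set(hap_sets[amp].genotype_ids)
        common = ids if common is None else (common & ids)
    out: list[Macrohaplotype] = []
    for gid in sorted(common or ()):
        r = by_id.get(gid)
        sex = r.sex if r is not None else None
        parts_a: list[str] = []   # F side
        parts_b: list[str] = []   # alternate (M/H) side
        labels_a: list[str] = []
        labels_b: list[str] = []
        recomb = False
        for amp in amplicon_order:
            hs = hap_sets[amp]
            asg = assignments[amp]
            p = next(ph for ph in hs.phases if ph.genotype_id == gid)
            la, lb = asg.label_of(p.hap_a), asg.label_of(p.hap_b)
            ha, hb = hs.haplotypes[p.hap_a], hs.haplotypes[p.hap_b]
            if lb == F and la != F:
                ha, hb, la, lb = hb, ha, lb, la  # keep F on side a
            parts_a.append(ha)
            parts_b.append(hb)
            labels_a.append(la)
            labels_b.append(lb)
            # per-amplicon dosage check against the sex expectation
            dose = (la == F) + (lb == F)
            expect = {Sex.FEMALE: (2,), Sex.MALE: (1,),
                      Sex.HERMAPHRODITE: (0, 1)}.get(sex, (0, 1, 2))
            if dose not in expect:
                recomb = True
        def side_label(side_labels: list[str]) -> str:
            nonf = [l for l in side_labels if l not in (F, AMBIGUOUS)]
            if not nonf:
                return F if F in side_labels else AMBIGUOUS
            lab = max(sorted(set(nonf)), key=nonf.count)
            if sex is Sex.HERMAPHRODITE and lab == M:
                return H  # shared M/H haplotype carried by a hermaphrodite
            return lab

        label_a = F if sex is Sex.FEMALE else side_label(labels_a)
        label_b = F if sex is Sex.FEMALE else side_label(labels_b)
        if sex is not Sex.FEMALE:
            nonf_b = [l for l in labels_b if l not in (F, AMBIGUOUS)]
            allowed = {label_b, M} if sex is Sex.HERMAPHRODITE else {label_b}
            if any(l not in allowed for l in nonf_b):
                recomb = True
        out.append(Macrohaplotype(genotype_id=gid, copy=1,
                                  sequence="".join(parts_a), label=label_a,
                                  recombinant=recomb))
        out.append(Macrohaplotype(genotype_id=gid, copy=2,
                                  sequence="".join(parts_b), label=label_b,
                                  recombinant=recomb))
    return out
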