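"""F/M/H haplogroup assignment, NJ trees and macrohaplotypes."""

import numpy as np
import pytest

from sexlinkscan.datamodel import (
    A, T, Compartment, GenotypeRecord, Sex, SiteKind, SiteMeta,
)
from sexlinkscan.haplogroups import (
    assign_haplogroups,
    build_macrohaplotypes,
    build_nj_tree,
)
from sexlinkscan.phasing import GenotypePhase, HaplotypeSet


def test_nj_recovers_additive_quartet_topology():
    # ((A,B),(C,D)): AB and CD are cherries under the four-point condition
    haps = ["AAAAAA", "AAAATT", "TTTTAA", "TTTTTT"]
    tree = build_nj_tree(haps)
    tips = {t.name for t in tree.tips()}
    assert tips == set(haps)
    # the AB | CD bipartition must be present
    for node in tree.non_tips():
        names = {t.name for t in node.tips()}
        if len(names) == 2:
            assert names in ({"AAAAAA", "AAAATT"}.__class__(
                {"AAAAAA", "AAAATT"}), {"TTTTAA", "TTTTTT"})


def test_nj_degenerate_inputs_warn():
    with pytest.warns(UserWarning, match="star"):
        tree = build_nj_tree(["AA", "AT"])
    assert len(list(tree.tips())) == 2
    with pytest.warns(UserWarning, match="star"):
        tree = build_nj_tree(["AA", "AA", "AA"])
    assert len(list(tree.tips())) == 1


def _hapset(haplotypes, phase_pairs, amp="ampA"):
    sites = [SiteMeta(amp, 100 + j, SiteKind.SNP, (A, T))
             for j in range(len(haplotypes[0]))]
    phases = [GenotypePhase(gid, a, b, 1.0, False)
              for gid, (a, b) in phase_pairs.items()]
    return HaplotypeSet(
        amplicon=amp, sites=sites, haplotypes=list(haplotypes),
        frequencies=np.full(len(haplotypes), 1.0 / len(haplotypes)),
        phases=phases, loglik=0.0, converged=True,
        genotype_ids=list(phase_pairs))


def _phenos(spec):
    comp = {"f": Compartment.WILD, "m": Compartment.WILD,
            "h": Compartment.DOMESTICATED}
    sex = {"f": Sex.FEMALE, "m": Sex.MALE, "h": Sex.HERMAPHRODITE}
    return [GenotypeRecord(g, sex[g[0]], comp[g[0]]) for g in spec]


def test_textbook_assignment():
    # females {f1,f1},{f1,f2}; male {f1,m1} -> F={f1,f2}, M={m1}
    haps = ["AAAA", "AAAT", "TTTT"]   # f1, f2, m1
    hs = _hapset(haps, {"f0": (0, 0), "f1": (0, 1), "m0": (0, 2)})
    asg = assign_haplogroups(hs, _phenos(["f0", "f1", "m0"]))
    assert asg.label_of(0) == "F" and asg.label_of(1) == "F"
    assert asg.label_of(2) == "M"
    assert asg.f_dosage == {"f0": 2, "f1": 2, "m0": 1}
    assert asg.flags == {}


def test_hermaphrodite_with_two_f_haplotypes_is_flagged_not_coerced():
    haps = ["AAAA", "TTTT"]
    hs = _hapset(haps, {"f0": (0, 0), "m0": (0, 1), "h0": (0, 0)})
    asg = assign_haplogroups(hs, _phenos(["f0", "m0", "h0"]))
    assert asg.f_dosage["h0"] == 2
    assert "h0" in asg.flags


def test_near_f_haplotype_absorbed_into_f_set():
    # hap 1 is one mutation from a female haplotype, carried by a male
    haps = ["AAAA", "AAAT", "TTTT"]
    hs = _hapset(haps, {"f0": (0, 0), "m0": (1, 2), "m1": (2, 2)})
    asg = assign_haplogroups(hs, _phenos(["f0", "m0", "m1"]))
    assert asg.label_of(1) == "F"
    assert asg.label_of(2) == "M"
    assert "m1" in asg.flags  # male with F dosage 0


def test_shared_male_hermaphrodite_haplotype_is_m_at_hap_level():
    haps = ["AAAA", "TTTT"]
    hs = _hapset(haps, {"f0": (0, 0), "m0": (0, 1), "h0": (0, 1)})
    asg = assign_haplogroups(hs, _phenos(["f0", "m0", "h0"]))
    assert asg.label_of(1) == "M"  # dominance: carried by a male


def test_synthetic_assignment_matches_truth(default_dataset):
    from sexlinkscan import phasing, sites
    ds = default_dataset
    m = sites.filter_sites(sites.extract_polymorphic_sites(ds.alignments,
                                                           ds.panel))
    core = [r.id for r in ds.phenotypes
            if r.compartment is not Compartment.OUTGROUP]
    mm = m.subset_genotypes(core)
    for amp in ["AMP1", "AMP4"]:
        hs = phasing.em_phase(mm, amplicon=amp, seed=5, n_restarts=2)
        asg = assign_haplogroups(hs, ds.phenotypes)
        for p in hs.phases:
            tru = set(ds.truth["genotypes"][p.genotype_id]["labels"][amp])
            la, lb = asg.label_of(p.hap_a), asg.label_of(p.hap_b)
            if ds.truth["genotypes"][p.genotype_id]["sex"] == "hermaphrodite":
                la = "H" if la == "M" else la
                lb = "H" if lb == "M" else lb
            assert {la, lb} == tru


def test_macrohaplotypes_concatenate_in_genomic_order():
    hapsA = ["AAA", "TTT"]
    hapsB = ["GGGG".replace("G", "A"), "TTTT"]
    hsA = _hapset(hapsA, {"f0": (0, 0), "m0": (0, 1)}, amp="ampA")
    hsB = _hapset(hapsB, {"f0": (0, 0), "m0": (0, 1)}, amp="ampB")
    phenos = _phenos(["f0", "m0"])
    asgA = assign_haplogroups(hsA, phenos)
    asgB = assign_haplogroups(hsB, phenos)
    macros = build_macrohaplotypes({"ampA": hsA, "ampB": hsB},
                                   {"ampA": asgA, "ampB": asgB},
                                   phenos, ["ampA", "ampB"])
    by = {(m.genotype_id, m.copy): m for m in macros}
    male_m = by[("m0", 2)]
    assert male_m.label == "M"
    assert male_m.sequence == "TTT" + "TTTT"
    assert male_m.sequence[:3] in hapsA and male_m.sequence[3:] in hapsB
    assert by[("f0", 1)].label == "F" and not by[("f0", 1)].recombinant


def test_hermaphrodite_dosage_departure_flagged_recombinant():
    hapsA = ["AAA", "TTT"]
    hsA = _hapset(hapsA, {"f0": (0, 0), "m0": (0, 1), "h0": (0, 1)}, "ampA")
    hapsB = ["AAAA", "TTTT"]
    # hermaphrodite has two F haplotypes at ampB: departs from HF at one
    hsB = _hapset(hapsB, {"f0": (0, 0), "m0": (0, 1), "h0": (0, 0)}, "ampB")
    phenos = _phenos(["f0", "m0", "h0"])
    asgA, asgB = (assign_haplogroups(h, phenos) for h in (hsA, hsB))
    macros = build_macrohaplotypes({"ampA": hsA, "ampB": hsB},
                                   {"ampA": asgA, "ampB": asgB},
                                   phenos, ["ampA", "ampB"])
    h_macros = [m for m in macros if m.genotype_id == "h0"]
    assert all(m.recombinant for m in h_macros)
    assert {m.label for m in h_macros} == {"F", "H"}
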