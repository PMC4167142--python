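"""Synthetic XY-region amplicon datasets with known truth.

The generator emulates the statistical structure of a small,
non-recombining XY sex-determining region resequenced as four amplicons
in a dioecious wild population plus derived hermaphrodite cultivars:

* a diverse X-like (F) haplotype pool drawn from a neutral coalescent,
* a bottlenecked Y-like (M) pool: one ancestral background haplotype
  carrying fixed M-diagnostic alleles (making males obligate
  heterozygotes at those sites) plus rare private singletons,
* hermaphrodite (H) alleles derived from the M background with extra
  private mutations, optionally importing a random F haplotype's alleles
  within a designated amplicon window (X-into-Y introgression),
* diploid consensus FASTA output (heterozygotes as IUPAC codes, indels
  as gaps), MCAR missing data, outgroup records of a sister species, and
  fabricated kinship/structure matrices.

A truth record captures every haplotype, phase, haplogroup label and
sex-diagnostic site so each downstream stage can be scored without
re-simulation.  Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import coalsim
from .datamodel import (
    AmpliconDef,
    Compartment,
    GenotypeRecord,
    KinshipMatrix,
    PAIR_TO_IUPAC,
    Sex,
    StructureMatrix,
    _BASE_CODE,
)
from . import io as slio

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_female: int = 30
    n_male: int = 30
    n_herm: int = 20
    amplicon_lengths: tuple[int, ...] = (1111, 849, 690, 498)
    #: per-amplicon count of fixed M-diagnostic sites (the emulated region
    #: carries ~46 sex-linked polymorphisms over its four amplicons, so the
    #: Y-like background differs from every X-like haplotype at many sites)
    m_diag_sites: tuple[int, ...] = (12, 12, 11, 11)
    #: per-amplicon scaled mutation rate of the F pool
    theta_f: float = 3.5
    #: expected private singletons per sampled M copy
    m_rare_rate: float = 0.25
    #: expected private mutations per H copy on top of the M background
    h_extra_rate: float = 1.0
    #: probability an H copy imports a random F haplotype in the window
    h_recomb_prob: float = 0.0
    #: amplicon indices eligible for the F import (default: last amplicon)
    h_recomb_window: tuple[int, ...] = (3,)
    missing_rate: float = 0.02
    #: expected mutations separating the outgroup species per amplicon
    outgroup_divergence: float = 8.0
    herm_hh_prob: float = 0.1
    #: fraction of F-pool variant sites coded as 1-bp indels
    indel_rate: float = 0.05
    kinship_block: tuple[int, ...] = ()
    structure_k: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.h_recomb_prob, self.missing_rate, self.herm_hh_prob,
                  self.indel_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if min(self.n_female, self.n_male, self.n_herm) < 0:
            raise ValueError("genotype counts must be >= 0")
        if len(self.m_diag_sites) != len(self.amplicon_lengths):
            raise ValueError("m_diag_sites must match amplicon count")


#: chromosome-2 style coordinates for the default four sex-linked amplicons
_DEFAULT_STARTS = (4900275, 4921838, 4989467, 5009549)
_FLANKS = ((4883461, 4884818), (5036645, 5037597))


def default_panel(cfg: SimConfig, with_flanks: bool = False) -> list[AmpliconDef]:
    """Amplicon definitions for the generated region (optionally with
    non-sex-linked flanking amplicons for region delimitation)."""
    panel = []
    if with_flanks:
        s, e = _FLANKS[0]
        panel.append(AmpliconDef("FLANK_UP", "chr2", s, e, e - s + 1))
    for k, (start, L) in enumerate(zip(_DEFAULT_STARTS, cfg.amplicon_lengths)):
        panel.append(AmpliconDef(f"AMP{k + 1}", "chr2", start, start + L - 1, L))
    if with_flanks:
        s, e = _FLANKS[1]
        panel.append(AmpliconDef("FLANK_DOWN", "chr2", s, e, e - s + 1))
    return panel


# ---------------------------------------------------------------------------
# haplotype pools


def _ref_sequence(L: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=L).astype(np.int8)  # base codes 0..3


def simulate_f_pool(cfg: SimConfig, amp_idx: int, n_copies: int,
                    ref: np.ndarray, diag_pos: np.ndarray,
                    rng: np.random.Generator) -> list[dict[int, str]]:
    """Draw ``n_copies`` F haplotypes as {column: derived state} sparse maps.

    Variation comes from a neutral coalescent genealogy with theta_f
    mutations; derived states are substitutions or (at ``indel_rate``)
    1-bp deletions, on columns disjoint from the M-diagnostic sites.
    """
    if n_copies < 2 or cfg.theta_f <= 0:
        return [dict() for _ in range(max(n_copies, 0))]
    g = coalsim.sample_genealogy(n_copies, rng)
    mat = coalsim.mutate_theta(g, cfg.theta_f, rng)
    L = cfg.amplicon_lengths[amp_idx]
    avail = np.setdiff1d(np.arange(L), diag_pos)
    n_mut = mat.shape[1]
    cols = rng.choice(avail, size=min(n_mut, len(avail)), replace=False)
    pool: list[dict[int, str]] = [dict() for _ in range(n_copies)]
    for m in range(len(cols)):
        col = int(cols[m])
        if rng.random() < cfg.indel_rate:
            derived = "-"
        else:
            derived = _BASES[int(rng.choice(
                [b for b in range(4) if b != ref[col]]))]
        for copy in np.nonzero(mat[:, m])[0]:
            pool[int(copy)][col] = derived
    return pool


def _private_mutations(cfg_rate: float, L: int, used: set[int], ref: np.ndarray,
                       rng: np.random.Generator) -> dict[int, str]:
    out: dict[int, str] = {}
    k = rng.poisson(cfg_rate)
    for _ in range(int(k)):
        col = int(rng.integers(0, L))
        if col in used:
            continue
        out[col] = _BASES[int(rng.choice(
            [b for b in range(4) if b != ref[col]]))]
    return out


def simulate_m_pool(cfg: SimConfig, amp_idx: int, n_copies: int,
                    ref: np.ndarray, diag_pos: np.ndarray,
                    diag_alleles: dict[int, str],
                    rng: np.random.Generator) -> list[dict[int, str]]:
    """M haplotypes: fixed diagnostic alleles + rare private singletons."""
    L = cfg.amplicon_lengths[amp_idx]
    pool = []
    for _ in range(n_copies):
        hap = dict(diag_alleles)
        hap.update(_private_mutations(cfg.m_rare_rate, L, set(diag_alleles),
                                      ref, rng))
        pool.append(hap)
    return pool


def derive_h_pool(cfg: SimConfig, amp_idx: int, n_copies: int,
                  ref: np.ndarray, diag_alleles: dict[int, str],
                  f_pool: list[dict[int, str]],
                  recomb_flags: np.ndarray,
                  rng: np.random.Generator) -> list[dict[int, str]]:
    """H haplotypes: M background + extra private mutations; recombined
    copies (``recomb_flags``) import a random F haplotype instead when
    this amplicon is in the eligible window."""
    L = cfg.amplicon_lengths[amp_idx]
    pool = []
    for c in range(n_copies):
        if recomb_flags[c] and amp_idx in cfg.h_recomb_window and f_pool:
            donor = f_pool[int(rng.integers(0, len(f_pool)))]
            pool.append(dict(donor))
            continue
        hap = dict(diag_alleles)
        hap.update(_private_mutations(cfg.h_extra_rate, L, set(diag_alleles),
                                      ref, rng))
        pool.append(hap)
    return pool


# ---------------------------------------------------------------------------
# assembly


def _hap_to_seq(ref: np.ndarray, hap: dict[int, str]) -> list[str]:
    seq = [_BASES[b] for b in ref]
    for col, state in hap.items():
        seq[col] = state
    return seq


def _consensus(seq_a: list[str], seq_b: list[str],
               missing_cols: set[int]) -> str:
    out = []
    for j, (a, b) in enumerate(zip(seq_a, seq_b)):
        if j in missing_cols:
            out.append("N")
        elif a == b:
            out.append(a)  # includes '-' for hom deletion
        elif a == "-" or b == "-":
            base = a if b == "-" else b
            out.append(base.lower())  # heterozygous presence/absence
        else:
            pair = tuple(sorted((_BASE_CODE[a], _BASE_CODE[b])))
            out.append(PAIR_TO_IUPAC[pair])
    return "".join(out)


@dataclass
class SimDataset:
    cfg: SimConfig
    panel: list[AmpliconDef]
    alignments: dict[str, dict[str, str]]
    phenotypes: list[GenotypeRecord]
    kinship: KinshipMatrix
    structure: StructureMatrix
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for amp in self.panel:
            slio.write_amplicon_fasta(outdir / f"{amp.name}.fasta",
                                      self.alignments[amp.name])
        slio.write_phenotypes(outdir / "phenotypes.tsv", self.phenotypes)
        slio.write_kinship(outdir / "kinship.csv", self.kinship)
        slio.write_structure(outdir / "structure.csv", self.structure)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def assemble_dataset(cfg: SimConfig, with_flanks: bool = False) -> SimDataset:
    """Generate a full synthetic dataset under ``cfg``.

    Females are FF, males FM, hermaphrodites HF (or HH with probability
    ``herm_hh_prob``); three outgroup records of sister species are
    appended.  Returns an in-memory dataset; use :meth:`SimDataset.write`
    for files.
    """
    n_tot = cfg.n_female + cfg.n_male + cfg.n_herm
    if n_tot == 0:
        raise ValueError("zero genotypes requested")
    rng = np.random.default_rng(cfg.seed)
    panel = default_panel(cfg, with_flanks)
    sex_amps = [a for a in panel if a.name.startswith("AMP")]

    gids = ([f"F{i:03d}" for i in range(cfg.n_female)]
            + [f"M{i:03d}" for i in range(cfg.n_male)]
            + [f"H{i:03d}" for i in range(cfg.n_herm)])
    sexes = ([Sex.FEMALE] * cfg.n_female + [Sex.MALE] * cfg.n_male
             + [Sex.HERMAPHRODITE] * cfg.n_herm)
    comps = ([Compartment.WILD] * (cfg.n_female + cfg.n_male)
             + [Compartment.DOMESTICATED] * cfg.n_herm)
    herm_hh = rng.random(cfg.n_herm) < cfg.herm_hh_prob
    h_recomb = rng.random(cfg.n_herm * 2) < cfg.h_recomb_prob

    outgroups = [
        GenotypeRecord("OUT_bal", Sex.MALE, Compartment.OUTGROUP,
                       species="V. balansaeana"),
        GenotypeRecord("OUT_mon", Sex.FEMALE, Compartment.OUTGROUP,
                       species="V. monticola"),
        GenotypeRecord("OUT_coi", Sex.FEMALE, Compartment.OUTGROUP,
                       species="V. coignetiae"),
    ]

    n_f_copies = 2 * cfg.n_female + cfg.n_male + int((~herm_hh).sum())
    alignments: dict[str, dict[str, str]] = {}
    truth: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "amplicons": {},
        "genotypes": {},
    }
    for gid, sex, comp in zip(gids, sexes, comps):
        truth["genotypes"][gid] = {"sex": sex.value, "compartment": comp.value,
                                   "haplotypes": {}, "labels": {}}

    for amp_idx, amp in enumerate(sex_amps):
        L = amp.aligned_length
        ref = _ref_sequence(L, rng)
        n_diag = cfg.m_diag_sites[amp_idx]
        diag_pos = np.sort(rng.choice(L, size=n_diag, replace=False))
        diag_alleles: dict[int, str] = {}
        for p in diag_pos:
            p = int(p)
            if rng.random() < cfg.indel_rate:
                diag_alleles[p] = "-"
            else:
                diag_alleles[p] = _BASES[int(rng.choice(
                    [b for b in range(4) if b != ref[p]]))]

        f_pool = simulate_f_pool(cfg, amp_idx, n_f_copies, ref, diag_pos, rng)
        rng.shuffle(f_pool)
        m_pool = simulate_m_pool(cfg, amp_idx, cfg.n_male, ref, diag_pos,
                                 diag_alleles, rng)
        n_h_copies = int(herm_hh.sum()) * 2 + int((~herm_hh).sum())
        h_pool = derive_h_pool(cfg, amp_idx, n_h_copies, ref, diag_alleles,
                               f_pool, h_recomb, rng)

        truth["amplicons"][amp.name] = {
            "length": L,
            "diag_positions": [int(amp.start + p) for p in diag_pos],
            "diag_alleles": {str(int(amp.start + p)): a
                             for p, a in diag_alleles.items()},
        }

        seqs: dict[str, str] = {}
        fi = mi = hi = 0
        for g_idx, (gid, sex) in enumerate(zip(gids, sexes)):
            if sex is Sex.FEMALE:
                hap1, hap2 = f_pool[fi], f_pool[fi + 1]; fi += 2
                labels = ("F", "F")
            elif sex is Sex.MALE:
                hap1, hap2 = f_pool[fi], m_pool[mi]; fi += 1; mi += 1
                labels = ("F", "M")
            else:
                k = g_idx - cfg.n_female - cfg.n_male
                if herm_hh[k]:
                    hap1, hap2 = h_pool[hi], h_pool[hi + 1]; hi += 2
                    labels = ("H", "H")
                else:
                    hap1, hap2 = f_pool[fi], h_pool[hi]; fi += 1; hi += 1
                    labels = ("F", "H")
            seq1, seq2 = _hap_to_seq(ref, hap1), _hap_to_seq(ref, hap2)
            var_cols = set(hap1) | set(hap2) | set(diag_alleles)
            missing_cols = {c for c in var_cols
                            if rng.random() < cfg.missing_rate}
            seqs[gid] = _consensus(seq1, seq2, missing_cols)
            truth["genotypes"][gid]["haplotypes"][amp.name] = [
                "".join(seq1), "".join(seq2)]
            truth["genotypes"][gid]["labels"][amp.name] = list(labels)

        # outgroup: homozygous diverged background (ancestral at sample sites)
        for rec in outgroups:
            hap = _private_mutations(cfg.outgroup_divergence, L,
                                     set(diag_alleles), ref, rng)
            seq = _hap_to_seq(ref, hap)
            seqs[rec.id] = _consensus(seq, seq, set())
        alignments[amp.name] = seqs

    # neutral flanking amplicons: every genotype draws two coalescent haps
    for amp in panel:
        if amp.name.startswith("AMP"):
            continue
        L = amp.aligned_length
        ref = _ref_sequence(L, rng)
        pool = simulate_f_pool(
            SimConfig(seed=cfg.seed, theta_f=cfg.theta_f,
                      amplicon_lengths=(L,), m_diag_sites=(0,),
                      indel_rate=cfg.indel_rate),
            0, 2 * (n_tot + len(outgroups)), ref, np.array([], dtype=int), rng)
        rng.shuffle(pool)
        seqs = {}
        for k, gid in enumerate(gids + [r.id for r in outgroups]):
            h1, h2 = pool[2 * k], pool[2 * k + 1]
            seqs[gid] = _consensus(_hap_to_seq(ref, h1), _hap_to_seq(ref, h2),
                                   set())
        alignments[amp.name] = seqs

    phenotypes = [GenotypeRecord(gid, sex, comp)
                  for gid, sex, comp in zip(gids, sexes, comps)] + outgroups
    all_ids = [r.id for r in phenotypes]

    kin = np.eye(len(all_ids))
    pos = 0
    for fam in cfg.kinship_block:
        fam = min(fam, n_tot - pos)
        if fam <= 0:
            break
        kin[pos:pos + fam, pos:pos + fam] = 0.5
        np.fill_diagonal(kin[pos:pos + fam, pos:pos + fam], 1.0)
        pos += fam
    kinship = KinshipMatrix(all_ids, kin)

    k = max(cfg.structure_k, 1)
    groups = rng.integers(0, k, size=len(all_ids))
    q = np.full((len(all_ids), k), 0.1 / max(k - 1, 1)) if k > 1 \
        else np.ones((len(all_ids), 1))
    if k > 1:
        q[np.arange(len(all_ids)), groups] = 0.9
    structure = StructureMatrix(all_ids, q)

    truth["structure_groups"] = {g: int(grp) for g, grp in zip(all_ids, groups)}
    return SimDataset(cfg=cfg, panel=panel, alignments=alignments,
                      phenotypes=phenotypes, kinship=kinship,
                      structure=structure, truth=truth)
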