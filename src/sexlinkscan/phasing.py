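"""Haplotype reconstruction by expectation-maximization.

Per amplicon, unphased diploid genotypes over biallelic segregating sites
are resolved into haplotype pairs under a multinomial haplotype-frequency
model (the classic gene-counting EM): the E-step distributes each
ambiguous genotype over all compatible ordered haplotype pairs in
proportion to the product of current frequencies, the M-step re-estimates
frequencies from the expected counts.  Multiple seeded restarts guard
against local optima; the best-likelihood solution is kept and each
genotype is assigned its most probable compatible pair.  Missing sites
are marginalized over rather than imputed (both haplotype alleles free at
that site), up to an enumeration cap beyond which the missing site is
imputed to the major allele with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import ALLELES, INS, DEL, MISSING, SiteMatrix, SiteMeta

log = logging.getLogger(__name__)

_PAIR_CAP = 1 << 10       # full-enumeration budget per genotype
_ANCHOR_CAP = 1 << 6      # only near-unambiguous genotypes donate anchors
_MISSING_CAP = 64         # marginalization budget for missing sites


def allele_char(code: int) -> str:
    """One-character representation used in haplotype strings."""
    return {INS: "+", DEL: "-"}.get(code, ALLELES[code] if code >= 0 else "N")


@dataclass
class GenotypePhase:
    genotype_id: str
    hap_a: int               # index into HaplotypeSet.haplotypes
    hap_b: int
    posterior: float         # probability of the reported unordered pair
    ambiguous: bool          # True when >1 compatible pair existed


@dataclass
class HaplotypeSet:
    amplicon: str
    sites: list[SiteMeta]
    haplotypes: list[str]            # allele strings over segregating sites
    frequencies: np.ndarray
    phases: list[GenotypePhase]
    loglik: float
    converged: bool
    genotype_ids: list[str] = field(default_factory=list)

    def haplotype_pair(self, gid: str) -> tuple[str, str]:
        ph = next(p for p in self.phases if p.genotype_id == gid)
        return self.haplotypes[ph.hap_a], self.haplotypes[ph.hap_b]

    def all_haplotype_copies(self) -> list[tuple[str, int, str]]:
        """(genotype_id, copy index 1/2, haplotype string) for every copy."""
        out = []
        for p in self.phases:
            out.append((p.genotype_id, 1, self.haplotypes[p.hap_a]))
            out.append((p.genotype_id, 2, self.haplotypes[p.hap_b]))
        return out


def _genotype_codes(m: SiteMatrix) -> np.ndarray:
    """Per-site genotype code: 0 hom-major, 1 het, 2 hom-minor, -1 missing."""
    n, s = m.n_genotypes, m.n_sites
    g = np.full((n, s), -1, dtype=np.int8)
    for j, site in enumerate(m.sites):
        maj, minr = site.alleles
        pair = m.calls[:, j, :]
        ok = pair[:, 0] != MISSING
        dos = (pair == minr).sum(axis=1)
        g[ok, j] = dos[ok]
    return g


def _enumerate_pairs(row: np.ndarray) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Compatible haplotype pairs (as 0/1 tuples) for one genotype row,
    unordered, each with a multiplicity of 2 when heterozygous (the two
    orderings) or 1 when identical; marginalizes missing sites unless
    that alone would exceed its budget (then imputes to the major
    allele)."""
    mis = [j for j, v in enumerate(row) if v == -1]
    if 4 ** len(mis) > _MISSING_CAP:
        row = row.copy()
        row[row == -1] = 0
        mis = []
    het = [j for j, v in enumerate(row) if v == 1]
    base = np.where(row == 2, 1, 0).astype(np.int8)
    base[row == -1] = 0
    pairs = []
    n_het, n_mis = len(het), len(mis)
    # fix the first het site's phase: pairs are stored unordered with a
    # multiplicity of 2 whenever the two haplotypes differ
    for het_bits in range(1 << max(n_het - 1, 0)):
        for mis_bits in range(1 << (2 * n_mis)):
            h1 = base.copy()
            h2 = base.copy()
            for k, j in enumerate(het):
                if k == 0:
                    h1[j], h2[j] = 1, 0
                elif (het_bits >> (k - 1)) & 1:
                    h1[j], h2[j] = 1, 0
                else:
                    h1[j], h2[j] = 0, 1
            for k, j in enumerate(mis):
                h1[j] = (mis_bits >> (2 * k)) & 1
                h2[j] = (mis_bits >> (2 * k + 1)) & 1
            t1, t2 = tuple(h1.tolist()), tuple(h2.tolist())
            pairs.append((t1, t2, 2 if t1 != t2 else 1))
    if n_het == 0:
        # no het site was fixed; deduplicate unordered (h1, h2) vs (h2, h1)
        seen = {}
        for t1, t2, _ in pairs:
            key = (t1, t2) if t1 <= t2 else (t2, t1)
            seen[key] = 2 if t1 != t2 else 1
        pairs = [(a, b, mult) for (a, b), mult in seen.items()]
    return pairs


def _complement(row: np.ndarray, h: tuple[int, ...]) -> tuple[int, ...] | None:
    """The haplotype forced by a genotype once one haplotype is fixed;
    None if ``h`` is incompatible with the genotype.  Missing sites copy
    ``h``'s allele (no information either way)."""
    out = []
    for v, a in zip(row.tolist(), h):
        if v == 0:
            if a != 0:
                return None
            out.append(0)
        elif v == 2:
            if a != 1:
                return None
            out.append(1)
        elif v == 1:
            out.append(1 - a)
        else:  # missing
            out.append(a)
    return tuple(out)


def _ambiguity(row: np.ndarray) -> int:
    het = int((row == 1).sum())
    mis = int((row == -1).sum())
    return (1 << het) * (1 << (2 * mis))


def _compatible_pairs_all(codes: np.ndarray
                          ) -> list[list[tuple[tuple[int, ...], tuple[int, ...]]]]:
    """Per-genotype compatible (unordered) pairs, with anchored enumeration.

    Genotypes are processed in order of increasing ambiguity.  Those below
    the enumeration budget are expanded exhaustively and their haplotypes
    become anchor candidates; a genotype above the budget is resolved
    against the anchors: each compatible anchor haplotype determines the
    complementary haplotype, giving a linear-size pair list (the classic
    parsimony anchoring used when exhaustive expansion is infeasible).  If
    no anchor is compatible, the fully coupled split (all het minor
    alleles on one haplotype) is used as a deterministic fallback.
    """
    n, s = codes.shape
    order = sorted(range(n), key=lambda i: (_ambiguity(codes[i]), i))
    anchor_set: set[tuple[int, ...]] = set()
    anchor_list: list[tuple[int, ...]] = []

    def add_anchor(h: tuple[int, ...]) -> None:
        if h not in anchor_set:
            anchor_set.add(h)
            anchor_list.append(h)

    out: list[list] = [None] * n
    for i in order:
        row = codes[i]
        if _ambiguity(row) <= _PAIR_CAP:
            plist = _enumerate_pairs(row)
        else:
            mis = [j for j, v in enumerate(row.tolist()) if v == -1]
            if (1 << len(mis)) > 32:
                mis = []  # too many: complement copies the anchor there
            plist = []
            if anchor_list:
                A = np.array(anchor_list, dtype=np.int8)
                bad = (((row == 0) & (A == 1))
                       | ((row == 2) & (A == 0))).any(axis=1)
                comp = np.where(row == 1, 1 - A,
                                np.where(row == 2, 1,
                                         np.where(row == 0, 0, A)))
                n_compat = int((~bad).sum())
                if n_compat * (1 << len(mis)) > _PAIR_CAP:
                    mis = []  # complement copies the anchor at missing sites
                seen = set()
                for h_arr, c_arr in zip(A[~bad], comp[~bad]):
                    h = tuple(h_arr.tolist())
                    variants = [tuple(c_arr.tolist())]
                    for j in mis:
                        variants = [c[:j] + (b,) + c[j + 1:]
                                    for c in variants for b in (0, 1)]
                    for c in variants:
                        key = (h, c) if h <= c else (c, h)
                        if key not in seen:
                            seen.add(key)
                            plist.append((key[0], key[1],
                                          2 if h != c else 1))
                    if len(plist) >= 4 * _PAIR_CAP:
                        break  # deterministic cap; anchors are ordered
            if not plist:
                row_imp = row.copy()
                row_imp[row_imp == -1] = 0
                h1 = tuple(np.where(row_imp == 0, 0, 1).astype(int).tolist())
                h2 = _complement(row_imp, h1)
                plist = [(h1, h2, 2)] if h1 != h2 else [(h1, h1, 1)]
        out[i] = plist
        # only near-unambiguous genotypes (and anchored resolutions, whose
        # pair lists are small) donate anchors; exhaustive expansions of
        # mid-ambiguity genotypes would flood the anchor set
        if _ambiguity(row) <= _ANCHOR_CAP or _ambiguity(row) > _PAIR_CAP:
            for h1, h2, _ in plist:
                add_anchor(h1)
                add_anchor(h2)
    return out


def em_phase(m: SiteMatrix, amplicon: str | None = None, n_restarts: int = 20,
             tol: float = 1e-8, max_iter: int = 1000, seed: int = 0,
             check_monotone: bool = False) -> HaplotypeSet:
    """Phase one amplicon's genotypes by multi-restart EM.

    ``m`` is a (filtered) SiteMatrix; if ``amplicon`` is given only its
    sites are used.  Deterministic given ``seed``.
    """
    if amplicon is not None:
        keep = [j for j, s in enumerate(m.sites) if s.amplicon == amplicon]
        m = m.subset_sites(keep)
        amp_name = amplicon
    else:
        amps = {s.amplicon for s in m.sites}
        amp_name = amps.pop() if len(amps) == 1 else "+".join(sorted(amps))
    if m.n_genotypes < 2:
        raise ValueError("need >= 2 genotypes to phase")
    codes = _genotype_codes(m)

    # enumerate compatible pairs, building the global haplotype registry
    hap_index: dict[tuple[int, ...], int] = {}

    def idx(h: tuple[int, ...]) -> int:
        if h not in hap_index:
            hap_index[h] = len(hap_index)
        return hap_index[h]

    all_pairs = _compatible_pairs_all(codes)
    pair_h1, pair_h2, pair_geno, pair_mult = [], [], [], []
    geno_pairs: list[list[int]] = []
    for i in range(m.n_genotypes):
        plist = all_pairs[i]
        start = len(pair_h1)
        for h1, h2, mult in plist:
            pair_h1.append(idx(h1))
            pair_h2.append(idx(h2))
            pair_geno.append(i)
            pair_mult.append(mult)
        geno_pairs.append(list(range(start, len(pair_h1))))
    H = len(hap_index)
    pair_h1 = np.asarray(pair_h1)
    pair_h2 = np.asarray(pair_h2)
    pair_geno = np.asarray(pair_geno)
    pair_mult = np.asarray(pair_mult, dtype=float)
    n = m.n_genotypes

    rng = np.random.default_rng(seed)
    best = None
    inits = [np.full(H, 1.0 / H)]
    inits += [rng.dirichlet(np.ones(H)) for _ in range(max(n_restarts - 1, 0))]
    for f0 in inits:
        f = f0.copy()
        prev_ll = -np.inf
        converged = False
        for _ in range(max_iter):
            w = f[pair_h1] * f[pair_h2] * pair_mult
            geno_tot = np.bincount(pair_geno, weights=w, minlength=n)
            geno_tot = np.maximum(geno_tot, 1e-300)
            ll = float(np.log(geno_tot).sum())
            if check_monotone and ll < prev_ll - 1e-9:
                raise AssertionError("EM likelihood decreased")
            w_norm = w / geno_tot[pair_geno]
            f_new = (np.bincount(pair_h1, weights=w_norm, minlength=H)
                     + np.bincount(pair_h2, weights=w_norm, minlength=H)) / (2 * n)
            if abs(ll - prev_ll) < tol:
                f = f_new
                converged = True
                break
            f, prev_ll = f_new, ll
        if best is None or ll > best[0]:
            best = (ll, f, converged)
    ll, f, converged = best
    if not converged:
        warnings.warn("EM did not converge within max_iter; returning best "
                      "iterate", stacklevel=2)

    haps_bin = [None] * H
    for h, i in hap_index.items():
        haps_bin[i] = h

    _string_cache: dict[int, str] = {}

    def hap_string(k: int) -> str:
        if k not in _string_cache:
            _string_cache[k] = "".join(
                allele_char(m.sites[j].alleles[haps_bin[k][j]])
                for j in range(m.n_sites))
        return _string_cache[k]

    raw_phases: list[tuple] = []
    for i in range(n):
        pids = geno_pairs[i]
        # collapse ordered pairs into unordered
        unordered: dict[tuple[int, int], float] = {}
        for pid in pids:
            key = tuple(sorted((pair_h1[pid], pair_h2[pid])))
            unordered[key] = unordered.get(key, 0.0) \
                + f[pair_h1[pid]] * f[pair_h2[pid]] * pair_mult[pid]
        total = sum(unordered.values())
        if total <= 0:
            # degenerate: pick any compatible pair uniformly
            key = tuple(sorted((pair_h1[pids[0]], pair_h2[pids[0]])))
            post = 1.0 / len(unordered)
        else:
            best_p = max(unordered.values())
            ties = [k for k, v in unordered.items()
                    if v >= best_p - 1e-12 * max(best_p, 1)]
            key = min(ties, key=lambda k: (hap_string(k[0]), hap_string(k[1])))
            post = unordered[key] / total
        a, b = key
        if hap_string(a) > hap_string(b):
            a, b = b, a
        raw_phases.append((i, a, b, float(post), len(unordered) > 1))

    # prune the registry to haplotypes used in a phase or carrying
    # appreciable frequency mass; renormalize
    keep = sorted({a for _, a, _, _, _ in raw_phases}
                  | {b for _, _, b, _, _ in raw_phases}
                  | set(np.flatnonzero(f > 1e-6).tolist()))
    remap = {old: new for new, old in enumerate(keep)}
    f_kept = f[keep]
    f_kept = f_kept / f_kept.sum() if f_kept.sum() > 0 else f_kept
    hap_strings = [hap_string(k) for k in keep]
    phases = [GenotypePhase(genotype_id=m.genotype_ids[i], hap_a=remap[a],
                            hap_b=remap[b], posterior=post, ambiguous=amb)
              for i, a, b, post, amb in raw_phases]
    return HaplotypeSet(
        amplicon=amp_name, sites=list(m.sites), haplotypes=hap_strings,
        frequencies=f_kept, phases=phases, loglik=ll, converged=converged,
        genotype_ids=list(m.genotype_ids))


def phase_report(hs: HaplotypeSet, flag_below: float = 0.9) -> list[dict]:
    """Per-genotype phase summary; genotypes with posterior below
    ``flag_below`` are flagged."""
    used: dict[int, int] = {}
    for p in hs.phases:
        used[p.hap_a] = used.get(p.hap_a, 0) + 1
        used[p.hap_b] = used.get(p.hap_b, 0) + 1
    rows = []
    for p in hs.phases:
        rows.append({
            "genotype": p.genotype_id,
            "hap_a": hs.haplotypes[p.hap_a],
            "hap_b": hs.haplotypes[p.hap_b],
            "posterior": round(p.posterior, 4),
            "flagged": p.posterior < flag_below,
        })
    return rows
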