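"""Polymorphic-site extraction and filtering.

From per-amplicon alignments of diploid consensus sequences, every column
with at least two observed alleles becomes a SNP site and every distinct
contiguous gap extent becomes a single presence/absence indel site.  The
filters mirror the scan stage's inclusion rules: strictly less than 20 %
missing data and a minor allele frequency strictly above 5 %, both computed
on diploid allele counts over the full sample.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np

from .datamodel import (
    DEL,
    INS,
    MISSING,
    AmpliconDef,
    SiteKind,
    SiteMatrix,
    SiteMeta,
    decode_iupac,
)

log = logging.getLogger(__name__)


def _gap_extents(seq: str) -> list[tuple[int, int, str]]:
    """Maximal runs of indel characters ('-' or lowercase) in one sequence.

    Returns ``(start_col, end_col, state)`` with state ``'del'`` for an
    all-gap run (del/del), ``'het'`` for an all-lowercase run (ins/del) and
    ``'mixed'`` for a malformed mixture (treated as missing).
    """
    runs = []
    i, n = 0, len(seq)
    while i < n:
        ch = seq[i]
        if ch == "-" or ch.islower():
            j = i
            while j < n and (seq[j] == "-" or seq[j].islower()):
                j += 1
            chunk = seq[i:j]
            if set(chunk) == {"-"}:
                state = "del"
            elif "-" not in chunk:
                state = "het"
            else:
                state = "mixed"
            runs.append((i, j - 1, state))
            i = j
        else:
            i += 1
    return runs


def extract_polymorphic_sites(
    alignments: Mapping[str, Mapping[str, str]],
    panel: Sequence[AmpliconDef],
) -> SiteMatrix:
    """Extract all polymorphic sites across a panel of aligned amplicons.

    ``alignments`` maps amplicon name to ``{genotype_id: sequence}``.
    Genotypes absent from an amplicon get missing calls at its sites.
    Monomorphic columns are dropped; columns with more than two alleles are
    kept but flagged multi-allelic (they are removed by :func:`filter_sites`).
    """
    panel_by_name = {a.name: a for a in panel}
    genotype_ids: list[str] = []
    for amp_name in alignments:
        for gid in alignments[amp_name]:
            if gid not in genotype_ids:
                genotype_ids.append(gid)
    if not genotype_ids:
        raise ValueError("no sequences in any amplicon")

    all_sites: list[SiteMeta] = []
    all_calls: list[np.ndarray] = []  # per site: (n_genotypes, 2)

    for amp_name, seqs in alignments.items():
        if amp_name not in panel_by_name:
            raise KeyError(f"amplicon {amp_name!r} not in panel")
        amp = panel_by_name[amp_name]
        if not seqs:
            raise ValueError(f"amplicon {amp_name!r} has zero sequences")
        L = amp.aligned_length

        # --- indel sites: distinct gap extents keyed by start column -------
        extents: dict[tuple[int, int], None] = {}
        per_geno_runs: dict[str, dict[tuple[int, int], str]] = {}
        for gid, seq in seqs.items():
            runs = {}
            for s, e, state in _gap_extents(seq):
                runs[(s, e)] = state
                extents.setdefault((s, e), None)
            per_geno_runs[gid] = runs

        for (s, e) in sorted(extents):
            calls = np.full((len(genotype_ids), 2), MISSING, dtype=np.int8)
            for i, gid in enumerate(genotype_ids):
                if gid not in seqs:
                    continue
                runs = per_geno_runs[gid]
                if (s, e) in runs:
                    state = runs[(s, e)]
                    if state == "del":
                        calls[i] = (DEL, DEL)
                    elif state == "het":
                        calls[i] = (INS, DEL)
                    # mixed -> missing
                elif any(rs <= s <= re or rs <= e <= re for rs, re in runs):
                    # overlapping but different extent -> uncertain here
                    pass
                else:
                    chunk = seqs[gid][s:e + 1]
                    if "N" in chunk or "n" in chunk:
                        continue
                    calls[i] = (INS, INS)
            present = calls[calls[:, 0] != MISSING]
            observed = set(present.ravel().tolist())
            if len(observed) < 2:
                continue  # monomorphic (e.g. every genotype deleted)
            maj, minr = _major_minor(calls)
            all_sites.append(SiteMeta(
                amplicon=amp_name, position=amp.start + s,
                kind=SiteKind.INDEL, alleles=(maj, minr)))
            all_calls.append(calls)

        # --- SNP columns ---------------------------------------------------
        for col in range(L):
            calls = np.full((len(genotype_ids), 2), MISSING, dtype=np.int8)
            for i, gid in enumerate(genotype_ids):
                if gid not in seqs:
                    continue
                ch = seqs[gid][col]
                if ch == "-" or ch.islower():
                    continue  # base obscured by an indel at this genotype
                pair = decode_iupac(ch)
                calls[i] = pair
            present = calls[calls[:, 0] != MISSING]
            observed = sorted(set(present.ravel().tolist()))
            if len(observed) < 2:
                continue
            maj, minr = _major_minor(calls)
            multi = len(observed) > 2
            all_sites.append(SiteMeta(
                amplicon=amp_name, position=amp.start + col,
                kind=SiteKind.SNP, alleles=(maj, minr),
                multiallelic=multi))
            all_calls.append(calls)

    if not all_sites:
        warnings.warn("no polymorphic sites found", stacklevel=2)
        calls = np.zeros((len(genotype_ids), 0, 2), dtype=np.int8)
        return SiteMatrix(genotype_ids, [], calls)

    order = sorted(range(len(all_sites)),
                   key=lambda j: (all_sites[j].amplicon, all_sites[j].position,
                                  all_sites[j].kind.value))
    sites = [all_sites[j] for j in order]
    calls = np.stack([all_calls[j] for j in order], axis=1)
    return SiteMatrix(genotype_ids, sites, calls)


def _major_minor(calls: np.ndarray) -> tuple[int, int]:
    """Major/minor allele codes by diploid allele count (ties: lower code)."""
    col = calls[calls[:, 0] != MISSING]
    vals, cnt = np.unique(col.ravel(), return_counts=True)
    order = sorted(range(len(vals)), key=lambda k: (-cnt[k], vals[k]))
    maj = int(vals[order[0]])
    minr = int(vals[order[1]]) if len(vals) > 1 else maj
    return maj, minr


def filter_sites(m: SiteMatrix, max_missing: float = 0.20,
                 min_maf: float = 0.05) -> SiteMatrix:
    """Apply the missingness and frequency inclusion rules.

    A site is retained iff its missing fraction is strictly below
    ``max_missing`` and its minor allele frequency strictly above
    ``min_maf``.  Multi-allelic sites are dropped with a warning.  The
    thresholds are recorded on the returned matrix as ``provenance``.
    """
    keep: list[int] = []
    miss = m.missing_fraction()
    for j, site in enumerate(m.sites):
        if getattr(site, "multiallelic", False):
            log.warning("site %s:%d dropped: multi-allelic", site.amplicon,
                        site.position)
            continue
        if not miss[j] < max_missing:
            log.info("site %s:%d dropped: missing fraction %.3f", site.amplicon,
                     site.position, miss[j])
            continue
        maf = m.minor_allele_frequency(j)
        if not maf > min_maf:
            log.info("site %s:%d dropped: MAF %.3f", site.amplicon,
                     site.position, maf)
            continue
        keep.append(j)
    if not keep:
        warnings.warn("no sites pass the filters", stacklevel=2)
    out = m.subset_sites(keep)
    out.provenance = {"max_missing": max_missing, "min_maf": min_maf}
    return out
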