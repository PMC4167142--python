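"""Readers and writers for the file formats the pipeline touches.

Formats: aligned IUPAC multi-FASTA per amplicon (Biopython), tab-separated
phenotype tables, CSV kinship/structure matrices, the per-site report TSV
and an unphased VCF 4.2 export of a :class:`~sexlinkscan.datamodel.SiteMatrix`.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datamodel import (
    ALLELES,
    MISSING,
    VALID_FASTA_CHARS,
    AmpliconDef,
    Compartment,
    GenotypeRecord,
    KinshipMatrix,
    Sex,
    SiteKind,
    SiteMatrix,
    SiteMeta,
    StructureMatrix,
)

log = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = [
    "id", "sex", "compartment", "species",
    "geography", "use", "domestication_class", "structure_group",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def read_amplicon_fasta(path: str | Path, amplicon: AmpliconDef) -> dict[str, str]:
    """Read one amplicon's aligned diploid consensus FASTA.

    Every record must have length ``amplicon.aligned_length``.  Heterozygous
    positions are IUPAC ambiguity codes, ``N`` is missing, ``-`` marks a
    homozygous deletion and a lowercase base marks a heterozygous
    presence/absence indel.  Returns ``{genotype_id: sequence}`` with
    sequences validated but otherwise untouched (decoding happens during
    site extraction).
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if len(seq) != amplicon.aligned_length:
            raise FormatError(
                f"{path}: record {rec.id!r} has length {len(seq)}, expected "
                f"{amplicon.aligned_length} for amplicon {amplicon.name}"
            )
        bad = set(seq) - VALID_FASTA_CHARS
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains non-IUPAC characters {sorted(bad)}"
            )
        if rec.id in out:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        out[rec.id] = seq
    return out


def write_amplicon_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for gid, seq in sequences.items():
            fh.write(f">{gid}\n{seq}\n")


def read_phenotypes(path: str | Path) -> list[GenotypeRecord]:
    """Read the tab-separated phenotype table (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and len(df.columns) <= 1:
        warnings.warn(f"{path}: empty phenotype file", stacklevel=2)
        return []
    missing_cols = {"id", "sex", "compartment"} - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing required columns {sorted(missing_cols)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise FormatError(f"{path}: duplicate genotype id {dup!r}")
    records: list[GenotypeRecord] = []
    for _, row in df.iterrows():
        if pd.isna(row["sex"]):
            raise FormatError(f"{path}: genotype {row['id']!r} has no sex")
        try:
            sex = Sex(row["sex"])
        except ValueError:
            raise FormatError(
                f"{path}: genotype {row['id']!r} has unknown sex {row['sex']!r}"
            ) from None
        try:
            comp = Compartment(row["compartment"])
        except ValueError:
            raise FormatError(
                f"{path}: genotype {row['id']!r} has unknown compartment "
                f"{row['compartment']!r}"
            ) from None

        def opt(col: str) -> str | None:
            v = row.get(col)
            return None if v is None or pd.isna(v) else str(v)

        records.append(GenotypeRecord(
            id=str(row["id"]), sex=sex, compartment=comp,
            species=opt("species") or "V. vinifera",
            geography=opt("geography"), use=opt("use"),
            domestication_class=opt("domestication_class"),
            structure_group=opt("structure_group"),
        ))
    if not records:
        warnings.warn(f"{path}: empty phenotype file", stacklevel=2)
    return records


def write_phenotypes(path: str | Path, records: Sequence[GenotypeRecord]) -> None:
    rows = [{
        "id": r.id, "sex": r.sex.value, "compartment": r.compartment.value,
        "species": r.species, "geography": r.geography, "use": r.use,
        "domestication_class": r.domestication_class,
        "structure_group": r.structure_group,
    } for r in records]
    pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_kinship(path: str | Path, ids: Sequence[str]) -> KinshipMatrix:
    """Read a square CSV kinship matrix (id header row and column) and
    reorder it to the pipeline genotype order."""
    df = pd.read_csv(path, index_col=0)
    km = KinshipMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))
    return km.reorder(list(ids))


def read_structure(path: str | Path, ids: Sequence[str]) -> StructureMatrix:
    """Read a CSV ancestry matrix (id column + K ancestry columns)."""
    df = pd.read_csv(path, index_col=0)
    sm = StructureMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))
    return sm.reorder(list(ids))


def write_kinship(path: str | Path, km: KinshipMatrix) -> None:
    pd.DataFrame(km.values, index=km.ids, columns=km.ids).to_csv(path)


def write_structure(path: str | Path, sm: StructureMatrix) -> None:
    cols = [f"Q{k + 1}" for k in range(sm.k)]
    pd.DataFrame(sm.values, index=sm.ids, columns=cols).to_csv(path)


# ---------------------------------------------------------------------------
# site report TSV


def _call_to_str(pair: np.ndarray) -> str:
    if pair[0] == MISSING:
        return "./."
    return f"{ALLELES[pair[0]]}/{ALLELES[pair[1]]}"


def _call_from_str(s: str) -> tuple[int, int]:
    if s == "./.":
        return (MISSING, MISSING)
    a, b = s.split("/")
    return (ALLELES.index(a), ALLELES.index(b))


def write_site_matrix(path: str | Path, m: SiteMatrix,
                      provenance: dict | None = None) -> None:
    """Write a SiteMatrix as TSV: one row per site, one call column per
    genotype, with ``# key=value`` provenance header comments."""
    with open(path, "w") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}={v}\n")
        header = ["amplicon", "position", "kind", "major", "minor"] + m.genotype_ids
        fh.write("\t".join(header) + "\n")
        for j, site in enumerate(m.sites):
            row = [site.amplicon, str(site.position), site.kind.value,
                   *site.allele_labels]
            row += [_call_to_str(m.calls[i, j]) for i in range(m.n_genotypes)]
            fh.write("\t".join(row) + "\n")


def read_site_matrix(path: str | Path) -> SiteMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    gids = list(df.columns[5:])
    sites = [
        SiteMeta(
            amplicon=row["amplicon"], position=int(row["position"]),
            kind=SiteKind(row["kind"]),
            alleles=(ALLELES.index(row["major"]), ALLELES.index(row["minor"])),
        )
        for _, row in df.iterrows()
    ]
    calls = np.full((len(gids), len(sites), 2), MISSING, dtype=np.int8)
    for j in range(len(sites)):
        for i, g in enumerate(gids):
            calls[i, j] = _call_from_str(df.iloc[j][g])
    return SiteMatrix(gids, sites, calls)


def write_vcf(path: str | Path, m: SiteMatrix, chrom_of: dict[str, str]) -> None:
    """Minimal unphased VCF 4.2 export (GT only; indels as symbolic alleles)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(m.genotype_ids) + "\n")
        for j, site in enumerate(m.sites):
            maj, minr = site.allele_labels
            ref = maj if site.kind is SiteKind.SNP else "<INS>"
            alt = minr if site.kind is SiteKind.SNP else "<DEL>"
            gts = []
            for i in range(m.n_genotypes):
                pair = m.calls[i, j]
                if pair[0] == MISSING:
                    gts.append("./.")
                else:
                    gts.append("/".join(
                        "0" if a == site.alleles[0] else "1" for a in pair))
            fh.write(f"{chrom_of.get(site.amplicon, '.')}\t{site.position}\t"
                     f"{site.amplicon}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
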