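"""Core domain types shared by every pipeline stage.

The pipeline works on per-amplicon alignments of *diploid consensus*
sequences: one Sanger-style sequence per genotype, heterozygous positions
written as IUPAC ambiguity codes and alignment gaps as ``-``.  Calls are
stored as unordered diploid allele pairs over the six-letter alphabet
``A, C, G, T, ins, del``; a missing call is represented by ``(-1, -1)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# allele coding

#: ordered allele alphabet; integer codes index into this tuple
ALLELES: tuple[str, ...] = ("A", "C", "G", "T", "ins", "del")
A, C, G, T, INS, DEL = range(6)
MISSING: int = -1

_BASE_CODE = {"A": A, "C": C, "G": G, "T": T}

#: IUPAC ambiguity code -> unordered pair of base codes (sorted)
IUPAC_TO_PAIR: dict[str, tuple[int, int]] = {
    "A": (A, A), "C": (C, C), "G": (G, G), "T": (T, T),
    "R": (A, G), "Y": (C, T), "S": (C, G), "W": (A, T),
    "K": (G, T), "M": (A, C),
}
PAIR_TO_IUPAC: dict[tuple[int, int], str] = {v: k for k, v in IUPAC_TO_PAIR.items()}

#: characters legal in an aligned diploid consensus FASTA record
VALID_FASTA_CHARS = set("ACGTRYSWKMN-") | set("acgtn")


def decode_iupac(char: str) -> tuple[int, int]:
    """Decode one consensus character to an unordered base-pair call.

    ``N`` (either case) decodes to missing.  Gap and lowercase characters
    carry indel information and are handled at site-extraction time, not
    here; passing them raises ``ValueError``.
    """
    up = char.upper()
    if up == "N":
        return (MISSING, MISSING)
    try:
        return IUPAC_TO_PAIR[up]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {char!r}") from None


def encode_iupac(pair: tuple[int, int]) -> str:
    """Encode an unordered pair of base codes back to one IUPAC character."""
    key = tuple(sorted(pair))
    if key == (MISSING, MISSING):
        return "N"
    try:
        return PAIR_TO_IUPAC[key]  # type: ignore[index]
    except KeyError:
        raise ValueError(f"cannot encode allele pair {pair!r} as IUPAC") from None


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    HERMAPHRODITE = "hermaphrodite"


class Compartment(str, enum.Enum):
    WILD = "wild"
    DOMESTICATED = "domesticated"
    OUTGROUP = "outgroup"


class SiteKind(str, enum.Enum):
    SNP = "SNP"
    INDEL = "indel"


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class AmpliconDef:
    """One PCR amplicon: name, chromosome placement and aligned length."""

    name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    aligned_length: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start {self.start} > end {self.end}")
        if self.aligned_length <= 0:
            raise ValueError(f"{self.name}: aligned_length must be positive")

    @property
    def span_bp(self) -> int:
        """Genomic footprint, 1-based inclusive: end - start + 1."""
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenotypeRecord:
    id: str
    sex: Sex
    compartment: Compartment
    species: str = "V. vinifera"
    geography: str | None = None
    use: str | None = None
    domestication_class: str | None = None
    structure_group: str | None = None

    def __post_init__(self) -> None:
        if self.compartment is Compartment.OUTGROUP and self.species == "V. vinifera":
            raise ValueError(
                f"{self.id}: outgroup records must carry a non-V. vinifera species"
            )


@dataclass(frozen=True)
class SiteMeta:
    """Metadata for one polymorphic site (column of the SiteMatrix)."""

    amplicon: str
    position: int          # 1-based bp on the chromosome
    kind: SiteKind
    alleles: tuple[int, int]  # (major, minor) allele codes
    multiallelic: bool = False

    @property
    def allele_labels(self) -> tuple[str, str]:
        return ALLELES[self.alleles[0]], ALLELES[self.alleles[1]]


class SiteMatrix:
    """Genotypes x polymorphic sites matrix of unordered diploid calls.

    ``calls`` has shape ``(n_genotypes, n_sites, 2)`` (int8), each pair
    sorted ascending; missing calls are ``(-1, -1)``.
    """

    def __init__(self, genotype_ids: Sequence[str], sites: Sequence[SiteMeta],
                 calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(genotype_ids), len(sites), 2):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(genotype_ids)} genotypes x {len(sites)} sites"
            )
        if len(set(genotype_ids)) != len(genotype_ids):
            raise ValueError("duplicate genotype ids")
        self.genotype_ids = list(genotype_ids)
        self.sites = list(sites)
        self.calls = np.sort(calls, axis=2)  # unordered pairs: canonical order
        # missing is (-1,-1); sorting keeps that invariant
        self._index = {g: i for i, g in enumerate(self.genotype_ids)}

    # -- basic introspection -------------------------------------------------
    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def genotype_index(self, gid: str) -> int:
        return self._index[gid]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_genotypes, n_sites): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing calls."""
        return self.missing_mask().mean(axis=0)

    def allele_counts(self, j: int) -> dict[int, int]:
        """Diploid allele counts at site ``j`` (heterozygote adds 1 to each)."""
        col = self.calls[:, j, :]
        col = col[col[:, 0] != MISSING]
        vals, cnt = np.unique(col.ravel(), return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))

    def minor_allele_frequency(self, j: int) -> float:
        counts = self.allele_counts(j)
        total = sum(counts.values())
        if total == 0 or len(counts) < 2:
            return 0.0
        return min(counts.values()) / total

    def subset_genotypes(self, ids: Iterable[str]) -> "SiteMatrix":
        idx = [self._index[g] for g in ids]
        return SiteMatrix([self.genotype_ids[i] for i in idx], self.sites,
                          self.calls[idx])

    def subset_sites(self, keep: Sequence[int]) -> "SiteMatrix":
        keep = list(keep)
        return SiteMatrix(self.genotype_ids, [self.sites[j] for j in keep],
                          self.calls[:, keep, :])

    def __repr__(self) -> str:  # pragma: no cover
        return f"SiteMatrix({self.n_genotypes} genotypes x {self.n_sites} sites)"


@dataclass
class KinshipMatrix:
    """Pairwise relatedness, symmetric, entries in [0, 1]; consumed, never computed."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix is not symmetric (tolerance 1e-8)")
        if (self.values < 0).any():
            raise ValueError("kinship entries must be non-negative")

    def reorder(self, ids: Sequence[str]) -> "KinshipMatrix":
        pos = {g: i for i, g in enumerate(self.ids)}
        try:
            idx = [pos[g] for g in ids]
        except KeyError as e:
            raise KeyError(f"genotype {e.args[0]!r} absent from kinship matrix") from None
        return KinshipMatrix(list(ids), self.values[np.ix_(idx, idx)])


@dataclass
class StructureMatrix:
    """Genotypes x K ancestry proportions; rows sum to 1."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.ids):
            raise ValueError("structure matrix shape does not match ids")
        rowsum = self.values.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-6):
            bad = np.argmax(np.abs(rowsum - 1.0))
            raise ValueError(
                f"structure row for {self.ids[bad]!r} sums to {rowsum[bad]:.6f}, not 1"
            )

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def reorder(self, ids: Sequence[str]) -> "StructureMatrix":
        pos = {g: i for i, g in enumerate(self.ids)}
        try:
            idx = [pos[g] for g in ids]
        except KeyError as e:
            raise KeyError(f"genotype {e.args[0]!r} absent from structure matrix") from None
        return StructureMatrix(list(ids), self.values[idx])
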