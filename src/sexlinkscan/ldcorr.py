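"""Pairwise linkage disequilibrium corrected for kinship and structure.

On unphased diploid data, the baseline is composite LD: the squared
Pearson correlation of minor-allele dosages (r^2).  Family relatedness and
population structure both inflate r^2 between physically unlinked sites;
the corrected estimator (r^2_VS) removes them by generalized least
squares: both dosage vectors are whitened by the inverse Cholesky factor
of the kinship covariance and the (whitened) ancestry covariates are
projected out before correlating.  With identity kinship and a trivial
structure matrix r^2_VS reduces exactly to the classic r^2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .datamodel import MISSING, KinshipMatrix, SiteMatrix, StructureMatrix

log = logging.getLogger(__name__)


def dosage(calls: np.ndarray, minor: int) -> np.ndarray:
    """Minor-allele dosage (0/1/2) per genotype; NaN for missing calls.

    ``calls`` is (n, 2) unordered pairs; for indel sites the counted allele
    is whichever code is passed as ``minor``.
    """
    alleles = set(calls[calls[:, 0] != MISSING].ravel().tolist())
    if len(alleles) > 2:
        raise ValueError("multi-allelic site has no scalar dosage")
    out = np.full(calls.shape[0], np.nan)
    ok = calls[:, 0] != MISSING
    out[ok] = (calls[ok] == minor).sum(axis=1)
    return out


def site_dosages(m: SiteMatrix) -> np.ndarray:
    """Dosage matrix (n_genotypes, n_sites) with NaN for missing."""
    cols = []
    for j, site in enumerate(m.sites):
        cols.append(dosage(m.calls[:, j, :], site.alleles[1]))
    return np.column_stack(cols) if cols else np.empty((m.n_genotypes, 0))


def r2_classic(x: np.ndarray, y: np.ndarray) -> float | None:
    """Squared Pearson correlation of dosages over pairwise-complete
    genotypes; None if < 2 complete pairs or zero variance."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return None
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return None
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def _whitener(K: np.ndarray) -> np.ndarray:
    """Inverse Cholesky factor of the kinship covariance (with jitter on
    singularity)."""
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        warnings.warn("singular kinship matrix; adding 1e-6 diagonal jitter",
                      stacklevel=3)
        try:
            L = np.linalg.cholesky(K + 1e-6 * np.eye(K.shape[0]))
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "kinship matrix singular even after jitter") from None
    return np.linalg.inv(L)


def r2_vs(x: np.ndarray, y: np.ndarray, kinship: KinshipMatrix | np.ndarray,
          structure: StructureMatrix | np.ndarray | None = None) -> float | None:
    """Kinship- and structure-corrected squared correlation (r^2_VS).

    The kinship covariance is restricted to the pairwise-complete
    genotypes, both dosages are whitened by its inverse Cholesky factor,
    the whitened covariates (intercept + ancestry proportions with the
    last, collinear column dropped) are projected out, and the squared
    correlation of the residuals is returned.
    """
    K = kinship.values if isinstance(kinship, KinshipMatrix) else np.asarray(kinship)
    Q = None
    if structure is not None:
        Q = structure.values if isinstance(structure, StructureMatrix) \
            else np.asarray(structure)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3:
        return None
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return None
    Ksub = K[np.ix_(ok.nonzero()[0], ok.nonzero()[0])]
    # covariance of dosages under relatedness is proportional to K; make
    # sure the diagonal is positive
    if np.any(np.diag(Ksub) <= 0):
        Ksub = Ksub + 1e-6 * np.eye(Ksub.shape[0])
    W = _whitener(Ksub)
    xw, yw = W @ xs, W @ ys
    cov = [W @ np.ones(ok.sum())]
    if Q is not None and Q.shape[1] > 1:
        cov.append(W @ Q[ok][:, :-1])  # drop last ancestry column (collinear)
    C = np.column_stack(cov)
    # project out covariates
    beta_x, *_ = np.linalg.lstsq(C, xw, rcond=None)
    beta_y, *_ = np.linalg.lstsq(C, yw, rcond=None)
    rx, ry = xw - C @ beta_x, yw - C @ beta_y
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        return None
    r = float(rx @ ry / denom)
    return r * r


@dataclass
class LDMatrix:
    site_labels: list[str]
    amplicons: list[str]
    r2: np.ndarray           # (n_sites, n_sites), NaN where undefined
    n_used: np.ndarray       # pairwise-complete genotype counts
    flavor: str = "VS"

    def pair_table(self) -> list[tuple[str, str, float, int]]:
        rows = []
        n = len(self.site_labels)
        for i, j in combinations(range(n), 2):
            if not np.isnan(self.r2[i, j]):
                rows.append((self.site_labels[i], self.site_labels[j],
                             float(self.r2[i, j]), int(self.n_used[i, j])))
        return rows


@dataclass
class LDSummary:
    ld: LDMatrix
    amplicon_pair_means: dict[tuple[str, str], float] = field(default_factory=dict)
    dropped_sites: list[str] = field(default_factory=list)


def ld_summary(m: SiteMatrix, kinship: KinshipMatrix | None = None,
               structure: StructureMatrix | None = None,
               min_maf: float = 0.2, max_missing: float = 0.2) -> LDSummary:
    """All pairwise r^2_VS among sites passing the LD-stage filters,
    plus mean r^2_VS within and between amplicons.

    The LD stage has its own, stricter frequency filter (default minor
    allele frequency 0.2) computed on the analysed subset; excluded sites
    are logged.  With no kinship/structure supplied, identity kinship and
    a trivial structure matrix are used (r^2_VS then equals classic r^2).
    """
    keep, dropped = [], []
    miss = m.missing_fraction()
    for j, site in enumerate(m.sites):
        label = f"{site.amplicon}:{site.position}"
        if getattr(site, "multiallelic", False):
            dropped.append(label)
            continue
        if not (miss[j] < max_missing and m.minor_allele_frequency(j) > min_maf):
            dropped.append(label)
            log.info("LD: site %s excluded by filters", label)
            continue
        keep.append(j)
    if len(keep) < 2:
        raise ValueError("fewer than 2 sites pass the LD filters")
    sub = m.subset_sites(keep)
    D = site_dosages(sub)
    K = kinship.values if kinship is not None else np.eye(m.n_genotypes)
    Q = structure
    n_sites = sub.n_sites
    r2 = np.full((n_sites, n_sites), np.nan)
    n_used = np.zeros((n_sites, n_sites), dtype=int)
    np.fill_diagonal(r2, 1.0)
    for i, j in combinations(range(n_sites), 2):
        val = r2_vs(D[:, i], D[:, j], K, Q)
        ok = int((~np.isnan(D[:, i]) & ~np.isnan(D[:, j])).sum())
        if val is not None:
            r2[i, j] = r2[j, i] = val
        n_used[i, j] = n_used[j, i] = ok
    labels = [f"{s.amplicon}:{s.position}" for s in sub.sites]
    amps = [s.amplicon for s in sub.sites]
    ld = LDMatrix(site_labels=labels, amplicons=amps, r2=r2, n_used=n_used)

    means: dict[tuple[str, str], float] = {}
    amp_names = sorted(set(amps))
    for a, b in combinations(amp_names, 2):
        vals = [r2[i, j] for i in range(n_sites) for j in range(n_sites)
                if i < j and {amps[i], amps[j]} == {a, b}
                and not np.isnan(r2[i, j])]
        if vals:
            means[(a, b)] = float(np.mean(vals))
    for a in amp_names:
        vals = [r2[i, j] for i, j in combinations(range(n_sites), 2)
                if amps[i] == amps[j] == a and not np.isnan(r2[i, j])]
        if vals:
            means[(a, a)] = float(np.mean(vals))
    return LDSummary(ld=ld, amplicon_pair_means=means, dropped_sites=dropped)
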