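"""Per-sex Hardy-Weinberg deviation scan and XY-model classification.

Under male heterogamety the sex-determining region behaves like a fixed
heterozygote in males (XY) and a fixed homozygote in females (XX).  The
scan tests, separately for wild males and wild females, whether the
observed homozygote/heterozygote split at each site deviates from the
Hardy-Weinberg expectation computed from the pooled (male + female) allele
frequencies, using a two-sided Fisher exact test with Bonferroni control.
Sites are then classified against the strict XY pattern (all males
heterozygous, all females homozygous for the major allele) or a relaxed
version tolerating one or two non-heterozygous males.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .datamodel import (
    MISSING,
    AmpliconDef,
    Compartment,
    GenotypeRecord,
    Sex,
    SiteMatrix,
    SiteMeta,
)

log = logging.getLogger(__name__)


class XYClass:
    PERFECT = "perfect"
    NEAR = "near"
    NONE = "none"


@dataclass
class SexTestResult:
    n_obs: int
    het_obs: int
    hom_obs: int
    het_exp: float          # expected heterozygote count (real)
    p_fisher: float | None
    significant: bool = False


@dataclass
class SexScanResult:
    site: SiteMeta
    male: SexTestResult | None
    female: SexTestResult | None
    xy_class: str = XYClass.NONE

    @property
    def significant_male(self) -> bool:
        return bool(self.male and self.male.significant)

    @property
    def significant_female(self) -> bool:
        return bool(self.female and self.female.significant)


def hwe_expected_proportions(p_major: float) -> tuple[float, float]:
    """Hardy-Weinberg heterozygote and homozygote proportions for a
    biallelic site with major-allele frequency ``p_major``."""
    if not 0.0 < p_major < 1.0:
        raise ValueError(f"monomorphic site: p_major = {p_major}")
    het = 2.0 * p_major * (1.0 - p_major)
    return het, 1.0 - het


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def fisher_hwe_test(het_obs: int, hom_obs: int, het_exp_prop: float) -> float | None:
    """Two-sided Fisher exact test of observed vs expected het/hom counts.

    The expected row is the observed sample size apportioned by the
    Hardy-Weinberg proportion, rounded half-up to integers so that the
    2x2 table is valid.  Returns ``None`` when no genotypes were observed.
    """
    n = het_obs + hom_obs
    if n == 0:
        return None
    het_e = _round_half_up(n * het_exp_prop)
    table = [[het_obs, hom_obs], [het_e, n - het_e]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def binomial_hwe_test(het_obs: int, hom_obs: int, het_exp_prop: float) -> float | None:
    """Exact binomial alternative: observed heterozygotes vs p = 2pq."""
    n = het_obs + hom_obs
    if n == 0:
        return None
    return float(stats.binomtest(het_obs, n, het_exp_prop).pvalue)


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> tuple[float, float]:
    """Bonferroni-adjusted p threshold and its -log10 (2 dp in summaries)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    p = alpha / n_tests
    return p, -math.log10(p)


def region_span_kb(start: int, end: int, decimals: int = 2) -> float:
    """Length in kb of the open interval between two bp coordinates."""
    return round((end - start) / 1000.0, decimals)


def classify_xy_fit(calls: np.ndarray, sexes: Sequence[Sex], major: int,
                    max_nonhet_males: int = 2) -> str:
    """Classify one site's fit to the XY model.

    ``calls`` is (n, 2) unordered diploid pairs; missing calls are excluded.
    *perfect*: every male heterozygous and every female homozygous for the
    major allele.  *near*: all females homozygous-major and 1..``max_nonhet_males``
    males not heterozygous.  Otherwise *none*.
    """
    male_idx = [i for i, s in enumerate(sexes)
                if s is Sex.MALE and calls[i, 0] != MISSING]
    female_idx = [i for i, s in enumerate(sexes)
                  if s is Sex.FEMALE and calls[i, 0] != MISSING]
    if not male_idx or not female_idx:
        warnings.warn("site has no non-missing calls for one sex", stacklevel=2)
        return XYClass.NONE
    females_ok = all(
        calls[i, 0] == calls[i, 1] == major for i in female_idx)
    if not females_ok:
        return XYClass.NONE
    nonhet_males = sum(1 for i in male_idx if calls[i, 0] == calls[i, 1])
    if nonhet_males == 0:
        return XYClass.PERFECT
    if 1 <= nonhet_males <= max_nonhet_males:
        return XYClass.NEAR
    return XYClass.NONE


@dataclass
class ScanSummary:
    n_sites: int
    alpha: float
    p_threshold: float
    neglog10_threshold: float
    n_significant_male: int
    n_significant_female: int
    perfect_by_amplicon: dict[str, int] = field(default_factory=dict)
    near_by_amplicon: dict[str, int] = field(default_factory=dict)


def scan_region(m: SiteMatrix, phenos: Sequence[GenotypeRecord],
                alpha: float = 0.05, max_nonhet_males: int = 2,
                use_binomial: bool = False) -> tuple[list[SexScanResult], ScanSummary]:
    """Run the per-sex Hardy-Weinberg scan over all sites of ``m``.

    Only wild males and wild females enter the tests; hermaphrodites and
    outgroups are excluded.  Expected proportions come from allele
    frequencies in the pooled wild male + female sample.
    """
    by_id = {r.id: r for r in phenos}
    wild_sex: list[Sex | None] = []
    for gid in m.genotype_ids:
        r = by_id.get(gid)
        if r is not None and r.compartment is Compartment.WILD and \
                r.sex in (Sex.MALE, Sex.FEMALE):
            wild_sex.append(r.sex)
        else:
            wild_sex.append(None)
    wild_idx = [i for i, s in enumerate(wild_sex) if s is not None]
    sexes_present = {wild_sex[i] for i in wild_idx}
    if Sex.MALE not in sexes_present or Sex.FEMALE not in sexes_present:
        raise ValueError("scan requires both wild males and wild females")

    test = binomial_hwe_test if use_binomial else fisher_hwe_test
    p_threshold, neglog = bonferroni_threshold(alpha, max(m.n_sites, 1))

    results: list[SexScanResult] = []
    for j in range(m.n_sites):
        site = m.sites[j]
        calls = m.calls[wild_idx, j, :]
        sexes = [wild_sex[i] for i in wild_idx]
        # pooled major-allele frequency over wild males + females
        present = calls[calls[:, 0] != MISSING]
        counts: dict[int, int] = {}
        for a in present.ravel().tolist():
            counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        if total == 0 or len(counts) < 2:
            results.append(SexScanResult(site=site, male=None, female=None))
            continue
        maj = site.alleles[0]
        p_major = counts.get(maj, 0) / total
        if not 0.0 < p_major < 1.0:
            results.append(SexScanResult(site=site, male=None, female=None))
            continue
        het_prop, _ = hwe_expected_proportions(p_major)

        per_sex: dict[Sex, SexTestResult | None] = {}
        for sex in (Sex.MALE, Sex.FEMALE):
            idx = [k for k, s in enumerate(sexes) if s is sex
                   and calls[k, 0] != MISSING]
            n = len(idx)
            if n == 0:
                per_sex[sex] = None
                continue
            het = sum(1 for k in idx if calls[k, 0] != calls[k, 1])
            hom = n - het
            p = test(het, hom, het_prop)
            res = SexTestResult(n_obs=n, het_obs=het, hom_obs=hom,
                                het_exp=n * het_prop, p_fisher=p)
            res.significant = p is not None and p < p_threshold
            per_sex[sex] = res

        xy = classify_xy_fit(calls, sexes, maj, max_nonhet_males)
        results.append(SexScanResult(site=site, male=per_sex[Sex.MALE],
                                     female=per_sex[Sex.FEMALE], xy_class=xy))

    perfect_by_amp: dict[str, int] = {}
    near_by_amp: dict[str, int] = {}
    for r in results:
        if r.xy_class == XYClass.PERFECT:
            perfect_by_amp[r.site.amplicon] = perfect_by_amp.get(r.site.amplicon, 0) + 1
        elif r.xy_class == XYClass.NEAR:
            near_by_amp[r.site.amplicon] = near_by_amp.get(r.site.amplicon, 0) + 1
    summary = ScanSummary(
        n_sites=m.n_sites, alpha=alpha, p_threshold=p_threshold,
        neglog10_threshold=round(neglog, 2),
        n_significant_male=sum(r.significant_male for r in results),
        n_significant_female=sum(r.significant_female for r in results),
        perfect_by_amplicon=perfect_by_amp, near_by_amplicon=near_by_amp,
    )
    return results, summary


def delimit_sex_region(results: Sequence[SexScanResult],
                       panel: Sequence[AmpliconDef]) -> tuple[int, int, int]:
    """Delimit the sex-determining region by external flanking amplicons.

    Qualifying amplicons carry at least one perfect-or-near site.  The
    region runs from the end of the last non-qualifying amplicon upstream
    of the first qualifying one to the start of the first non-qualifying
    amplicon downstream of the last (an open interval), so its length is
    ``end - start``.
    """
    qualifying = {r.site.amplicon for r in results
                  if r.xy_class in (XYClass.PERFECT, XYClass.NEAR)}
    if not qualifying:
        raise ValueError("no sex-linked region detected")
    ordered = sorted(panel, key=lambda a: a.start)
    q_idx = [i for i, a in enumerate(ordered) if a.name in qualifying]
    first_q, last_q = q_idx[0], q_idx[-1]
    if first_q == 0:
        warnings.warn("no upstream flanking amplicon; using the qualifying "
                      "amplicon's own start", stacklevel=2)
        start = ordered[first_q].start
    else:
        start = ordered[first_q - 1].end
    if last_q == len(ordered) - 1:
        warnings.warn("no downstream flanking amplicon; using the qualifying "
                      "amplicon's own end", stacklevel=2)
        end = ordered[last_q].end
    else:
        end = ordered[last_q + 1].start
    return start, end, end - start
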