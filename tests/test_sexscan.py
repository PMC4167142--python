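"""Per-sex Hardy-Weinberg scan, XY classification and region bounds."""

import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from sexlinkscan.datamodel import (
    A, T, MISSING, AmpliconDef, Compartment, GenotypeRecord, Sex, SiteKind,
    SiteMatrix, SiteMeta,
)
from sexlinkscan.sexscan import (
    XYClass,
    bonferroni_threshold,
    classify_xy_fit,
    delimit_sex_region,
    fisher_hwe_test,
    hwe_expected_proportions,
    region_span_kb,
    scan_region,
)


def test_hwe_expected_proportions():
    het, hom = hwe_expected_proportions(0.5)
    assert het == hom == pytest.approx(0.5)
    het, hom = hwe_expected_proportions(0.9)
    assert het == pytest.approx(0.18)
    assert hom == pytest.approx(0.82)
    for bad in (0.0, 1.0):
        with pytest.raises(ValueError):
            hwe_expected_proportions(bad)


def _fisher_two_sided_oracle(table):
    """Independent oracle: enumerate every 2x2 table with the observed
    margins; two-sided p sums hypergeometric probabilities not exceeding
    the observed table's."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = hypergeom.pmf(x, n, col1, row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


@pytest.mark.parametrize("het,hom,prop", [
    (10, 10, 0.5), (23, 2, 0.334), (0, 20, 0.0), (15, 5, 0.2),
    (3, 17, 0.5), (20, 0, 0.5), (7, 13, 0.45),
])
def test_fisher_hwe_test_matches_hypergeometric_enumeration(het, hom, prop):
    n = het + hom
    het_e = int(math.floor(n * prop + 0.5))
    p = fisher_hwe_test(het, hom, prop)
    oracle = _fisher_two_sided_oracle([[het, hom], [het_e, n - het_e]])
    assert p == pytest.approx(oracle, rel=1e-9)


def test_fisher_degenerate_cases():
    assert fisher_hwe_test(10, 10, 0.5) == pytest.approx(1.0)
    assert fisher_hwe_test(0, 20, 0.0) == pytest.approx(1.0)
    assert fisher_hwe_test(0, 0, 0.5) is None


def test_bonferroni_threshold():
    p, neglog = bonferroni_threshold(0.05, 146)
    assert round(neglog, 2) == 3.47
    assert bonferroni_threshold(0.05, 1)[0] == pytest.approx(0.05)
    assert bonferroni_threshold(0.05, 50)[0] == pytest.approx(0.001)
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


def _calls(pairs):
    arr = np.array(pairs, dtype=np.int8)
    return arr


def test_classify_xy_fit_classes():
    # 25 het males + 34 hom-major females: the strict XY pattern
    males = [(A, T)] * 25
    females = [(A, A)] * 34
    calls = _calls(males + females)
    sexes = [Sex.MALE] * 25 + [Sex.FEMALE] * 34
    assert classify_xy_fit(calls, sexes, major=A) == XYClass.PERFECT

    # one or two non-heterozygous males -> near
    males = [(A, T)] * 23 + [(A, A), (T, T)]
    calls = _calls(males + females)
    assert classify_xy_fit(calls, sexes, major=A) == XYClass.NEAR

    # any heterozygous female -> none
    calls = _calls([(A, T)] * 25 + [(A, T)] + [(A, A)] * 33)
    assert classify_xy_fit(calls, sexes, major=A) == XYClass.NONE

    # three non-het males exceed the default allowance
    males = [(A, T)] * 22 + [(A, A)] * 3
    calls = _calls(males + [(A, A)] * 34)
    assert classify_xy_fit(calls, sexes, major=A) == XYClass.NONE


def test_classify_xy_fit_ignores_missing_and_warns_on_empty_sex():
    calls = _calls([(A, T), (MISSING, MISSING), (A, A)])
    sexes = [Sex.MALE, Sex.MALE, Sex.FEMALE]
    assert classify_xy_fit(calls, sexes, major=A) == XYClass.PERFECT
    with pytest.warns(UserWarning):
        out = classify_xy_fit(_calls([(A, T)]), [Sex.MALE], major=A)
    assert out == XYClass.NONE


def _single_site_matrix(male_calls, female_calls):
    sites = [SiteMeta("ampA", 101, SiteKind.SNP, (A, T))]
    ids = [f"m{i}" for i in range(len(male_calls))] + \
          [f"f{i}" for i in range(len(female_calls))]
    calls = np.array([[c] for c in male_calls + female_calls], dtype=np.int8)
    phenos = [GenotypeRecord(f"m{i}", Sex.MALE, Compartment.WILD)
              for i in range(len(male_calls))] + \
             [GenotypeRecord(f"f{i}", Sex.FEMALE, Compartment.WILD)
              for i in range(len(female_calls))]
    return SiteMatrix(ids, sites, calls), phenos


def test_scan_region_flags_sex_linked_site():
    m, phenos = _single_site_matrix([(A, T)] * 20, [(A, A)] * 20)
    results, summary = scan_region(m, phenos)
    assert results[0].xy_class == XYClass.PERFECT
    assert results[0].male.p_fisher < 1e-4
    assert summary.perfect_by_amplicon == {"ampA": 1}


def test_scan_region_requires_both_sexes():
    m, phenos = _single_site_matrix([], [(A, A)] * 10 + [(A, T)] * 10)
    with pytest.raises(ValueError, match="wild males and wild females"):
        scan_region(m, phenos)


def test_neutral_sites_rarely_significant_after_bonferroni(rng):
    """Under random mating the Bonferroni-controlled scan keeps the
    family-wise false-positive count near alpha."""
    n_sites, n_per_sex = 250, 30
    sites = [SiteMeta("ampA", 100 + j, SiteKind.SNP, (A, T))
             for j in range(n_sites)]
    ids = [f"m{i}" for i in range(n_per_sex)] + \
          [f"f{i}" for i in range(n_per_sex)]
    phenos = [GenotypeRecord(g, Sex.MALE if g[0] == "m" else Sex.FEMALE,
                             Compartment.WILD) for g in ids]
    calls = np.empty((2 * n_per_sex, n_sites, 2), dtype=np.int8)
    for j in range(n_sites):
        p = rng.uniform(0.2, 0.8)
        alleles = rng.choice([A, T], p=[p, 1 - p],
                             size=(2 * n_per_sex, 2)).astype(np.int8)
        calls[:, j, :] = np.sort(alleles, axis=1)
    m = SiteMatrix(ids, sites, calls)
    _, summary = scan_region(m, phenos)
    n_sig = summary.n_significant_male + summary.n_significant_female
    assert n_sig <= 3  # expected count at alpha 0.05 is ~0.1 across sexes


def test_permuting_sex_labels_destroys_perfect_classification(rng):
    male_calls = [(A, T)] * 20
    female_calls = [(A, A)] * 20
    calls = _calls(male_calls + female_calls)
    survived = 0
    for _ in range(200):
        perm = rng.permutation(40)
        sexes = [(Sex.MALE if k < 20 else Sex.FEMALE) for k in perm]
        if classify_xy_fit(calls, sexes, major=A) == XYClass.PERFECT:
            survived += 1
    assert survived == 0


PANEL = [
    AmpliconDef("up", "chr2", 4883461, 4884818, 1358),
    AmpliconDef("q1", "chr2", 4900275, 4901493, 1219),
    AmpliconDef("q2", "chr2", 5009549, 5010222, 673),
    AmpliconDef("down", "chr2", 5036645, 5037597, 953),
]


class _FakeResult:
    def __init__(self, amp, xy):
        self.site = SiteMeta(amp, 0, SiteKind.SNP, (A, T))
        self.xy_class = xy


def test_delimit_sex_region_external_flanks():
    results = [_FakeResult("q1", XYClass.PERFECT),
               _FakeResult("q2", XYClass.NEAR),
               _FakeResult("up", XYClass.NONE)]
    start, end, length = delimit_sex_region(results, PANEL)
    assert (start, end) == (4884818, 5036645)
    assert length == 151827
    assert region_span_kb(start, end) == 151.83


def test_delimit_single_amplicon_and_missing_flank():
    panel = [AmpliconDef("a", "c", 50, 100, 51),
             AmpliconDef("b", "c", 150, 250, 101),
             AmpliconDef("c", "c", 300, 400, 101)]
    start, end, length = delimit_sex_region(
        [_FakeResult("b", XYClass.PERFECT)], panel)
    assert (start, end, length) == (100, 300, 200)
    with pytest.warns(UserWarning, match="flanking"):
        start, end, _ = delimit_sex_region(
            [_FakeResult("a", XYClass.PERFECT)], panel)
    assert start == 50

    with pytest.raises(ValueError, match="no sex-linked region"):
        delimit_sex_region([_FakeResult("a", XYClass.NONE)], panel)
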