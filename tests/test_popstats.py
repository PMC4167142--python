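"""Diversity, neutrality and differentiation statistics."""

import numpy as np
import pytest

from sexlinkscan import popstats
from sexlinkscan.popstats import (
    dh_null_sample,
    dh_orthant_p,
    dh_test,
    diversity,
    fuli_dstar,
    hudson_fst,
    mean_pairwise_differences,
    polarized_sfs,
    tajimas_d,
    tajima_d_pvalue,
    zeng_e_and_h,
)


def _haps_from_counts(counts, singleton_sites, L):
    """Haplotype strings: one common background plus rare haplotypes each
    carrying private singleton substitutions."""
    background = "A" * L
    haps = [background] * counts[0]
    pos = 0
    for c, k in zip(counts[1:], singleton_sites):
        hap = list(background)
        for _ in range(k):
            hap[pos] = "T"
            pos += 1
        haps.extend(["".join(hap)] * c)
    return haps


class TestDiversity:
    def test_two_haplotypes_single_singleton_site(self):
        haps = _haps_from_counts([21, 1], [1], L=849)
        d = diversity(haps, 849)
        assert (d.n, d.S, d.Nh) == (22, 1, 2)
        assert round(d.H, 2) == 0.09
        assert round(d.pi, 5) == 0.00011

    def test_three_haplotypes_five_private_singletons(self):
        haps = _haps_from_counts([20, 1, 1], [2, 3], L=1111)
        d = diversity(haps, 1111)
        assert (d.n, d.S, d.Nh) == (22, 5, 3)
        assert round(d.H, 2) == 0.18
        assert round(d.pi, 5) == 0.00041
        assert d.pi_locus == pytest.approx(105 / 231)

    def test_identical_haplotypes(self):
        d = diversity(["ACGT"] * 5, 4)
        assert (d.S, d.Nh, d.H, d.pi) == (0, 1, 0.0, 0.0)

    def test_pi_against_column_frequency_oracle(self, rng):
        """Mean pairwise distance equals the column-wise heterozygosity sum
        sum_j c_j (n - c_j) / C(n,2) — an independent computation path."""
        for _ in range(10):
            n, L = int(rng.integers(4, 30)), 12
            mat = rng.integers(0, 2, size=(n, L))
            haps = ["".join("AT"[b] for b in row) for row in mat]
            c = mat.sum(axis=0)
            oracle = float((c * (n - c)).sum()) / (n * (n - 1) / 2)
            assert mean_pairwise_differences(haps) == pytest.approx(oracle)

    def test_h_invariant_to_relabeling(self, rng):
        haps = _haps_from_counts([10, 5, 2], [1, 2], L=30)
        d1 = diversity(haps, 30)
        relabeled = ["".join("CA"[ch == "A"] for ch in h) for h in haps]
        d2 = diversity(relabeled, 30)
        assert d1.H == pytest.approx(d2.H)
        assert d1.pi == pytest.approx(d2.pi)

    def test_errors(self):
        with pytest.raises(ValueError):
            diversity(["A"], 1)
        with pytest.raises(ValueError):
            diversity(["AA", "A"], 2)


class TestTajimaD:
    def test_single_singleton_n22(self):
        assert round(tajimas_d(22, 1, 21 / 231), 2) == -1.16

    def test_five_singletons_n22(self):
        assert round(tajimas_d(22, 5, 105 / 231), 2) == -1.99

    def test_zero_when_pi_equals_watterson(self):
        a1 = sum(1 / i for i in range(1, 22))
        assert tajimas_d(22, 5, 5 / a1) == pytest.approx(0.0, abs=1e-12)

    def test_s_zero_undefined(self):
        assert tajimas_d(22, 0, 0.0) is None

    def test_beta_approximation_pvalue_orientation(self):
        assert tajima_d_pvalue(22, 0.0) > 0.5
        assert tajima_d_pvalue(22, -2.2) < 0.05


class TestFuLiDStar:
    def test_single_singleton_n22(self):
        assert round(fuli_dstar(22, 1, 1), 2) == -1.57

    def test_five_singletons_n22(self):
        assert round(fuli_dstar(22, 5, 5), 2) == -2.91

    def test_more_singletons_more_negative(self):
        vals = [fuli_dstar(22, 6, k) for k in range(7)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_eta_zero_undefined(self):
        assert fuli_dstar(22, 0, 0) is None


class TestPolarizedSFS:
    def test_outgroup_major_makes_minor_derived(self):
        haps = ["AA"] * 9 + ["AT"]
        xi, excluded = polarized_sfs(haps, "AA")
        assert xi[1] == 1 and xi.sum() == 1 and excluded == 0

    def test_outgroup_minor_makes_major_derived(self):
        haps = ["AA"] * 9 + ["AT"]
        xi, _ = polarized_sfs(haps, "AT")
        assert xi[9] == 1

    def test_third_state_excluded(self):
        haps = ["AA"] * 9 + ["AT"]
        xi, excluded = polarized_sfs(haps, "AG")
        assert xi.sum() == 0 and excluded == 1


class TestZengEH:
    def test_all_singletons_closed_form(self):
        n, S = 22, 5
        xi = np.zeros(n, dtype=np.int64)
        xi[1] = S
        theta_l, h_norm, e = zeng_e_and_h(n, xi, S)
        assert theta_l == pytest.approx(S / (n - 1))
        assert e < 0
        assert h_norm > 0  # rare-variant excess: pi exceeds theta_L

    def test_single_singleton_value(self):
        xi = np.zeros(22, dtype=np.int64)
        xi[1] = 1
        _, _, e = zeng_e_and_h(22, xi, 1)
        assert round(e, 2) == -0.87

    def test_neutral_mean_near_zero(self):
        rng = np.random.default_rng(5)
        from sexlinkscan.coalsim import simulate_fixed_s
        es = []
        for _ in range(2000):
            mat = simulate_fixed_s(20, 10, rng)
            xi = np.bincount(mat.sum(axis=0), minlength=20)[:20]
            _, _, e = zeng_e_and_h(20, xi, 10)
            es.append(e)
        # like Tajima's D, the normalized statistic is slightly negatively
        # biased under fixed-S conditioning
        assert -0.2 < np.mean(es) < 0.1


class TestDHTest:
    def test_infinite_observed_gives_p_one(self):
        assert dh_test(20, 5, np.inf, np.inf, reps=1000, seed=0) == 1.0

    def test_sweep_like_configuration_rejects(self):
        # joint excess of singletons and of high-frequency derived variants
        n, S = 20, 12
        xi = np.zeros(n, dtype=np.int64)
        xi[1] = 6
        xi[n - 1] = 6
        pi = float(sum(2 * i * (n - i) * xi[i] for i in range(1, n))) \
            / (n * (n - 1))
        d = tajimas_d(n, S, pi)
        _, h, _ = zeng_e_and_h(n, xi, S)
        assert dh_test(n, S, d, h, reps=2000, seed=1) < 0.05

    def test_low_reps_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            dh_test(10, 2, 0.0, 0.0, reps=500, seed=0)

    def test_null_calibrated_threshold_controls_size(self):
        null = dh_null_sample(12, 6, 800, seed=7)
        obs = dh_null_sample(12, 6, 400, seed=8)
        thr = np.quantile([dh_orthant_p(null, d, h) for d, h in null], 0.05)
        rate = np.mean([dh_orthant_p(null, d, h) <= thr for d, h in obs])
        assert 0.01 <= rate <= 0.10


class TestHudsonFst:
    def test_fixed_difference_gives_one(self):
        assert hudson_fst(["AAA", "AAA"], ["TTT", "TTT"]) == pytest.approx(1.0)

    def test_identical_pools_negative_no_clamping(self):
        assert hudson_fst(["A", "T"], ["A", "T"]) == pytest.approx(-1.0)

    def test_zero_between_diversity_undefined(self):
        assert hudson_fst(["AA", "AA"], ["AA", "AA"]) is None

    def test_divergent_pools_high_fst(self, default_dataset):
        ds = default_dataset
        amp = "AMP1"
        fpool, mpool = [], []
        for gid, g in ds.truth["genotypes"].items():
            for hap, lab in zip(g["haplotypes"][amp], g["labels"][amp]):
                if lab == "F" and g["sex"] == "female":
                    fpool.append(hap)
                elif lab == "M":
                    mpool.append(hap)
        assert hudson_fst(mpool, fpool) > 0.8
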