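"""Diversity, neutrality and differentiation statistics per haplogroup.

All statistics operate on lists of equal-length haplotype strings (one
character per segregating site, or full-length sequences).  Diversity:
segregating sites S, distinct haplotypes Nh, haplotype diversity H with
the n/(n-1) small-sample correction, and per-site nucleotide diversity pi.
Neutrality: Tajima's D, Fu & Li's D* (no-outgroup, singleton-based),
Zeng's theta_L, the normalized Fay & Wu H and Zeng's E (both requiring an
outgroup-polarized site-frequency spectrum), and the joint D/H ("DH")
test whose null distribution comes from fixed-S coalescent simulation.
Differentiation: Hudson's Fst in the 1 - Hw/Hb form.

A mutation-count excess of rare variants (negative D and D*) is the
classic footprint of purifying/background selection or a recent sweep on
a non-recombining haplotype, which is what these statistics are used to
detect on the male (Y-like) haplogroup.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from . import coalsim

MISSING_CHARS = {"N", "n", "?"}


# ---------------------------------------------------------------------------
# helper constants


def _a1(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def _a2(n: int) -> float:
    return sum(1.0 / i**2 for i in range(1, n))


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b)
               if x != y and x not in MISSING_CHARS and y not in MISSING_CHARS)


def mean_pairwise_differences(haps: Sequence[str]) -> float:
    """Mean Hamming distance over all C(n,2) haplotype pairs (per locus)."""
    n = len(haps)
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    total = sum(_hamming(a, b) for a, b in combinations(haps, 2))
    return total / (n * (n - 1) / 2)


def segregating_columns(haps: Sequence[str]) -> list[int]:
    """Indices of columns with >= 2 distinct non-missing states."""
    L = len(haps[0])
    out = []
    for j in range(L):
        states = {h[j] for h in haps} - MISSING_CHARS
        if len(states) >= 2:
            out.append(j)
    return out


# ---------------------------------------------------------------------------
# diversity


@dataclass
class DiversityStats:
    n: int
    L: int
    S: int
    Nh: int
    H: float
    pi: float        # per site
    theta_w: float   # per site
    pi_locus: float  # mean pairwise differences per locus

    def rounded(self) -> dict:
        """Report-scale rounding: H to 2 dp, pi to 5 dp."""
        return {"n": self.n, "S": self.S, "Nh": self.Nh,
                "H": round(self.H, 2), "pi": round(self.pi, 5)}


def diversity(haps: Sequence[str], L: int) -> DiversityStats:
    """Diversity statistics for a haplogroup of ``n`` haplotypes over ``L`` bp."""
    n = len(haps)
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    if len({len(h) for h in haps}) != 1:
        raise ValueError("haplotypes differ in length")
    seg = segregating_columns(haps)
    S = len(seg)
    counts: dict[str, int] = {}
    for h in haps:
        counts[h] = counts.get(h, 0) + 1
    Nh = len(counts)
    freqs = np.array(list(counts.values())) / n
    H = (n / (n - 1)) * (1.0 - float((freqs**2).sum()))
    pi_locus = mean_pairwise_differences(haps)
    theta_w = S / _a1(n) / L if n >= 2 else 0.0
    return DiversityStats(n=n, L=L, S=S, Nh=Nh, H=H, pi=pi_locus / L,
                          theta_w=theta_w, pi_locus=pi_locus)


# ---------------------------------------------------------------------------
# neutrality


def tajimas_d(n: int, S: int, pi_locus: float) -> float | None:
    """Tajima's D from sample size, segregating sites and mean pairwise
    differences (per locus)."""
    if n < 4:
        raise ValueError("need n >= 4")
    if S == 0:
        return None
    a1, a2 = _a1(n), _a2(n)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return None
    return (pi_locus - S / a1) / math.sqrt(var)


def tajima_d_pvalue(n: int, d: float) -> float:
    """Two-sided p-value for Tajima's D under the beta approximation of the
    original test (D rescaled to its [Dmin, Dmax] support, mean 0, var 1)."""
    a1, a2 = _a1(n), _a2(n)
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e2 = c2 / (a1**2 + a2)
    dmin = (2.0 / n - 1.0 / a1) / math.sqrt(e2)
    dmax = ((n + 1) / (2.0 * n) - 1.0 / a1) / math.sqrt(e2)
    a, b = dmin, dmax
    alpha = -(1 + a * b) * b / (b - a)
    beta = (1 + a * b) * a / (b - a)
    x = (d - a) / (b - a)
    x = min(max(x, 0.0), 1.0)
    cdf = stats.beta.cdf(x, beta, alpha)
    return float(2 * min(cdf, 1 - cdf))


def fuli_dstar(n: int, eta: int, eta_s: int) -> float | None:
    """Fu & Li's D* (no outgroup): total mutations ``eta`` against
    singletons ``eta_s``.

    Constants follow the DnaSP convention of the 1993 test (the bracketed
    ``d_n`` term uses ``a_n`` rather than ``a_{n+1}``), which reproduces
    published worked values to 2 dp.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if eta == 0:
        return None
    an, bn = _a1(n), _a2(n)
    cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = cn + (n - 2) / (n - 1)**2 + (2 / (n - 1)) * (
        1.5 - (2 * an - 3) / (n - 2) - 1.0 / n)
    vd = ((n / (n - 1))**2 * bn + an**2 * dn
          - 2 * (n * an * (an + 1)) / (n - 1)**2) / (an**2 + bn)
    ud = (n / (n - 1)) * (an - n / (n - 1)) - vd
    var = ud * eta + vd * eta**2
    if var <= 0:
        return None
    return ((n / (n - 1)) * eta - an * eta_s) / math.sqrt(var)


def polarized_sfs(haps: Sequence[str], outgroup_hap: str) -> tuple[np.ndarray, int]:
    """Unfolded site-frequency spectrum using an outgroup haplotype.

    At each segregating column the outgroup allele is taken as ancestral;
    columns where the outgroup is missing or carries a third state are
    excluded.  Returns ``(xi, n_excluded)`` with ``xi[i]`` the number of
    sites at derived count ``i`` (index 0 unused, length n).
    """
    n = len(haps)
    seg = segregating_columns(haps)
    xi = np.zeros(n, dtype=np.int64)
    excluded = 0
    for j in seg:
        states = {h[j] for h in haps} - MISSING_CHARS
        anc = outgroup_hap[j]
        if anc in MISSING_CHARS or anc not in states:
            excluded += 1
            continue
        derived = sum(1 for h in haps
                      if h[j] not in MISSING_CHARS and h[j] != anc)
        if 0 < derived < n:
            xi[derived] += 1
    if xi.sum() == 0:
        warnings.warn("outgroup polarization left no usable sites", stacklevel=2)
    return xi, excluded


def _theta_estimates(n: int, S: int) -> tuple[float, float]:
    an, bn = _a1(n), _a2(n)
    return S / an, S * (S - 1) / (an**2 + bn)


def zeng_e_and_h(n: int, xi: np.ndarray, S: int
                 ) -> tuple[float | None, float | None, float | None]:
    """theta_L, normalized Fay & Wu H and Zeng's E from a polarized SFS.

    Variances follow the closed forms of the cited joint test, with
    unbiased plug-ins ``theta = S/a_n`` and ``theta^2 = S(S-1)/(a_n^2+b_n)``.
    """
    if S == 0 or xi.sum() == 0:
        return None, None, None
    an, bn = _a1(n), _a2(n)
    bn1 = bn + 1.0 / n**2
    theta_l = float(sum(i * xi[i] for i in range(1, n))) / (n - 1)
    pi = float(sum(2 * i * (n - i) * xi[i] for i in range(1, n))) / (n * (n - 1))
    theta_w = S / an
    th, th2 = _theta_estimates(n, S)
    var_h = ((n - 2) / (6.0 * (n - 1)) * th
             + (18 * n**2 * (3 * n + 2) * bn1
                - (88 * n**3 + 9 * n**2 - 13 * n + 6))
             / (9.0 * n * (n - 1)**2) * th2)
    var_e = ((n / (2.0 * (n - 1)) - 1.0 / an) * th
             + (bn / an**2 + 2 * (n / (n - 1))**2 * bn
                - 2 * (n * bn - n + 1) / ((n - 1) * an)
                - (3 * n + 1) / (n - 1)) * th2)
    h_norm = (pi - theta_l) / math.sqrt(var_h) if var_h > 0 else None
    e = (theta_l - theta_w) / math.sqrt(var_e) if var_e > 0 else None
    return theta_l, h_norm, e


def _sim_d_h(n: int, S: int, rng: np.random.Generator) -> tuple[float, float]:
    """One fixed-S neutral replicate's (Tajima D, normalized Fay & Wu H)."""
    mat = coalsim.simulate_fixed_s(n, S, rng)
    derived = mat.sum(axis=0)
    xi = np.zeros(n, dtype=np.int64)
    for d in derived:
        if 0 < d < n:
            xi[d] += 1
    pi = float(sum(2 * i * (n - i) * xi[i] for i in range(1, n))) / (n * (n - 1))
    d_stat = tajimas_d(n, S, pi)
    _, h_norm, _ = zeng_e_and_h(n, xi, S)
    return (d_stat if d_stat is not None else 0.0,
            h_norm if h_norm is not None else 0.0)


def dh_test(n: int, S: int, d_obs: float, h_obs: float,
            reps: int = 10000, seed: int | np.random.Generator = 0) -> float:
    """Joint D/H test p-value from the fixed-S coalescent null.

    p is the proportion of neutral replicates with ``D <= d_obs`` and
    ``H <= h_obs`` simultaneously (one-tailed joint rejection region aimed
    at the sweep-like corner: both statistics negative).
    """
    if S < 1:
        raise ValueError("need S >= 1")
    if reps < 1000:
        warnings.warn("dh_test with < 1000 replicates is unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        d_sim, h_sim = _sim_d_h(n, S, rng)
        if d_sim <= d_obs and h_sim <= h_obs:
            hits += 1
    return hits / reps


def dh_null_sample(n: int, S: int, reps: int,
                   seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``reps`` (D, H) statistic pairs from the fixed-S neutral null."""
    rng = np.random.default_rng(seed)
    out = np.empty((reps, 2))
    for r in range(reps):
        out[r] = _sim_d_h(n, S, rng)
    return out


def dh_orthant_p(null_dh: np.ndarray, d_obs: float, h_obs: float) -> float:
    """Orthant p: fraction of null (D, H) pairs jointly <= the observed."""
    return float(np.mean((null_dh[:, 0] <= d_obs) & (null_dh[:, 1] <= h_obs)))


def dh_critical(n: int, S: int, alpha: float = 0.05, reps: int = 5000,
                seed: int | np.random.Generator = 0) -> float:
    """Null-calibrated threshold on the orthant p.

    The joint statistic's orthant measure is not uniform under the null
    (D and H are positively correlated), so a size-``alpha`` test rejects
    when the orthant p falls at or below the null ``alpha``-quantile
    returned here — the simulation calibration of the cited joint test.
    """
    rng = np.random.default_rng(seed)
    null = dh_null_sample(n, S, reps, rng)
    ps = np.array([dh_orthant_p(null, d, h) for d, h in null])
    return float(np.quantile(ps, alpha))


def dstar_pvalue(n: int, S: int, dstar_obs: float, reps: int = 5000,
                 seed: int | np.random.Generator = 0) -> float:
    """Two-sided empirical p for Fu & Li's D* from the fixed-S null."""
    rng = np.random.default_rng(seed)
    sims = []
    for _ in range(reps):
        mat = coalsim.simulate_fixed_s(n, S, rng)
        derived = mat.sum(axis=0)
        eta = len(derived)
        eta_s = int(np.sum((derived == 1) | (derived == n - 1)))
        ds = fuli_dstar(n, eta, eta_s)
        if ds is not None:
            sims.append(ds)
    sims = np.array(sims)
    lo = float(np.mean(sims <= dstar_obs))
    hi = float(np.mean(sims >= dstar_obs))
    return min(1.0, 2 * min(lo, hi))


# ---------------------------------------------------------------------------
# differentiation


def hudson_fst(pop_a: Sequence[str], pop_b: Sequence[str]) -> float | None:
    """Hudson's Fst = 1 - Hw/Hb on haplotype strings.

    Hw is the unweighted mean of the two within-population mean pairwise
    differences; Hb the mean between-population pairwise difference.  May
    be negative; no clamping.  Undefined (None) when Hb = 0.
    """
    if len(pop_a) < 2 or len(pop_b) < 2:
        raise ValueError("need >= 2 haplotypes per population")
    hw = (mean_pairwise_differences(pop_a) + mean_pairwise_differences(pop_b)) / 2
    hb = float(np.mean([_hamming(a, b) for a in pop_a for b in pop_b]))
    if hb == 0:
        return None
    return 1.0 - hw / hb


@dataclass
class NeutralityStats:
    tajima_d: float | None
    tajima_d_p: float | None
    fuli_dstar: float | None
    theta_L: float | None
    fay_wu_h_norm: float | None
    zeng_e: float | None
    dh_p: float | None


def neutrality(haps: Sequence[str], outgroup_hap: str | None = None,
               dh_reps: int = 10000, seed: int = 0) -> NeutralityStats:
    """All neutrality statistics for one haplogroup at one amplicon."""
    n = len(haps)
    div = diversity(haps, len(haps[0]))
    S = div.S
    if S == 0:
        return NeutralityStats(None, None, None, None, None, None, None)
    d = tajimas_d(n, S, div.pi_locus)
    d_p = tajima_d_pvalue(n, d) if d is not None else None
    # singletons: count columns where the rarer state occurs exactly once
    seg = segregating_columns(haps)
    eta_s = 0
    for j in seg:
        vals = [h[j] for h in haps if h[j] not in MISSING_CHARS]
        counts = sorted(
            (sum(1 for v in vals if v == s) for s in set(vals)))
        if counts[0] == 1:
            eta_s += 1
    dstar = fuli_dstar(n, S, eta_s)
    theta_l = h_norm = e = dh_p = None
    if outgroup_hap is not None:
        xi, _ = polarized_sfs(haps, outgroup_hap)
        if xi.sum() > 0:
            theta_l, h_norm, e = zeng_e_and_h(n, xi, int(xi.sum()))
            if d is not None and h_norm is not None:
                dh_p = dh_test(n, S, d, h_norm, reps=dh_reps, seed=seed)
    return NeutralityStats(tajima_d=d, tajima_d_p=d_p, fuli_dstar=dstar,
                           theta_L=theta_l, fay_wu_h_norm=h_norm, zeng_e=e,
                           dh_p=dh_p)
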