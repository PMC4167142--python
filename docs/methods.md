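# Methods

`sexlinkscan` re-implements, as a tested library, the analysis chain used
to locate and characterise a small XY sex-determining region from Sanger
amplicon resequencing of a dioecious plant (the motivating system is wild
grapevine, *Vitis vinifera* subsp. *sylvestris*, with hermaphrodite
domesticated cultivars). This note records the models, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Data model

Input sequences are per-amplicon alignments of *diploid consensus*
sequences: one sequence per genotype, heterozygous positions as IUPAC
ambiguity codes, missing as `N`. Indels are coded presence/absence: a run
of `-` is a homozygous deletion, a lowercase run a heterozygous one, and
each distinct gap extent becomes one biallelic `ins`/`del` site keyed by
its start column. The lowercase convention is this package's own — a
single consensus sequence cannot otherwise carry a heterozygous indel.
Coordinates are 1-based inclusive throughout; an amplicon spanning
4,900,275–4,901,493 bp has length 1,219.

Site filters follow the scan's inclusion rules literally with strict
inequalities: missing fraction < 0.20 and minor allele frequency > 0.05,
MAF computed on diploid allele counts (a heterozygote contributes one to
each allele) over the full sample. Sites with more than two alleles are
dropped with a warning: all downstream tests are binary.

## Per-sex Hardy–Weinberg scan

Under male heterogamety a site inside the non-recombining sex region is
heterozygous in every XY male and homozygous (major allele) in every XX
female. For each site, and for wild males and wild females separately,
the observed heterozygote/homozygote split is compared to the
Hardy–Weinberg expectation computed from pooled (male + female) allele
frequencies with a two-sided Fisher exact test. The expected row of the
2×2 table is the sample size apportioned by 2p(1−p) and rounded half-up —
an integer-table convention this package fixes because an exact test
needs integer margins; an exact-binomial alternative is available behind
a flag for sensitivity analysis. Multiple testing is Bonferroni-controlled
(α/n over all retained sites; reported as −log10 to 2 decimals).

Sites are classified against the XY model: *perfect* (every non-missing
male heterozygous, every non-missing female homozygous-major), *near*
(all females homozygous-major, one or two non-heterozygous males;
the allowance is configurable), else *none*. The sex region is delimited
externally: from the end of the last non-qualifying amplicon upstream of
the first perfect-or-near amplicon to the start of the first
non-qualifying amplicon downstream, an open interval whose length is
`end − start` (reported in kb to 2 decimals).

## Kinship/structure-corrected LD

Composite LD between unphased sites is the squared Pearson correlation of
minor-allele dosages over pairwise-complete genotypes. Relatedness and
population structure inflate it; the corrected estimator whitens both
dosage vectors by the inverse Cholesky factor of the kinship covariance
(restricted to the complete genotypes; 1e-6 diagonal jitter on
singularity, with a warning), projects out the whitened ancestry
covariates (intercept plus the structure matrix with its last, collinear
column dropped), and squares the correlation of the residuals. With
identity kinship and a trivial structure matrix this reduces to the
classic r² exactly (checked to 1e-10). The LD stage carries its own
frequency filter (MAF > 0.2 on the analysed subset), separate from the
scan's 0.05.

## Haplotype phasing

PHASE-style coalescent-prior sampling is replaced by multi-restart
expectation–maximization on the multinomial haplotype-frequency model
(gene-counting EM): deterministic given a seed, dependency-free, and
adequate for the ≤ ~30 segregating sites per amplicon seen here. The
likelihood is non-decreasing by construction (assertable in debug mode);
the best of `n_restarts` seeded starts is kept and each genotype is
assigned its most probable compatible pair, with exact ties broken toward
the lexicographically smallest haplotype and reported at posterior 0.5.

Genotypes are expanded into compatible haplotype pairs exhaustively up to
an ambiguity budget (2^10 pairs, missing sites marginalized within their
own budget). Beyond it, *anchored enumeration* is used: near-unambiguous
genotypes donate their haplotypes as anchors, and a high-ambiguity
genotype is resolved as (anchor, forced complement) for every compatible
anchor — the structure that makes XY data identifiable in practice, since
homozygous females pin the X-like haplotypes and each male's Y-like
complement is then determined. Pair lists are capped deterministically;
the anchor order is the processing order. Variants too rare to pass the
MAF filter are not phased: their placement within a genotype is not
identifiable from genotype frequencies alone, so pipeline haplotypes are
defined over the filtered sites.

## Haplogroup assignment

The F (X-like) side is seeded with every haplotype carried by a
non-outgroup female; the M (Y-like) side with the modal male-exclusive
haplotype (the shared M background) and its one-mutation neighbourhood.
Remaining haplotypes attach by competitive single-linkage growth —
repeatedly joining the unassigned haplotype closest to either side — a
distance formulation of the tree-clade criterion that is robust when M/F
divergence dominates within-F diversity (the regime the data show:
M-vs-F differentiation ~0.9). Equidistant haplotypes are flagged
ambiguous, never silently resolved. Haplotypes on the M side carried by
males are M; carried only by hermaphrodites, H (a haplotype shared by
males and hermaphrodites is labelled M at the haplotype level and read as
H in hermaphrodite carriers, following M > H > F dominance). Genotypes
violating the XY dosage expectation (females ≠ FF, males ≠ MF,
hermaphrodites with two F copies) are flagged, not coerced.
Macrohaplotypes concatenate each genotype's per-amplicon haplotypes in
genomic order, F side and alternate side separately; per-amplicon label
conflicts mark the genotype recombinant and exclude it from the network
by default.

Trees for inspection are neighbor-joining on Hamming distances (indels
count 1) rather than GTR maximum likelihood: with few segregating sites
and deep M/F divergence, clade membership does not depend on the tree
method.

## Diversity and neutrality statistics

Per haplogroup and amplicon: segregating sites S, distinct haplotypes Nh,
haplotype diversity H = (n/(n−1))(1 − Σp²), and per-site nucleotide
diversity π (mean pairwise Hamming distance / length; report rounding
H 2 dp, π 5 dp). Tajima's D and Fu & Li's D* (no-outgroup,
singleton-based) use the standard constants; for D* the d_n constant
follows the convention with a_n inside the bracketed term, which
reproduces published worked values at 2 decimals (the a_{n+1} variant
differs in the second decimal). D's significance uses the original
beta-approximation over its [Dmin, Dmax] support; D*'s comes from this
package's own fixed-S coalescent null, since the original test published
simulated critical tables rather than a closed form.

With an outgroup haplotype the site-frequency spectrum is polarized
(outgroup allele ancestral; sites with a missing or third-state outgroup
excluded and counted), giving θ_L = Σ i·ξ_i/(n−1), the normalized
Fay & Wu H, and Zeng's E, with the closed-form variances of the joint
test and unbiased plug-ins θ̂ = S/a_n, θ̂² = S(S−1)/(a_n²+b_n). Both
variance formulas were cross-validated against a genealogy-decomposition
Monte Carlo and full coalescent simulation. Note that, like Tajima's D,
the normalized statistics have a small negative null mean under fixed-S
conditioning (≈ −0.1 for E at n=20, S=10).

The joint D/H ("DH") test targets the sweep-like corner (both statistics
negative). Its p is the orthant measure: the fraction of fixed-S neutral
coalescent replicates with D ≤ D_obs and H ≤ H_obs simultaneously.
Because D and H are positively correlated, the orthant p is not uniform
under the null; a size-α test therefore rejects at the null α-quantile of
the orthant p, calibrated by simulation (`dh_critical`), exactly as the
original joint test calibrates its critical values.

Differentiation is Hudson's Fst = 1 − Hw/Hb with Hw the unweighted mean
of the two within-pool mean pairwise differences (pool sizes differ) and
Hb the mean between-pool difference; negative values are reported without
clamping.

## Coalescent null

A plain Kingman coalescent (exponential waiting times at rate k(k−1)/2,
uniform pair merges) with S mutations dropped on branches proportionally
to length under infinite sites. Fixed-S rather than fixed-θ conditioning
because the joint-test null is defined that way and it removes the
nuisance dependence on θ; no recombination, matching the presentation of
the sex region as essentially non-recombining.

## Synthetic data generator

The generator emulates the study design: four sex-linked amplicons of
1111/849/690/498 aligned bp on a chromosome-2-like coordinate frame
(optional neutral flanking amplicons for region delimitation), with
XX females, XY males and hermaphrodites whose H alleles derive from M.

* **F pool** — neutral coalescent haplotypes at θ_F = 3.5 per amplicon,
  matching the observed X-pool Watterson/π scale of roughly 1.5–5 per
  amplicon; a small fraction (5%) of variants are 1-bp indels.
* **M pool** — one ancestral background carrying fixed M-diagnostic
  alleles at 12/12/11/11 designated sites (46 across the region,
  matching the count of sex-linked polymorphisms the design emulates and
  producing M-vs-F differentiation of ~0.85–0.95), plus Poisson(0.25)
  private singletons per sampled copy — the bottlenecked, low-diversity
  Y-like pool whose excess of rare variants drives negative D and D*.
* **H pool** — each H copy is the M background plus Poisson(1) private
  mutations; with probability `h_recomb_prob` a copy instead imports a
  random F haplotype within the eligible window (default: the last
  amplicon), emulating X-into-Y introgression. At the default
  `h_recomb_prob = 0` H is M-like everywhere.
* Genotypes: females FF, males FM, hermaphrodites HF (HH with
  probability 0.1). Missingness is MCAR at rate 0.02 per variant call
  (no mechanism is stated for the real data). Three homozygous outgroup
  records of sister species diverge by ~8 private mutations per
  amplicon and carry the ancestral state at sample-variable sites, so
  they polarize the SFS. Kinship (identity plus optional 0.5 family
  blocks) and structure (0.9 home-group ancestry, K=2) matrices are
  fabricated inputs, as they are inputs in the emulated analysis.

Identical seeds give byte-identical files; a truth record stores every
haplotype, phase, label and diagnostic site, sufficient to score each
downstream stage without re-simulation.

What the generator does *not* emulate: intra-amplicon recombination in
the wild populations, sequencing/chromatogram error, allele dropout,
geographic population structure in the sequences themselves (structure is
only in the fabricated ancestry matrix), and inter-amplicon LD within the
F pool (X haplotypes are drawn independently per amplicon). Passing
end-to-end tests therefore demonstrate correct recovery under the stated
generative model, not robustness to these real-data complications.

## Median-joining network

Star contraction first collapses star-like clusters: within the
δ-neighbourhood graph (δ = 1 mutation) a haplotype merges into the
neighbour of strictly higher (degree, multiplicity) rank, rounds
repeating to stability; equal-rank pairs never merge and multiplicities
are conserved. The median-joining iteration alternates between the
ε-relaxed minimum spanning network (ε = 0 default) and quasi-median
generation from triples with at least two MSN edges, adding a median when
its three-way star cost beats the triple's current spanning cost;
unobserved nodes of degree ≤ 2 are pruned, and ties everywhere break
lexicographically so networks are reproducible. Distances are weighted
shortest paths in mutation counts; the H-origin analysis reports each H
node's minimum distance to the M group and a one-way ANOVA
(r² = SS_between/SS_total) of those distances against categorical
factors, dropping levels with fewer than two observations.

## Problem sizes used in the tests

The end-to-end suite runs 50 seeded replicates per arm at the default
conditions (30 F / 30 M / 20 H genotypes), with EM at 2 restarts; the
null-calibration suite uses 2,000–2,500 fixed-S replicates at n = 20,
S = 10. The full test run completes in a few minutes on one CPU.

## Known limitations

* EM phasing commits to the maximum-likelihood phase; unlike a
  coalescent-prior sampler it has no notion of mutational proximity, so
  on data with many equally-likely configurations it can pick a
  population-frequency-optimal but historically wrong phase. The
  anchored construction mitigates this in the XY setting.
* Sub-MAF variants are excluded from phased haplotypes (unidentifiable
  placement), so pipeline diversity statistics are computed on common
  sites; the statistics themselves accept any haplotype lists, including
  full sequences from other sources.
* The orthant DH p-value is reported as-is alongside the calibrated
  threshold; comparing the raw orthant p to α directly would be
  conservative or anticonservative depending on the D–H dependence.
* Star contraction and median-joining use uniform site weights; weighted
  variants are out of scope.
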