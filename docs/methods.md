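# Methods

`glpop` re-implements, at desk scale, the analysis chain used to resolve
population structure and putative chromosomal inversions in low-coverage
whole-genome resequencing (lcWGS) studies of wild fish populations: genotype
likelihoods in, QC filters, iterative PCA and admixture EM, Hudson FST and
isolation by distance, windowed diversity, a PCA-based selection scan, and a
local-PCA/MDS structural-variant scan with inversion characterisation. All
components are exercised end to end against a synthetic generator with a
machine-readable truth ledger.

## The synthetic generator

The generator emulates the statistical structure the analyses assume, not a
full coalescent.

**Drift.** Demes are connected by a graph whose edges carry a drift
coefficient `F`, defined as the *target pairwise Hudson FST* across that
edge. Frequencies propagate along a BFS spanning tree: a child deme's
frequency is a Balding–Nichols draw `Beta(p(1-c)/c, (1-p)(1-c)/c)` around
its parent's `p` with conditional coefficient `c = 2F`. With the parent
being the pair's common ancestor, `E[Hudson FST] = c/2 = F` exactly (ratio
of expected numerator/denominator), so a two-deme graph with `F = 0.05`
yields genome-wide FST near 0.05. The flip side of this calibration is that
the conditional variance identity reads
`E[(p_child − p_parent)² / (p_parent(1 − p_parent))] = 2F`, which the test
suite asserts. Along a chain, residual heterozygosity decays by `(1 − 2F)`
per edge and pairwise FST between demes `u, v` with most recent common
ancestor `a` is `1 − (r_u + r_v)/2` with `r_x` the decay from `a` to `x`;
`expected_pairwise_fst` computes exactly this and the truth ledger records
it. Valid edge range is `(0, 0.5)`.

**Ancestral frequencies** are `Uniform(0.05, 0.5)` by default (the 0.05
floor lets most sites survive the MAF filter). In `neutral_sfs_mode` they
are drawn from a density proportional to `1/x` truncated to
`[1/(2N), 1 − 1/(2N)]` (`N` = 10,000 by default), which induces an exactly
neutral expected sample spectrum (`E[#sites with count i] ∝ 1/i`), the
condition under which Tajima's D is centred at zero.

**Inversion.** Two non-recombining haplogroups A/B occupy a configured span.
A regular stride of in-span SNPs (`divergent_fraction`, default 0.5) is
divergent: `|p_A − p_B| = δ` around a midpoint drawn so both stay in
`[0, 1]`. Karyotypes are Hardy–Weinberg draws at each deme's
arrangement frequency; within the span each haplotype draws its alleles
from its haplogroup's frequencies with zero recombination. This produces the
three expected signatures: three karyotype clusters on local PC1, elevated
heterokaryotype heterozygosity, and elevated internal LD.

**Reads.** Per site×individual depth is `Poisson(λ)`, alternate reads are
`Binomial(d, g/2·(1−ε) + (1−g/2)·ε)`, and the emitted genotype likelihoods
use the same binomial model, normalised to sum 1. Depth 0 yields the flat
triplet `(1/3, 1/3, 1/3)`, the conventional missingness encoding. Defaults
`λ = 1.5` (matching the ~1.5× regime lcWGS studies report) and `ε = 0.005`
(post-filter Illumina error) are study conditions, not tuning knobs.

**Regular grids.** SNP positions are evenly spaced per chromosome and
divergent sites are placed by a regular stride. Both choices make window
membership deterministic and keep LD-based boundary refinement identifiable
(under uniform random placement the link-count argmax is noise-dominated;
see below). Real genomes are not regular; conclusions about boundary
precision therefore transfer only qualitatively.

**All randomness** flows from one seed through named substreams (ancestral,
drift, inversion, outlier, genotypes, reads, alleles), so stages are
individually reproducible and output is byte-identical across runs.

What the generator does **not** emulate: linked selection, recombination
maps and background LD decay, coalescent genealogies, batch effects,
reference bias, and indel/mapping artefacts. Passing tests show the
estimators recover the planted structure under the stated model — not that
they are robust to everything real data contains.

## Estimators and the shallow-coverage corrections

Several textbook estimators are biased at ~1.5× coverage because genotypes
are uncertain. Where that bias broke the estimator's own calibration, the
likelihood-aware standard was implemented instead; each case is noted here.

**Allele frequencies** are per-site maximum-likelihood under HWE by EM
(tolerance 1e-6, ≤100 iterations, converged sites dropped from the active
set). All-missing sites are flagged.

**Hudson FST** uses per-site components summed as a ratio of averages.
The hard-genotype correction `p(1−p)/(n_hap−1)` removes only
genotype-sampling noise; at 2× it leaves read noise in the numerator
(measured +0.01 on a true 0.05). The default therefore splits each group
into two alternating halves and forms
`N = (p1A − p2A)(p1B − p2B)` and the symmetrised
`D = ½[p1A(1−p2B) + p2A(1−p1B) + p1B(1−p2A) + p2B(1−p1A)]`,
whose expectations equal the population quantities for *any* unbiased,
independent half-estimates — no variance correction needed. Without halves
the classical corrected form is used. AFD is the mean absolute frequency
difference with a globally fixed allele polarity; linearised FST is
`f/(1−f)`.

**Duplicate detection** correlates *standardised* posterior-mean dosages
(centred by `2f`), because raw dosage vectors share the allele-frequency
baseline (unrelated pairs sit near r ≈ 0.38, not 0). Genotype-likelihood
shrinkage caps duplicate pairs near r ≈ 0.77 at 1.5×, while full sibs stay
below ≈ 0.4; the default threshold is 0.5.

**Excess-heterozygosity site filter** (a surrogate for read-level
mismapping tests): one-sided exact binomial tail of the called heterozygote
count against its HWE expectation, BH-adjusted, flagged at adjusted
p < 0.001.

**Individual and region heterozygosity** use summed posterior heterozygote
probabilities rather than maximum-posterior calls: at shallow depth hard
calls lose single-read heterozygotes (−25% at 2×) and, where the site
frequency sits near 0.5, the call is prior-dominated and can even invert
the karyotype-group ordering. The posterior is calibrated under the HWE
prior and reduces to plain counting on confident genotypes.

**Diversity.** The default SFS path computes each site's likelihood of
carrying `j` of `2n` allele copies by the standard polynomial convolution
over individuals (divided by `C(2n, j)`), fits the sample SFS by EM across
sites, and takes per-site segregating probabilities and heterozygosity
expectations from the empirical-Bayes posterior. Hard-call counting
(`method='calls'`) is retained but inflates singletons through sequencing
error at 1.5× (measured mean Tajima's D −0.8 on neutral data, vs −0.015
for the likelihood path). Window estimators: `θ_W = S/a₁`,
`θ_π = Σ E[j(2n−j)]/C(2n,2)`, both per 1000 callable sites, 25 kb windows
with 5 kb step and a 1000-site floor; Tajima's D uses the standard
`a₁..e₂` constants at the subsample size (26 individuals by default,
seeded without replacement). Note that a MAF-filtered SNP panel has, by
construction, a rare-variant deficit and strongly positive D; neutral
calibration holds only for all-sites input.

## PCA, selection scan, admixture

**PCA** follows the iterative individual-allele-frequency scheme for
genotype likelihoods: expected genotypes under per-individual HWE priors,
standardised by site frequency, rank-K SVD reconstruction feeding back into
the prior (frequencies truncated to `[1e-4, 1−1e-4]`), stopping when the
RMS change of the frequency surface drops below 1e-5 (or 100 iterations).
On hard genotypes this reproduces direct PCA of the standardised genotype
matrix exactly (sign-invariant), which the suite asserts. The axis count
K* defaults to the scree elbow (argmax of the second difference of the
eigenvalue curve), with an explicit override because visual scree choices
don't reduce to one rule.

**Selection scan.** Per axis k, `s_jk = (x_j · u_k)²/λ_k`, chi-square with
1 d.o.f. under drift alone; the mean is exactly 1 by construction
(`Σ_j s_jk = M`). p-values feed Storey q-values (π₀ from a cubic smoother
over the λ-grid 0.05..0.95, falling back to π₀ = 1, i.e. plain BH, when
the estimate leaves (0,1]); outliers at q < 0.01; ≥10 outliers per
non-overlapping 1000-SNP window flag the window; flagged windows fewer
than 10 windows apart merge into candidate regions. Two practical notes:
the scan must run on MAF-filtered data (near-monomorphic sites produce
unstable standardised genotypes whose p-values underflow), and the
statistic is bounded by `n/λ_k`, so genome-wide q < 0.01 on a
high-eigenvalue axis is unattainable in small cohorts — the analysis
drivers report rank-based enrichment alongside for that reason.

**Admixture** is the standard genotype-likelihood EM: `h_is = Σ_k q_ik
f_ks`, binomial genotype prior, expected allele-copy attributions to
clusters, tolerance 1e-5 on the log-likelihood, ≤2000 iterations, F
initialised at the site MAF ± Uniform(0.05) and Q at Dirichlet(1) from the
seed. The log-likelihood is monotone (asserted per run). Replicate
comparisons align labels by Hungarian assignment on column correlations.
Cluster counts use the four threshold-based estimators
(MedMedK/MedMeanK/MaxMedK/MaxMeanK at thresholds 0.5–0.8); individuals with
membership > 0.99 to a cluster other than their site's dominant cluster are
reassigned as putative first-generation migrants, and maximum membership
< 0.8 flags putative admixture.

## LD, local PCA, inversions

**LD** is the squared Pearson correlation of posterior-mean dosages over
jointly covered individuals (≥10 required), a simpler stand-in for
haplotype-EM estimators that preserves the relative contrasts the pipeline
needs. Pruning greedily removes the site with the most violating pairs
(ties: lower MAF, then later position) until no pair within 200 kb exceeds
r² = 0.075; the result is verified by exhaustive pair check.

**Local PCA** summarises each non-overlapping 100-SNP window by its rank-4
eigen-approximation of the individual covariance, scaled to unit Frobenius
norm; window distances are Frobenius distances between summaries (a metric
by construction). Classical (Torgerson) MDS embeds windows on 5 axes;
windows beyond 3 SD from an axis mean (genome-wide) are outliers; outliers
within 20 window indices merge; clusters of ≥10 windows are kept. The 3-SD
rule self-masks once outliers dominate an axis's variance (the flagging
threshold then scales with the outliers themselves), so detection
degrades, by construction, for structures spanning more than ~10% of
windows.

**Karyotyping** is k-means on region PC1 with 50 restarts; if a cluster has
fewer than 2 members or silhouette < 0.3, k = 4..6 solutions are merged
back to three groups by 1-D 3-means on their centres. The middle PC1 group
is AB; the commoner extreme is AA. Heterokaryotype excess heterozygosity is
tested with one-sided Wilcoxon rank-sum tests (AB > AA, AB > BB) on
per-individual posterior heterozygosity over region SNPs.

**LD-block test.** Mean pairwise r² inside the candidate (pairs subsampled
to ≤100,000 with the seed) against 1000 random same-length windows on the
same chromosome (uniform start, overlap with the candidate excluded so the
null is uncontaminated; ≤2000 pairs per null window), summarised as a
one-tailed Z-test.

**Boundary refinement.** The chromosome-wide top-5% r² threshold is taken
over all same-chromosome pairs within 200 kb. Within the candidate span
padded by 25%, the start is the SNP tightly linked to the most downstream
SNPs of the padded window (ties → smallest position) and the end the SNP
linked to the most upstream ones (ties → largest position). The link
counts deliberately ignore the 200 kb cap: capping them makes the count
profile flat and noise-dominated inside any span longer than 200 kb
(refined starts wandered up to half a megabase into a 1.5 Mb inversion),
whereas whole-window counts decrease monotonically away from the true
breakpoints. Degenerate refinements (no link above threshold, or end ≤
start) fall back to the original span, flagged. Lengths are reported as
`(end − start)/1000` kbp to one decimal — the convention validated against
all four published boundary/length pairs the suite checks.

## Geography

Least-cost in-water distances run Dijkstra (scipy sparse graph) over water
cells of an Arc-ASCII raster, 8-neighbour moves costing the cell size (×√2
diagonally), land impassable, samples snapped to the nearest water cell.
The Mantel test is one-tailed (greater) with simultaneous row/column
permutation and the +1 correction, seeded. The bundled stepping-stone
study places demes unevenly along a corridor and scales each edge's drift
with its geographic length; with even spacing (or spacing-independent
drift) the order-reversing permutation ties the identity and the 4-deme
null (24 permutations, p-floor 1/24) cannot reach 0.05.

## Problem sizes

The bundled studies run on one CPU in a few minutes total: FST recovery at
50,000 SNPs (30+30 diploids, 2×); scan calibration at 20,000 SNPs (100
individuals, 1.5×); the inversion study on two 10 Mb chromosomes × 10,000
SNPs (3 demes × 30, 1500-SNP inversion, δ = 0.8, frequencies
0.2/0.4/0.6), repeated over 20 seeds in the suite; IBD at 10,000 SNPs
(4 × 20); neutral diversity at 100,000 densely packed sites (26-individual
subsample); admixture at 5,000 SNPs (90 pure + 10 half-admixed). These are
the package's study conditions, chosen so every estimator has the
resolution its check needs.

## Known limitations

- The FastPCA statistic's `n/λ` ceiling makes genome-wide q < 0.01
  unreachable for small cohorts on dominant axes; region calling at desk
  scale therefore relies on the null calibration plus rank enrichment.
- Split-half FST costs a factor ~2 in per-site precision (immaterial when
  summing over tens of thousands of sites) and needs ≥2 covered
  individuals per half.
- The GO enrichment assumes a pre-propagated gene→term map and skips terms
  with fewer than two universe genes; no ontology-graph propagation is
  performed.
- LD from posterior-mean dosages understates absolute r² at shallow depth
  (shrinkage); all LD-based decisions here use relative contrasts, which
  are preserved.
- Boundary refinement assumes LD decays away from the breakpoints; on a
  regular synthetic grid it recovers boundaries within a few percent of
  span length, but irregular SNP density and background LD will widen this
  on real data.
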