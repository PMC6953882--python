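# Methods

`transmqtl` maps trans-acting regulators of CHH-context DNA methylation
(mCHH) from population data: a genotype matrix for inbred lines,
per-line per-TE bisulfite read counts, a TE annotation, a
knockout-panel differential-methylation table, and per-line geography.
Because real population bisulfite compendia are far too large for a
desk, the package ships a synthetic-cohort generator that reproduces
the statistical structure the analysis assumes, so every stage is
exercised end to end at small scale.

## The synthetic cohort

**Genotypes.** Lines are inbred and selfing, so genotypes are coded
haploid 0/1 with no heterozygotes, and haplotypes between loci are
directly observed. Background SNPs follow a Balding–Nichols model:
each SNP draws an ancestral frequency p ~ U(0.1, 0.9) and
subpopulation frequencies from Beta(p(1−F)/F, (1−p)(1−F)/F), with the
divergence parameter F = 0.1 by default (0 gives panmixia). Lines are
assigned to subpopulations whose sampling centres are spread along the
longitude window [−25, 100] degrees.

**Causal alleles.** Each planted trans-acting locus declares a target
TE class, an additive effect on the methylation-level scale, an
optional cross-class effect, a target frequency, and a longitudinal
cline slope. Carriage probability follows a logistic gradient in
longitude whose intercept is solved (Brent) so the mean equals the
target frequency; draws are repeated until the realised frequency is
within 20% relative of target, and an unreachable frequency (too few
lines) raises an error naming the locus. The default three-allele
architecture mirrors the canonical natural situation: one eastern
allele at a Pol V-subunit-like locus lowering RdDM-targeted
methylation (effect −0.06, MAF 0.09) with a weaker genome-wide term on
CMT2 targets (−0.03), and a western opposite-effect pair at a
chromomethylase-like locus (−0.05 at MAF 0.237 and +0.04 at MAF 0.10)
restricted to CMT2 targets. Because the pair's clines oppose each
other, the class average shows no net longitudinal pattern, while the
single eastern allele drives one — the geographic signature the
pipeline is meant to detect.

**TE classes and annotation.** TEs are allocated to RdDM-like (short,
chromosome arms; superfamilies RC/Helitron, DNA/MuDR), CMT2-like
(long, pericentromeric; LTR/Gypsy, LTR/Copia) and untargeted classes
by exact largest-remainder fractions (default 0.4/0.4/0.2), with
lognormal lengths (medians 500/4000/800 bp, σ = 0.4). Intervals are
0-based half-open; overlap is permitted — the table is positional
only. Families nest within classes.

**Methylomes.** The latent level of line i at TE j is
class baseline (0.15 RdDM / 0.25 CMT2 / 0.05 untargeted)
+ Σ_l g_il·(class-restricted effect + cross-class term)
+ u_i + ε_i + ε_ij, clipped to [0, 1] (a warning reports clipping
beyond 5% of cells). The polygenic background u ~ N(0, σ_g²K) with K
the IBS kinship of the simulated SNPs, σ_g² set so it contributes the
fraction `h2_background` (default 0.3) of line-level variance — this
is what gives the mixed model genuine structure to correct. ε_i is
iid line noise (default SD 0.02; biologically, genome-wide methylation
level differences between lines) and ε_ij per-cell heterogeneity (SD
0.02). Observed counts are beta-binomial: depth ~ Poisson(40) per TE
(zero depth = missing cell), and the methylated count is binomial with
a Beta-distributed per-cell rate whose intra-class correlation is the
single overdispersion scalar ρ (default 0.1). Depth and ρ are invented
defaults — real per-TE depth distributions are not published — and
are config-exposed.

**Positional profiles.** On request the generator also emits 60-bin
counts (20 upstream flank, 20 body, 20 downstream). Effects whose
source targets the CMT2 class deplete the body bins only; RdDM-type
effects (including the cross-class term of the Pol V-like allele) act
over the whole element with flanks at half weight. This reproduces the
qualitative metaplot contrast between a heterochromatic-body knockout
and a whole-element natural allele.

**Knockout panel.** The panel holds per-mutant per-TE DML (mutant −
wild-type; negative = loss). It contains two pathway classifiers
(losing 0.3 on their class's TEs), one mutant matched to each planted
allele, and ≥10 sparse random decoys. A matched mutant's profile is a
positively scaled copy (default ×3 — knockouts are stronger than
natural alleles) of the planted allele's expected effect profile plus
noise, so its Spearman correlation with the allele profile is 1 at
zero noise. For an allele that *raises* methylation this gives a
hypermethylated "knockout", which no real loss-of-function line would
show; the convention keeps allele-mutant matching sign-consistent and
is documented rather than hidden.

**Expression.** A designated cis locus shifts a strictly positive,
log-normally noised expression value additively
(y = (baseline + shift·g)·e^σz), emulating a regulatory allele that
acts through transcript abundance.

## Phenotype construction

Methylation levels are *weighted*: summed methylated reads over summed
covered reads, never the mean of per-unit ratios; a region with zero
coverage is missing, not zero. The common-TE filter keeps TEs covered
in every line. Family phenotypes are unweighted means over member TEs
restricted to common TEs (weighting by length or coverage would be
defensible; unweighted is the simplest choice and is flagged as such).
Ranks use the average-tie convention (preserves rank sums). TEs are
classified RdDM / CMT2 / both / untargeted by whether |DML| against
each classifier knockout strictly exceeds 0.1; "both" is an explicit
extra label for TEs responding to both pathways. Family clustering
rank-transforms per line, uses Euclidean distance and complete
linkage, and cuts at k = 4 groups by default; distance, linkage input
and k are exposed because only the agglomeration method is canonical.

## Association scans

The mixed model y = μ + xβ + u + ε with cov(u) = σ_g²K, K the IBS
kinship (pairwise fraction of shared alleles, missing calls excluded
pairwise), is fitted in the EMMAX/P3D style: variance components are
estimated once on the null model by REML — a coarse grid on the
heritability ratio h = σ_g²/(σ_g²+σ_e²) followed by bounded refinement,
in the eigenbasis of K (eigenvalue floor 1e-8) — then every SNP is
tested by generalised least squares in the rotated space with those
components fixed (Wald, t with n−2 df). This costs one n×n
eigendecomposition plus O(n·m) per scan. SNPs are filtered at MAF
strictly > 5%; missing genotypes are mean-imputed per SNP. With K = I
the scan is exactly the per-SNP OLS t-test, and a brute-force per-SNP
REML oracle reproduces the scan to numerical precision when its
variance ratio is pinned to the null estimate. Re-estimating the
ratio per SNP moves mid-range p-values by more than 0.05 in −log10 for
roughly 5–15% of SNPs at n = 60 — the P3D approximation error itself,
which shrinks with sample size; the test suite asserts the exact
fixed-ratio equivalence and close bulk agreement rather than
pretending the free-ratio fits coincide.

Box-Cox preparation of expression picks λ on the grid [−2, 2] (step
0.01) by profile log-likelihood; non-positive values are an error (no
automatic shifting). Variance explained is the squared Pearson
correlation of genotype with phenotype.

## Meta-analysis and peaks

Per-SNP p-values from the k per-phenotype scans are pooled by Fisher's
method, X² = −2Σln p_i ~ χ²(2k); exact zeros are clamped to 1e-300
with a warning. Component scans share line-level noise and are
therefore positively correlated; the combined X² is treated as a
ranking statistic and its null calibrated implicitly by the enrichment
FDR rather than by the nominal χ² tail — the dependence is documented,
not corrected.

Gene-level significance is the best combined p among MAF-filtered SNPs
within the gene span ± 15 kb (closed interval, measured from the span,
not the midpoint). The significance threshold is calibrated by
candidate-gene enrichment: over the descending grid of observed gene
scores t, FDR(t) = (fraction of background genes ≥ t)/(fraction of a
priori candidate genes ≥ t), capped at 1, and the smallest t with
FDR ≤ 20% is returned with the full curve. The ratio is treated as
undefined until at least three a priori genes exceed t
(`min_apriori_hits`, exposed): with the denominator resting on one or
two genes the estimate is noise, and a single lucky candidate at the
top of the grid would declare a threshold under a completely
exchangeable null about a quarter of the time; requiring three drops
that to a few percent without affecting a genuinely enriched mixture.

Peaks above threshold are pruned greedily by descending X² (ties by
genomic order): a SNP is retained iff r² ≤ 0.2 against every retained
SNP, and pruned SNPs are recorded under the retained peak they
correlate with most.

## Allelic effects and the permutation causality test

The DML profile of an allele is, per TE, mean(alternative carriers) −
mean(reference carriers); negative means the alternative allele lowers
methylation. Profiles are compared to every panel mutant by Spearman
correlation over shared TEs (≥10 required). Significance of an
observed correlation is empirical: 1,500 SNPs (default) are drawn
uniformly from the MAF-filtered genome without frequency matching,
the profile is recomputed at each, and
p = (1 + #{|r_perm| ≥ |r_obs|})/(n_perm + 1) — two-sided, never zero,
monotone in |r_obs|. The null is genuinely interesting here: SNPs that
tag population structure inherit diluted copies of the causal class
structure, so the permutation distribution has heavier tails than an
independence null — which is exactly why the test is run this way.

Joint-genotype metaplots average the 60-bin profiles over each two-
locus genotype combination (empty combinations are dropped with a
warning, as the rarest combination typically is), and Welch's t-test
compares per-line levels on the central body bins (bins 10–11 of the
body; config-exposed) between designated combinations. Expression
differences by allele use Welch's unequal-variance two-sided t-test.

## Inter-locus LD and geography

For haploid lines D = p_AB − p_A p_B is computed from observed
haplotype counts; Dmax is min(p_A(1−p_B), (1−p_A)p_B) for D > 0 and
min(p_A p_B, (1−p_A)(1−p_B)) for D < 0; D′ = D/Dmax, 0 when D = 0.
The matched-frequency null collects all SNPs whose MAF equals the
partner's within ±0.5 percentage points (exact matching is brittle on
small panels; tolerance exposed) on chromosomes excluding both focal
loci, and reports the empirical p of the observed D′ with the
direction fixed a priori as depletion of the double non-reference
haplotype — the stabilising-selection hypothesis. Choosing the side
from the observed sign instead would double-dip and concentrate null p
below 0.5. One-sided Fisher's exact depletion tests (hypergeometric
tail of the double-carrier cell) accompany each pair.
Genotype-combination frequencies are compared with the random-mating
expectation n·Πf_l as observed/expected ratios, without asserting any
particular depletion factor.

Cline analysis averages methylation over the TEs whose focal-SNP
association reaches −log10 p ≥ 6 at full biobank scale; at the
package's default synthetic depth the per-TE score distribution tops
out lower, so the pipeline default is 1.3 (nominal p < 0.05), exposed
in both places. The value is regressed on longitude within [−25, 100]
by OLS; when a covariate SNP is given, the value is first regressed on
the genotype and the residuals carry to the longitude regression —
testing whether a cline is allele-mediated. BLUP correction fits
y = μ + u + ε by REML with the IBS kinship and returns y − μ̂ − û
(centred when σ̂_g² = 0); it subtracts the predicted random effect in
a two-stage design rather than refitting longitude inside the mixed
model.

## Pipeline

Stages simulate → summarize → gwas → meta → effects → geo run from one
YAML config and one seed; every stage receives the sub-seed
seed XOR stage-index so any stage can be re-run in isolation with
identical output, and a manifest records the config hash and SHA-256
of every output. All tables are TSV with a one-line `#` schema header;
genotypes are also written as minimal VCF. The effects stage
regenerates the binned count table deterministically from the config
and the simulate sub-seed instead of persisting the (large) per-bin
TSV. Logs are line-delimited JSON.

## Problem sizes and what the tests show

The default cohort is 500 lines × 5,000 SNPs × 400 TEs in 30 families;
unit tests use 60–500 lines. Calibration checks use 5,000 SNPs at
n = 250 with an explicit subpopulation shift plus a polygenic term, so
the uncorrected scan's inflation is structural rather than left to a
single random draw. The planted-QTL recovery study uses a single
locus calibrated so its realised target-class variance is ~6% at
n = 500 (effect −0.028 at MAF 0.25 against line noise 0.04), carrying
the weaker cross-class term characteristic of this architecture's
principal regulator; the causal SNP must top the Fisher meta-scan in
≥18/20 seeds.

Passing tests show the machinery is correct and calibrated on data
satisfying the generator's assumptions: biallelic SNPs, TE-level
resolution, beta-binomial read noise, additive class-restricted
effects, logistic clines. They do not show robustness to features the
generator omits — TE insertion polymorphism, per-cytosine context
mixtures, mapping artefacts on diverged genomes, dominance or
epistasis, or climate covariates beyond longitude.

## Known limitations

* Fisher combination over correlated family scans inflates X² tails;
  the enrichment FDR absorbs this in practice but the combined p is
  not a calibrated tail probability.
* The P3D variance components are estimated once; strongly associated
  SNPs in small panels would shift them under an exact per-SNP fit.
* Weak alleles (low MAF, small effect) can fail the permutation
  causality test at desk scale even though their full-scale analogues
  pass; the test's null is dominated by structure-tagging SNPs.
* The generator plants class-restricted additive effects only; the
  "both" target class arises solely through classifier noise.
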