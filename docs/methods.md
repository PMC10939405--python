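# Methods

This note documents the models, the synthetic study design, the numerical
choices and the known limitations of `grapegwas`.

## Phenotype model and BLUE estimation

Phenotypic records enter as a long table of (accession, season, trait,
value) with covariate columns.  For each trait we fit, by ordinary least
squares,

    y = X1 β + X2 ω + X3 g + ε,   ε ~ N(0, σ²ε)

with season fixed effects β, covariate slopes ω and accession fixed
effects g.  Identifiability: seasons are sum-to-zero coded, accessions
enter as a full dummy block (no separate intercept), so the reported BLUE
for accession *i* is its expected value in an average season at covariate
value zero.  Accession *contrasts* — all the scan ever uses — are invariant
to this convention.  σ²ε is a single homoscedastic residual variance pooled
across seasons (the model admits nothing finer).  Records with missing
covariate values are dropped per trait fit and counted; a rank-deficient
design raises an error naming the columns outside the pivoted-QR basis.

The covariate map encodes breeder knowledge for 13 traits: berry
(B_height, B_width, B_shape, B_weight) and harvest (H_cluster, H_rachis)
traits are corrected for soluble solids (°Brix) and seed dry weight
(S_dry); post-harvest traits (P_cluster, P_cluster_loss, P_rachis,
P_rachis_loss) for soluble solids only; seed traits (S_number, S_fresh,
S_dry) for nothing.  `use_covariates=False` gives the uncorrected variant.
Correcting berry/cluster traits for S_dry intentionally removes signal
shared with the chromosome-18 seed-development locus — the suppression is
demonstrated, not hidden: on synthetic data the covariate-mediated LOD at
that locus drops from well above the genome-wide threshold to ~0 after
adjustment.  Seed traits are left untransformed despite their bimodality
(a major-locus mixture is exactly what the model should see).

## Genotype QC, structure and LD

Filter order: samples with call rate < 50% first, then SNPs with MAF < 5%
recomputed on the retained samples.  Both thresholds are strict (`<`), so
boundary values survive and the filter is idempotent.  MAF uses
non-missing calls only.  Missing dosages are then replaced by the SNP's
rounded mean dosage — a deliberately simple, deterministic stand-in for
haplotype-based imputation, which is out of scope.

PCA operates on column-centered, unscaled dosages via the accession-space
Gram matrix (n ≪ p); explained fractions are eigenvalues over total
variance; each component's sign is fixed by forcing its largest-magnitude
loading positive.  Kinship follows VanRaden:
`K = ZZᵀ / (2 Σ pⱼ(1−pⱼ))` with Z centered by twice the observed allele
frequency; monomorphic SNPs contribute nothing.  Clustering runs K-means
(fixed seed, 10 restarts) and average-linkage agglomerative clustering on
the PC scores and reports their adjusted Rand agreement; K defaults to 9
(seven crosses + cultivars + selfs).  LD decay uses composite
(dosage-correlation) r², not haplotype-phase LD, since inputs are unphased:
all intra-chromosome pairs within 500 kbp are binned by distance (5-kbp
bins) and the decay distance is the midpoint of the first populated bin
whose mean r² falls below 0.2.

## Association scan

The scan is a single-marker OLS with PC covariates — a documented stand-in
for multi-locus model-search methods (BLINK's BIC search and LD-based
pseudo-QTN filtering are out of scope; kinship is not in the model, in the
same spirit as BLINK's fixed-effect approximation).  Per SNP: regress the
BLUE on [1, PC1..PC6, dosage] and report the two-sided t-test of the
dosage term as LOD = −log₁₀ p.  Implementation residualizes phenotype and
dosages on the PC block once (Frisch–Waugh–Lovell), making the scan two
matrix products.  Monomorphic SNPs get p = 1 and a degeneracy flag;
p-values below the smallest positive double are floored (LOD ≈ 307.65) and
logged.  Thresholds: Bonferroni LOD = −log₁₀(α/n) with α = 0.05 (5.99 at
n = 49 210), and BH FDR at α = 0.05 (BH, not BY) reported as the LOD of the
last rejected test, +∞ if none.  Bonferroni rejection always implies BH
rejection at the same α.  QQ data pair sorted observed p with uniform
quantiles (i−0.5)/n on the −log₁₀ scale.

## Bootstrap rank–genotype suitability statistic

For one SNP and one trait: draw R = 200 bootstrap populations of S = 250
accessions *with replacement* (S may exceed the panel; a warning is
logged), sort each by phenotype descending (rank 1 = highest), record the
dosage at every rank, and average over replicates.  The statistic is
Spearman ρ between rank index 1..S and the mean-dosage profile, with
standard midrank treatment of ties; |ρ| is the headline suitability score
because the 0/2 homozygote labelling is arbitrary, while the signed ρ is
kept for null experiments (whose mean is 0 by symmetry).  Ties in
phenotype, including bootstrap duplicates, are broken by input position,
so the procedure is exactly reproducible from its seed.  The null
experiment draws 10 SNPs uniformly without replacement and reports the
mean and SD of their signed ρ; with a single SNP the SD is reported as 0
and flagged.

Two behaviours worth knowing:

- **Tie ceiling.**  A marker that separates phenotype classes *perfectly*
  produces exact tie blocks deep in the profile (every replicate's top
  ranks are all dosage 2), and midrank Spearman then caps around
  |ρ| ≈ 0.98 at R = 200, S = 250 — below 1 even though the marker is
  ideal.  A strong marker with mild class overlap has a tie-free, strictly
  monotone profile and scores ≥ 0.99.  Tests cover both regimes.
- **Null SD is large under structure.**  Because the profile averages away
  Monte-Carlo noise but not the panel-level empirical phenotype–dosage
  correlation, Spearman amplifies even weak monotone trends; random SNPs
  on a structured, heritable panel therefore show signed ρ with SD ~0.4–0.6
  — centred on zero but individually large.  This is why |ρ| of a
  candidate marker must be read against the null experiment, not against 0.

## Candidate-gene windows

Tier 1: all genes whose 1-based inclusive interval intersects
[pos − 10 kbp, pos + 10 kbp] (both ends inclusive).  Tier 2 (only if tier 1
is empty): the single nearest gene, accepted within ±25 kbp, ties broken by
lower start coordinate.  Otherwise the hit has no candidate.  Distance is
SNP to nearest gene boundary, 0 inside the gene, strand-ignorant.  The
±25-kbp region bounds are also reported, matching the layout of published
association tables; BED exports convert to 0-based half-open coordinates.
The bundled published association table (69 hits) reproduces the reported
funnel — 48 SNPs inside a gene, 20 within 10 kbp, 1 without a candidate —
and validates the coordinate conventions (e.g. 7 066 313 − 7 065 439 =
874 bp).

## GO trait networks

Occurrences are counted at (hit, candidate gene, GO term) granularity, so
a gene shared by two hits counts twice — this matches how per-hit candidate
lists are reported (172 candidates vs 163 distinct genes in the reference
study).  Terms with total count < 3 are dropped ("appeared more than
twice").  GO-based trait correlations are Pearson r between raw trait
count vectors restricted to one category (CC/MF/BP); zero-variance traits
are excluded and logged.  No normalization per trait and no GO-graph
ancestor propagation is performed.  Phenotype-based correlations are
Pearson r between trait BLUEs within an accession group (diversity panel
vs breeding lines), pairwise-complete; groups under 3 accessions are
skipped.  Edges classify as weak (0.3 < |r| ≤ 0.7) or strong (|r| > 0.7).
Top-term contributions report, per category, the 10 most frequent terms
(ties by GO id) with each trait's share of the count.

## Synthetic study design

The generator reproduces the statistical structure the analysis assumes,
not grape biology:

- **Panel.**  68 founder cultivars (the diversity panel, "jardin"), seven
  F1 families of 68 offspring (four sharing founder 0 as the female
  parent, giving the half-sib supercluster seen in real panels) and a
  selfed family of 44 — 588 accessions in 9 groups.  The family-size split
  is arbitrary; only the total and group count are anchored.
- **Genomes.**  19 chromosomes at approximate grape lengths (~440 Mbp);
  69 000 raw SNPs allocated proportionally, of which ~71% pass the 5% MAF
  filter, so the post-QC panel lands near the 49 210-marker study scale
  (the scan's own Bonferroni LOD then falls at ≈5.99).
- **LD.**  Founder haplotypes are drawn per 10-kbp block from a pool of 4
  ancestral haplotypes built by thresholding one latent uniform per
  (haplotype, block) at each SNP's allele frequency (drawn U(0.1, 0.5)) —
  comonotone within a block, independent across blocks — plus 1% random
  flips.  Offspring inherit one parental haplotype per block, i.e.
  recombination only at block boundaries.  This yields high within-block
  r², no long-range LD, and a measured decay distance of ~12.5 kbp at
  r² = 0.2, close to the ~10 kbp of real GBS grape panels.  It is not a
  coalescent model: no recombination gradient, no mutation-age structure.
- **Phenotypes.**  Values follow the BLUE model exactly: season offsets
  (0, +0.5, −0.5 for 2018–2020), covariate slopes (0.3 per °Brix of
  soluble solids, drawn N(16, 2) independent of genotype; 0.5 per unit
  S_dry for berry/harvest traits), additive causal SNPs and N(0, 1) noise.
  The default causal architecture plants a major S_dry locus
  (effect 2.0 per alt allele, h² ≈ 0.6) mid-chromosome 18 shared with
  S_fresh, a major B_width locus on chromosome 11, and modest loci for the
  remaining traits; S_number and P_rachis_loss get none.  Because the
  S_dry *trait value* (noise included) is used as the covariate of berry
  and harvest traits, the chromosome-18 locus confounds them exactly as a
  seed-development locus would.
- **Annotation.**  Non-overlapping genes per chromosome (exponential gaps,
  density 1/15 kbp, lengths U(1, 6) kbp), so a ±10-kbp window usually holds
  1–6 genes; 48% of genes carry 1–5 GO terms drawn without replacement
  from a fixed 30-term CC/MF/BP vocabulary with Zipf-like weights, so a
  handful of terms dominate as in real annotation sets.
- **Reproducibility.**  Each operation uses its own RNG stream seeded as
  (seed, fixed offset), so genotypes, phenotypes and annotation can be
  regenerated independently; a pipeline rerun with the same seed is
  byte-identical.

What passing tests on this generator do **not** show: robustness to
genotyping error and allele-frequency ascertainment, non-additive genetic
architecture, genotype-by-season interaction, selection/inbreeding
structure beyond simple selfing, or realistic GO term co-occurrence.

## Problem sizes

The acceptance script runs the full 588 × 69 000 design once (~1 minute on
one CPU); property experiments use panels of 125–600 accessions and
400–2 000 SNPs, and the test suite completes in well under a minute.
These sizes were chosen so the statistics under test (recovery
correlations, calibration rates, detection of planted loci) are far from
their decision boundaries.

## Known limitations

- The scan is single-marker: nearby SNPs in LD with a causal locus all
  light up, and effect sizes are marginal, not conditional.
- Mean imputation attenuates dosage variance at high missingness; the
  default generator is fully called.
- FDR is BH under arbitrary dependence assumptions typical of GWAS
  practice, not BY.
- The GO stage does no enrichment testing against a genomic background —
  counts are descriptive features for trait comparison only.
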