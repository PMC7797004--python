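# Methods

This note documents the models and procedures implemented in `rohmap`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Genotype panel and quality control

The in-memory currency is a samples × markers matrix of alternate-allele
dosages {0, 1, 2}, with −1 for missing calls, plus a physical marker map
(chromosomes "1".."8", 1-based positions strictly increasing within a
chromosome). Allele frequencies are always recomputed on the current
panel's non-missing calls, so every subsetting step refreshes them.

Marker QC keeps biallelic SNPs with MAF strictly > 0.05 and call rate
strictly > 0.7; sample QC keeps samples with overall call rate strictly
> 0.6. Filters run markers-first, then samples — the marker call rate is
therefore computed before low-call samples are removed; this ordering is a
declared choice, and both filters are idempotent. Half-missing diploid
calls ("0/.") count as missing. Records on contigs outside 1–8 are dropped
with a warning; multiallelic and indel records are read but flagged and
removed by marker QC.

## Clonal deduplication

IBS similarity for a pair is Σ_l (2 − |g_i − g_j|) / (2 L_pair) over loci
called in both samples. Known biological replicates calibrate a clonal
threshold, mean − 3·sd (sd with denominator n−1; with a single replicate
pair the threshold is that pair's IBS). Clonal groups are the connected
components of the graph whose edges are pairs with IBS ≥ threshold
(single linkage — chosen because clone sets are transitive in practice and
multi-member groups must aggregate chains); replicate pairs are always
merged. Each group is represented by its highest-call-rate member, ties
broken lexicographically. Without replicates the threshold must be given
explicitly.

## Method-of-moments kinship

For each pair, counts of loci at IBS 0/1/2 are equated to their
expectations given (Z0, Z1, Z2), the probabilities of sharing 0/1/2
alleles IBD, using per-locus allele frequencies:

    P(IBS0|Z0) = 2p²q²            P(IBS1|Z0) = 4p³q + 4pq³
    P(IBS1|Z1) = 2p²q + 2pq²      P(IBS2|Z2) = 1

Solved sequentially (Z0 from the IBS0 count, Z1 from IBS1 net of the Z0
contribution, Z2 = 1 − Z0 − Z1), truncated to [0, 1] and renormalised;
PI_HAT = Z2 + Z1/2. No finite-sample bias correction is applied: at the
panel sizes targeted the bias is well inside the calibration tolerances.
The truncation at zero leaves a small positive residual in PI_HAT for
unrelated pairs (≈ 0.05 at 500 loci, ≈ 0.015 at 10,000), which is why the
unrelated-pair calibration test runs at 10,000 loci while the
parent–offspring and full-sib tests run at the 500-locus design. Pairs
sharing < 100 called loci are flagged unreliable. The estimator expects a
polymorphic (ideally LD-pruned) marker set and raises on monomorphic loci.

## Runs of homozygosity and inbreeding

Detection runs on the MAF > 0.15 subset. A run is a maximal stretch of
consecutive markers with no heterozygous call, broken at chromosome ends,
heterozygous calls, and inter-marker gaps > 1 Mb (the gap rule prevents
runs from spanning marker deserts; it is a declared default, configurable).
Missing calls are allowed inside runs and counted; endpoints are trimmed to
the outermost non-missing homozygous call, and length is end − start + 1.
Runs are kept with ≥ 15 SNPs and ≥ 100 kb. The detector is tested for exact
equivalence against an independent enumerator that encodes each chromosome
as a break-delimited string.

F_PLINK = (O − E)/(L − E) per sample, with per-locus expected homozygosity
1 − 2pq·n/(n−1) where n is the non-missing genotype count at the locus,
computed on the LD-pruned set. On lines selfed g generations the panel
estimate tracks the pedigree expectation 1 − (1/2)^g within ±0.1.

## LD, pruning, PCA, decay

r² is the squared Pearson correlation of dosage vectors over
pairwise-complete samples (composite/dosage LD — appropriate for unphased
genotypes and comparable to PLINK). Pruning slides 50-marker windows in
steps of 5 and greedily removes the first marker of any remaining pair
with r² > 0.5 (the remove-high-LD direction, as in `--indep-pairwise`).

PCA mean-imputes missing dosages, centres by 2p and scales by √(2p(1−p)),
then takes the top singular directions; scores are additionally centred so
each component has mean zero.

LD decay collects within-chromosome pairs up to 100 kb apart (subsampled
per chromosome to a cap), and fits ρ in the Hill–Weir expectation of r² at
recombination scale C = ρ·d by bounded nonlinear least squares
(ρ ∈ [10⁻⁶, 10] per bp, initialised by log-spaced grid search; the grid
optimum is the fallback if the refinement fails). The LD threshold is the
mean r² over a seeded random sample of pairs drawn genome-wide (within and
between chromosomes), and the decay distance solves fitted E[r²](d) =
threshold by bracketed root finding. The 100 kb pair-distance cap is a
declared default; the expectation uses the panel's sample count n.

## Phenotype BLUPs

The trait model is an intercept plus crossed random genotype and year
effects with i.i.d. residuals. Records are expected at the clone-mean
level (one value per genotype × year). Variance components are estimated
by direct bounded maximisation of the restricted log-likelihood over
(σ²_G, σ²_Y, σ²_E) with L-BFGS-B from three moment-scaled starts — chosen
over an EM/average-information iteration because it is simple, attains the
σ² = 0 boundary exactly (σ²_G = 0 yields exactly zero BLUPs), and is
deterministic given the data. With a single year level the year variance
is pinned at zero (it is confounded with the intercept). BLUPs are the
conditional means σ²_G Z'V⁻¹(y − Xβ̂); in the balanced single-year case
they equal the closed-form shrinkage h²(ȳ_i − ȳ) to 1e−6, and the
implementation is cross-checked against lme4 (REML) on a small crossed
design.

Normality of BLUPs is tested with the one-sample KS statistic against a
normal with estimated mean and sd; by default the p-value uses the
Lilliefors null, which accounts for the estimation (a plain-KS flag is
available). Trait relations are pairwise OLS with adjusted R²; shell is
derived as nut − seed within records before analysis when absent.

## Homozygosity mapping

Candidate clusters of ROHs are maximal runs of consecutive detection
markers covered by ROHs of ≥ 10 phenotyped samples, kept if spanning
≥ 100 kb. Boundaries are then trimmed by repeated binary spectral
clustering of the marker columns of the sample × marker ROH incidence
matrix: Jaccard similarity between columns, normalised-Laplacian Fiedler
vector sign split, descent into the block with higher mean incidence,
stopping when the mean incidence among samples touching the block reaches
0.8 or a further split would violate the 100 kb minimum. The similarity
measure, homogeneity threshold and descent rule are a concrete
instantiation of a one-line published description and are configurable.
A sample is a carrier iff one of its ROHs spans the entire trimmed region
(the unambiguous definition; a partial-overlap threshold is available).
Cluster ids are `ROH_S{chrom}_{start}`.

Association per cluster and trait is OLS of the BLUP on the carrier
indicator plus the top five PCs (computed on the LD-pruned panel), a
two-sided t-test on the carrier coefficient, and BH adjustment across
clusters within trait (suggestive below FDR 0.1). Group means are compared
with a two-tailed pooled-variance Student t-test. Under a simulated null
the per-test type-I error at α = 0.05 is calibrated (checked over 200
replicates with several independent null carrier sets each), and a 1-sd
carrier shift with 15 of 98 carriers is detected at FDR < 0.1 in ≥ 90% of
replicates.

## EMMAX GWAS

The null model y = 1μ + u + e with cov(u) = σ²_g K is fitted once by REML:
K (the IBS matrix, used as-is with eigenvalues clipped at zero) is
eigendecomposed, the restricted likelihood is profiled over
δ = σ²_e/σ²_g, and δ is found by grid search plus bounded scalar
refinement. Every marker is then tested by GLS with V = σ̂²_g K + σ̂²_e I
held fixed (the EMMAX approximation), a two-sided t-test with n − 2
degrees of freedom, and BH adjustment. Missing dosages are mean-imputed
per marker so the fixed V applies to every test; zero-variance markers are
reported with NaN statistics. With K = I the per-marker p-values equal
simple OLS to 1e−8; scaling K by a constant leaves p-values unchanged up
to optimizer termination error because δ re-estimates compensatorily. No
structure PCs are included as fixed covariates by default (K alone absorbs
confounding; configurable).

## Synthetic data generator

The generator emulates the statistical structure of a GBS germplasm panel:
ancestral allele frequencies uniform on [0.1, 0.9]; subpopulation
frequencies by the Balding–Nichols beta construction at a given Fst
(default 0.1, 4 subpopulations); founder haplotypes drawn independently
per locus; offspring by Mendelian transmission with one crossover per
chromosome per meiosis at a uniform position (Poisson counts optional) —
enough recombination to create realistic IBD tract lengths for ROH work;
selfing repeated g generations to create autozygous tracts with pedigree
F = 1 − (1/2)^g; clones copying an accession's genotype; a panel-wide
genotype error rate (default 0.005, which makes replicate IBS ≈ 0.99 and
gives the clonal threshold something to calibrate against), optional
heterozygote under-calling (het → random homozygote, emulating the GBS
artifact that deflates PI_HAT), and uniform missingness (default 0.1).
Default sizes (8 chromosomes of 25 Mb; presets of 20 × 2,000 and
~130 × 50,000) bracket the scale of real GBS germplasm panels; routine
tests run on the smaller preset and mid-size configurations so the whole
suite completes in about a minute.

Phenotypes: genetic value = Σ QTL additive effects × dosage + polygenic
N(0, σ²_G); each year adds a year effect N(0, σ²_Y) and residual
N(0, σ²_E); clones inherit their source's genetic value and replicate
copies are not phenotyped (records represent clone means). Nut and seed
weight are generated (default means 4.5 g and 1.2 g, QTLs on chromosomes
1/2/7 and 1/6 respectively); shell = nut − seed per record.

What the generator does **not** emulate: coalescent-realistic background
LD (founder loci are independent, so LD exists only within pedigrees and
subpopulation structure), read-depth-driven error heterogeneity, and
linked-marker ascertainment. Consequently, passing tests demonstrate the
estimators' calibration under their own model assumptions — unbiasedness
of PI_HAT on pedigrees, ROH detectability of IBD tracts, EMMAX control of
structure confounding — not robustness to every artifact of real GBS data.

## Numerical conventions and degenerate inputs

Missing dosage is −1 throughout; pairs with no shared called locus have
undefined IBS (NaN, reported). All comparisons against thresholds in QC
are strict. BH adjustment is the statsmodels step-up implementation.
Random processes (decay pair subsampling, the generator) take explicit
seeds; reruns of the pipeline with the same config are byte-identical,
which the manifest's SHA256 records verify. Degenerate cases raise
explicit errors: empty panels after filtering (naming the stricter
filter), no replicate pairs without an explicit IBS threshold, monomorphic
loci in kinship, zero-variance values in the normality test, non-PSD
kinship in GWAS.

## Known limitations

- The ROH caller is rule-based, not probabilistic; very sparse marker
  regions are handled only by the gap rule.
- The spectral trimming recursion is one reasonable instantiation of
  "repeated binary spectral clustering"; different similarity/stopping
  choices move cluster boundaries by a few markers.
- EMMAX's fixed-variance approximation slightly miscalibrates p-values for
  markers with very large effects (the exact per-marker REML is not
  implemented).
- The method-of-moments kinship inherits PLINK's truncation bias near
  PI_HAT = 0 at small locus counts.
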