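# Methods

## The signal and the per-sample test

Within one RNA-seq sample from a heterozygous individual, both alleles of a
gene are measured under identical conditions, so allele-specific
alternative splicing (ASAS) can be read off a single library: a variant that
couples one haplotype to exon inclusion skews the allelic read ratio of SNPs
inside the alternatively spliced region, while constitutive exons of the
same gene stay balanced. The caller tests, per (SNP, event) pair:

* target: (ref, alt) read counts at a heterozygous SNP in the alternative
  region, total coverage ≥ `min_coverage` (default 20 reads);
* background: the gene's heterozygous, *phased* constitutive SNPs, counts
  oriented to (haplotype 1, haplotype 2) before summation — unphased
  heterozygous SNPs are excluded because their allele orientation across
  SNPs is undefined;
* two-sided Fisher's exact test on the 2×2 table, Benjamini–Hochberg FDR
  within sample, threshold 0.05. Significant SNPs are designated tag SNPs.

Genes with no usable constitutive SNP yield untestable records with a
reason code, never an exception. HLA genes are removed (bundled list,
replaceable), as their polymorphism produces mapping artifacts that mimic
allelic imbalance.

Fisher's exact test assumes a hypergeometric null and therefore ignores the
biological overdispersion of allelic ratios. At the generator defaults
(coverage 50, ρ = 0.02) this makes it mildly anti-conservative: the
measured significant-call rate on null cohorts is ≈ 0.053 at FDR 0.05
(≈ 0.066 at coverage 60), within the 0.07 tolerance used by the calibration
tests. Single-cohort realizations swing by ±0.02 because calls within a gene
share a constitutive aggregate; calibration is therefore always measured
pooled over several cohorts.

### Power at moderate effect sizes

For a heterozygous causal variant shifting inclusion from Ψ to Ψ + ΔΨ, the
expected reference-allele fraction at an exonic tag SNP is
Ψ_ref / (Ψ₁ + Ψ₂) — reads from the alternative exon sample the two
haplotypes in proportion to their inclusion. A ΔΨ of 0.4 on baseline 0.5
hence shifts the ratio to 0.5/1.4 ≈ 0.357, a departure of only 0.143 from
balance. With ~100 target reads against ~150 background reads the exact
test detects this in roughly half of samples after FDR; about half of
functional-SNP heterozygotes additionally lack a heterozygous, covered tag
SNP. Per-sample sensitivity is therefore ~0.45–0.55 *conditional on a
testable tag SNP*; cohort-level detection (the concordance scan below) is
what reaches high power, and the tests treat it that way.

## Concordance scoring of candidate functional SNPs

For individual i, d_i = 0.5 − R_i measures the imbalance at the tag SNP and
the concordance score of a candidate SNP in the same gene is
S_i = d_i²/0.25 when the candidate is heterozygous and 1 − d_i²/0.25 when
homozygous (the heterozygous branch when candidate = tag). The two branches
are exact complements, so S is always in [0, 1].

Inference: a one-sided permutation test on mean S_i. Candidate genotype
labels are permuted across usable individuals (B = 1,000 by default), and
p = (1 + #{permuted mean ≥ observed}) / (1 + B); the pseudocount keeps
p ≥ 1/(B+1). Records whose usable individuals all share one genotype class
admit no permutation test; they are reported with p = 1 and reason
`DEGENERATE_GENOTYPES` and kept out of the BH family. Testability requires
(i) heterozygotes ≥ 10% of usable individuals (inclusive) and (ii) usable
individuals strictly exceeding 10% of the cohort. Modes with fewer than 20
samples are skipped with a warning.

Tag SNPs are designated cohort-wide; the AD / CONTROL modes restrict only
the samples used for scoring. This is what makes "functional in AD only"
distinguishable from "untestable in controls": an event strongly
allele-specific in one group is still scored (and found null) in the other,
and the disease-specific partition {both, AD-only, control-only} is
restricted to candidates tested in both modes.

Best-candidate reporting breaks ties by smallest p, then largest mean S,
then smallest distance to the event exon, then lexicographic SNP id.

Measured operating characteristics (n = 150 individuals, coverage 100,
ρ = 0.02, B = 1,000): the planted variant is the top-ranked candidate in
its gene and passes FDR ≤ 0.05 in ≈ 100% of cohorts at ΔΨ = 0.4.
For strictly AD-specific effects (ΔΨ = 0 in controls) per-event detection
in the AD stratum (~75 samples) is ≈ 0.37 at an AD-specific ΔΨ of 0.3 and
≈ 0.75 at 0.4 — the score contrast grows with the squared ratio shift, so
power is steep in the effect size.

## Beta-binomial differential allelic imbalance

Allelic counts across samples are overdispersed relative to binomial
sampling; the beta-binomial with mean μ and intra-class correlation ρ
(α = μ(1−ρ)/ρ, β = (1−μ)(1−ρ)/ρ; ρ → 0 recovers the binomial) captures
both read-depth noise and biological variability. Group differences are
tested by a likelihood-ratio test: shared (μ, ρ) under the null versus
group-specific (μ, ρ) under the alternative — 4 vs 2 parameters, χ² with
2 df, statistic floored at 0. Group-specific dispersion is deliberate:
disease may alter variability, not just the mean. Fitting is deterministic:
a fixed (μ, ρ) grid is scored and the best point seeds one bounded L-BFGS-B
run; degenerate data fall back to the binomial fit at the pooled ratio, and
the fit is floored at that binomial fit. Measured null type-I error at
α = 0.05 (μ = 0.5, ρ = 0.05, 30 samples/group, coverage ~50) is ≈ 0.058.

A SNP is testable in a region when it was a significant tag SNP in ≥ 5 AD
and ≥ 5 control samples; those samples' counts enter the test. Significance
requires nominal p ≤ 0.05 *and* |mean ratio difference| ≥ 0.1 — the
effect-size filter, not FDR, screens technical noise.

**Folding.** Counts are folded to the per-sample major allele
(k = max(ref, alt)) before the group comparison. The reference/alternative
orientation of a ratio is arbitrary with respect to the causal haplotype,
which differs across individuals, so unfolded group means collapse toward
0.5 in every group and carry no signal; folded means compare the
*magnitude* of imbalance, which is the quantity of interest. Group means
are unweighted means of per-sample folded ratios (pooled-count ratios would
overweight deep samples).

Because testability demands tag-SNP status in both groups, the differential
scan addresses magnitude *shifts* of events allele-specific in both groups;
a variant active in only one group is instead caught by the AD-only
partition of the concordance scan. The recovery tests use a planted
configuration of that shape (baseline Ψ 0.15, control ΔΨ 0.85, AD ΔΨ 0.25:
folded group means ≈ 0.87 vs ≈ 0.73); weaker contrasts are swallowed by the
0.1 delta filter together with the upward selection bias that significance
filtering imposes on the lower-powered group.

## Enrichment machinery

* **Matched-background GO enrichment**: each query gene is matched by
  non-ASAS genes within ±10% expression and ±10% length (window widened in
  +5% steps to ±25%, then the gene is dropped with a warning); 10,000
  background sets by default; per term,
  p = (1 + #{sets with count ≥ query count}) / (1 + n_sets), BH FDR. The
  sampler returns the kept query genes so counts always compare equal-sized
  sets. Empirical p-values from tied discrete counts are slightly
  conservative, and when the universe barely exceeds the query the matched
  pools are small and shared, giving the null less spread than the query's
  own sampling distribution; null uniformity is therefore a large-universe
  property, and the calibration check runs at universe 4,000 / query 100
  (pools of ~50–150 genes).
* **LD-aware GWAS overlap**: a query SNP overlaps a trait when a GWAS SNP of
  that trait shares its LD block *and* lies within 200 kb; identical
  positions are flagged separately. LD blocks are a precomputed input (the
  R²/D′ thresholds belong to block construction, not to this package).
  Enrichment score (x_trait/x_total)/(y_trait/y_total) with a two-sided
  Fisher test on the raw counts; y_trait = 0 gets a 0.5 continuity
  correction for the score only. Trait categories by case-insensitive
  keyword matching with precedence AD > brain > immune; unmatched → other.
  The genome-wide significance filter (p < 5×10⁻⁸) is applied to the
  association table before overlap.
* **QTL p-value enrichment**: one-sided two-sample KS test of observed
  QTL p-values against an equal-size uniform sample from all tested
  associations (alternative: observed stochastically smaller).
* **Effect-size and fold-change resampling**: equal-size draws from the
  pool anchor a one-sided rank-sum test and an empirical percentile of the
  observed median among resampled medians; the fold-change statistic is
  median(observed deltas) / median(1,000 iteration medians), with a
  one-sided Mann–Whitney U against the pooled sampled deltas (a documented
  choice — the two-sample structure of that test is not otherwise pinned
  down).
* All empirical p-values carry the add-one pseudocount; a master seed fans
  out to per-operation child seeds by stable hashing of operation names, so
  adding a stage never perturbs another stage's stream.

## Exon annotation and proteome concordance

Exons are classified against the canonical transcript when flagged
(`Ensembl_canonical` tag), else the longest-CDS coding transcript; genes
with no coding transcript give NC_EXON. The class is the strand-aware
transcript span region (5′ UTR / CDS / 3′ UTR) with the largest base
overlap, ties resolved FIVE_UTR > THREE_UTR > CDS (UTR-favoring, since UTR
assignment is the biologically conservative call for a cassette exon).
A transcript *includes* an event exon when the exon matches one of its
exons exactly, and *skips* it when consecutive exons join the event's
flanking exon boundaries; partial overlaps are ignored and counted.
Start codons are compared at the strand-normalized genomic position of the
first base; events report per-transcript verdicts plus an event-level
any-ALTERNATIVE flag and whether the alternative start falls inside the
ASAS exon. mRNA–protein concordance is per-gene Spearman over shared
samples, dropping zero-RPKM samples, requiring ≥ 10 usable pairs (small-n
Spearman p-values are unstable below that), BH FDR 0.05.

## The synthetic cohort

What it emulates: phased diploid genotypes (HWE at the stated MAFs); one
cassette exon per event with flanking constitutive exons; one causal
variant per gene whose allele shifts inclusion by ΔΨ per haplotype (clamped
to [0, 1], clamping counted); an exonic tag SNP in moderate cis LD with the
causal variant (per-haplotype allele mismatch 0.3 — strong enough that
imbalance direction is correlated across individuals, weak enough that tag
heterozygotes still carry both candidate-genotype classes, which the
concordance score needs); balanced constitutive SNPs; Poisson(coverage)
read totals with beta-binomial reference counts (ICC ρ); exonic reads
drawn from haplotypes in proportion to inclusion, so a heterozygote's
expected reference fraction is Ψ_ref/(Ψ₁+Ψ₂); AD-specific regulation as an
additive ΔΨ modifier in AD-labelled individuals; causal-variant placement
intronic within 300 bp of the exon with probability 0.5, else exonic
(an exonic causal variant doubles as an expressed alt-region SNP).

What it does not emulate: read-level artifacts (mapping bias, double
counting from overlapping mates), reference-allele alignment bias, NMD
coupling between splicing and expression, multiple samples or brain regions
per individual, realistic LD beyond the single tag–causal pair, eQTL/pQTL
effect sizes (external tables are user-supplied). Passing tests therefore
demonstrate the statistical machinery under the declared generative model,
not robustness to alignment artifacts.

Defaults: 100 individuals, 10 genes, 1 event/gene, functional MAF 0.3,
ΔΨ 0.4, baseline Ψ 0.5, coverage 50×, ρ 0.02, 3 constitutive SNPs/gene,
50% AD. VCF is written 1-based phased GT; all internal coordinates are
0-based half-open.

## Problem sizes in the test suite and acceptance script

Simulation-backed checks run at: recovery — 20 cohorts × 3 genes, n = 150,
coverage 100; AD-only partition — 20 (tests) / 10 (script) cohorts × 2
genes at AD-specific ΔΨ 0.4; differential recovery — 20/10 cohorts of the
magnitude-shift configuration; LRT calibration — 1,000 null replicates;
caller calibration — 5 pooled null cohorts (~3,500 tests); GO calibration —
2,000 background sets (the default 10,000 is a production setting),
universe 4,000 / query 100; positional-bias null — 100 resampled sets;
oracle sweeps — all 2×2 tables with row sums ≤ 30 (tests) or ≤ 18 (script)
and 100 random beta-binomial parameter points at 50-digit precision.

## Known limitations

* Fisher's exact test is mildly anti-conservative under overdispersed
  counts (quantified above); a beta-binomial per-sample test would be
  calibrated but is not the designated per-sample method here.
* The differential scan cannot see effects confined to one group (by the
  testability rule); use the disease-stratified concordance partition.
* No covariate adjustment (age, sex, PMI) in the beta-binomial model.
* The concordance score saturates only at complete allelic exclusion
  (|d| = 0.5); moderate ΔΨ produces intermediate scores and power rests on
  the homozygote/heterozygote contrast across the cohort.
* Empirical GO p-values are conservative for heavily tied counts and
  miscalibrated when the matched universe is not much larger than the
  query set.
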