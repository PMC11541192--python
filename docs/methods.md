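# Methods

## Model and assumptions

The pipeline treats each catalog SNP as a biallelic autosomal SNV with a
known ancestral/archaic allele pair. An individual's genotype at SNP *j*
is summarized by the archaic-allele dosage *g* ∈ {0, 1, 2}; a burden score
over a SNP class is the mean dosage, so it lives in [0, 2] (the maximum is
an individual homozygous archaic at every SNP in the class). The score is
*not* divided by 2n; phrasing it as a "percentage of enrichment" is treated
as loose language.

Key modelling commitments:

- **Frequency = allele frequency.** Classification and screening use
  f = Σg/2n. Whether a rare/common rule of this kind should use allele or
  carrier frequency is genuinely ambiguous in practice, so a
  `freq_mode="carrier"` switch is provided; allele frequency is the default
  because it is the standard population-genetic convention and consistent
  with the catalog's provenance.
- **Control-anchored classes, per stratum.** The 1% rare/common boundary is
  evaluated in each ethnic stratum's controls only (cases and siblings never
  contribute), and the boundary is inclusive on the common side: one
  heterozygote among 50 controls gives f = 0.01, class common. A SNP may be
  rare in one stratum and common in another.
- **Strict pooled missing-data rule.** One missing call in any sample of
  any group removes the SNP pipeline-wide. Burden comparisons are extremely
  sensitive to differential missingness, and a pooled rule guarantees all
  groups share one SNP set. Applying the rule per stratum instead would
  leave strata on different SNP sets; pooled is the implemented choice.
- **Enrichment = absolute percentage-point difference.** "Enriched by
  ≥ X%" is read as case_freq − control_freq ≥ X/100 (inclusive, with a
  1e-12 guard against float representation at the boundary). A
  relative-ratio mode exists behind `mode="relative"`. Depletion never
  passes.
- **Z test on allele counts.** The two-proportion Z uses pooled variance
  with trials = 2 × samples, two-sided (sidedness unstated in this class of
  analysis; two-sided is conservative). Its square equals the uncorrected
  2×2 chi-square on the same allele-count table; the test suite checks this
  to 1e-9. The two-sided normal p is computed as erfc(|z|/√2), which is
  exact and avoids per-SNP distribution-object overhead in replicate
  screens.
- **BH within stratum, after the cutoff.** Correction applies to the SNPs
  that passed the stratum's cutoff, matching the workflow order
  (cutoff → Z → BH → annotation). Candidates missing from the annotation
  table are dropped with a warning rather than retained: only verified
  brain-QTLs survive the final filter.

## Randomization test

The observed difference of group means is ranked within B − 1 uniform
label shuffles *plus the observed arrangement*, so p = b/B with b ≥ 1 and
the attainable floor is exactly 1/B (1.000 × 10⁻⁴ at B = 10,000). The test
is one-sided toward the observed enrichment by default (it exists to
confirm an observed excess); a two-sided mode is provided. Shuffles are
drawn with replacement from the permutation space — standard Monte-Carlo
practice with negligible collision probability at cohort sizes. Both the
signed and absolute means of the null differences are reported, since
either summary may be wanted. The pooled vector is sorted before shuffling
so that the same seed yields the same p regardless of input row order.

## Group-comparison dispatch

Normality is gated by Shapiro-Wilk per group and variance homogeneity by
Brown-Forsythe (median-centered Levene), both at α = 0.05 — the
conventional level, chosen here since only the tests, not the level, are
dictated by the procedure. Dispatch:

| assumptions | 2 groups | ≥ 3 groups + post hoc |
|---|---|---|
| normal, equal var | pooled t | ANOVA + Tukey HSD |
| normal, unequal var | Welch t | Kruskal-Wallis + Games-Howell |
| any non-normal | Mann-Whitney U | Kruskal-Wallis + Games-Howell |

Effect sizes: classical η² (SS ratio) for ANOVA and
η²_H = (H − k + 1)/(n − k) for Kruskal-Wallis. Shapiro-Wilk is capped at
n = 5,000 by subsampling with a fixed internal seed (the statistic is
unsupported/overpowered beyond that). Post hocs are emitted only when the
omnibus p < 0.05. ANCOVA uses an OLS two-way model with interaction and
type-II sums of squares (invariant to factor order for main effects); an
empty design cell drops the interaction with a warning, a constant factor
reduces to the one-way model. Carrier-by-phenotype screens use Pearson
chi-square without continuity correction, OR = ad/bc, and a Woolf
(log-scale) 95% CI with Haldane-Anscombe 0.5 correction on zero cells.
Note that a symmetric natural-scale OR CI cannot arise from the Woolf
construction; Woolf is what this package computes. BH is applied within
each phenotype family.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
not real genomes:

- **Spectrum.** Control allele frequencies are drawn as a mixture:
  a configurable rare fraction (default 348/1288 ≈ 0.270) uniform on
  [0.0005, 0.01), the rest uniform on [0.01, 0.5]. The default rare
  fraction mirrors a realistic retained-catalog composition.
- **Genotypes.** Hardy-Weinberg: dosage ~ Binomial(2, f), sampled
  independently across SNPs. **No linkage disequilibrium** is simulated —
  no implemented stage consumes LD (LD partners arrive only as pass-through
  annotation), but this means passing tests say nothing about LD-driven
  artifacts in real data, e.g. clusters of correlated candidate SNPs.
- **Effects.** Cases shift a chosen SNP subset by an absolute
  `effect_delta` on the frequency scale; siblings shift by
  `sibling_fraction × effect_delta` (default 0.5, so sibling burdens sit
  midway between cases and controls). Missingness is uniform per call —
  real missingness is platform-structured, so the filter's *accounting* is
  tested here, not its behavior under informative missingness.
- **Admixture.** Optionally each individual draws one of two
  subpopulations with configurable weights (e.g. 1:6) and samples at that
  subpopulation's frequencies — emulating a control group assembled from
  two reference populations. Subpopulation spectra are supplied explicitly
  or jittered from the base spectrum with sd proportional to √(f(1−f)).
- **Phenotypes.** Bernoulli with logit = intercept + Σ w_j g_j on realized
  dosages. Default weights are zero (phenotypes independent of genotype) so
  association machinery can be validated for type-I error; default
  intercepts give base rates of roughly 20–40%, in the range reported for
  epilepsy/ID/language phenotypes in autism cohorts.
- **Determinism.** One root seed drives every draw; per-stratum seeds in
  the pipeline are derived arithmetically from the run seed.

## Numerical and degenerate-input choices

- Missing dosage is sentinel −1 in an int8 matrix; any arithmetic path
  first asserts completeness.
- A pooled proportion of exactly 0 or 1 makes the Z test degenerate:
  reported as z = 0, p = 1 with a flag, never NaN.
- An empty SNP class yields NaN scores with an explicit `*_defined = False`
  flag, never a silent 0.
- A zygosity class with no carriers in either group is flagged
  not-computable instead of producing a meaningless rank test.
- VCF records in swapped orientation (REF = archaic) are complemented
  (dosage = number of REF copies); allele mismatches and catalog SNPs
  absent from a file are coded missing and logged with distinct reasons,
  so they are removed by the strict filter with an auditable trail.
- Multi-allelic records are decomposed when REF matches the ancestral
  allele and some ALT the archaic one; calls carrying a different ALT
  cannot be expressed as a biallelic dosage and are coded missing.
  Indels are rejected outright: the catalog is SNV-only.

## Problem sizes in the test and acceptance runs

Replicate-based checks use sizes chosen to give stable Monte-Carlo
estimates at interactive runtimes: 200 replicate null screens of 1,000
SNPs at 200 v 200 samples for FDR control; 500 v 500 samples with 50
enriched SNPs of 1,000 for recovery; 500 null replicates per generator for
dispatcher type-I error; 20,000 draws for simulator goodness-of-fit;
B = 10,000 repetitions for the randomization floor.

## Known limitations

- No LD, haplotype structure, or introgression-aware coalescent
  simulation; the generator is a statistical emulator, not a population
  model. It cannot distinguish introgression from incomplete lineage
  sorting, and neither does the analysis.
- Sex chromosomes are treated as autosomal (the intended catalogs are
  autosomal); no liftover, no imputation.
- Functional annotation (brain-QTL status, host genes, LD partners,
  consequences) is consumed from a user-supplied table, never queried from
  external services.
- The η²_H convention for Kruskal-Wallis is one of several in use;
  comparisons against published values computed under another convention
  will differ.
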