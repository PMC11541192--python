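# neanderscore

Archaic-allele dosage scoring and rare-variant enrichment screening for
case/sibling/control cohorts.

A small fraction of the modern human genome derives from Neanderthal
introgression. Given a catalog of introgressed ("archaic") SNPs and cohort
genotypes, this package asks whether a case group (e.g. an autism cohort)
carries systematically more archaic alleles than matched controls — overall,
and specifically among *rare* archaic variants — and which individual SNPs
drive the signal.

It is written for statistical geneticists who have (or simulate) three
inputs: an archaic-SNP catalog (TSV), cohort genotypes (VCF), and sample
metadata (group, ethnicity, phenotypes). Because the cohorts this kind of
analysis targets are typically controlled-access, a first-class synthetic
cohort generator with known ground truth is part of the package, so the
entire pipeline is testable end to end.

## The method

For individual *i* and SNP *j*, the archaic-allele dosage is
*g<sub>ij</sub>* ∈ {0, 1, 2} (homozygous ancestral, heterozygous, homozygous
archaic). The pipeline:

1. **Strict missing-data filter.** Any SNP with ≥ 1 missing call across the
   *pooled* cohort is removed, so all groups are compared on one complete
   SNP set (small amounts of retained missingness can swing burden results
   substantially).
2. **Control-anchored rare/common stratification.** Per ethnic stratum, the
   control archaic-allele frequency *f<sub>j</sub>* = Σ*g<sub>ij</sub>* / 2*n*
   classifies each SNP: rare if *f* < 1%, common if *f* ≥ 1%. Cases and
   siblings never contribute to classification.
3. **NeanderScores.** Per individual, the mean dosage over a SNP class:
   *S* = Σ<sub>j∈class</sub> *g<sub>ij</sub>* / |class| ∈ [0, 2], reported
   as Total, Rare and Common scores.
4. **Per-SNP enrichment screen.** SNPs whose case-minus-control allele
   frequency difference meets a stratum cutoff (≥ 5 or ≥ 10 percentage
   points) are tested with a pooled two-proportion Z test on allele counts;
   Benjamini-Hochberg correction is applied within the stratum's passing
   set, and an optional annotation filter retains only brain-QTL
   candidates. A zygosity breakdown compares per-individual heterozygous
   and homozygous carrier counts between groups with rank-sum tests.
5. **Label-randomization validation.** The observed case-control difference
   in mean scores is compared against B − 1 random label shuffles plus the
   observed arrangement, giving a one-sided Monte-Carlo p with floor 1/B.
6. **Clinical association battery.** Assumption-gated dispatch
   (Shapiro-Wilk + Brown-Forsythe gates choosing pooled t / Welch t /
   Mann-Whitney, or ANOVA + Tukey / Kruskal-Wallis + Games-Howell),
   two-factor ANCOVA interactions, and carrier-by-phenotype chi-square/OR
   screens with per-phenotype BH.

## Worked example

Simulate one stratum (200 cases, 100 siblings, 200 controls over 1,000
SNPs, 5% of SNPs enriched by +0.12 in cases) and run the full pipeline:

```python
from neanderscore import RunConfig, run_pipeline

cfg = RunConfig(
    out_dir="runs/demo", seed=42, perm_reps=10_000,
    simulate={"WNH": dict(n_cases=200, n_siblings=100, n_controls=200,
                          n_snps=1000, enriched_snp_fraction=0.05,
                          effect_delta=0.12, missing_rate=0.001)},
)
summary = run_pipeline(cfg)
```

Key numbers from `summary` (also written to `runs/demo/summary.json`):

```
filter_accounting:  snps_input 1000, snps_removed 412, snps_retained 588
enrichment (WNH):   n_passed_cutoff 43, n_passed_bh 33
rare_score means:   case 0.0243, sibling 0.0166, control 0.0064
randomization:      observed_diff 1.789e-2, perm_diffs_mean 6.55e-6,
                    p = 1.000e-4 (B = 10,000)
```

Reading this: at a 0.1% per-call missingness rate the strict filter removes
412 of 1,000 SNPs (any missing call anywhere removes the SNP). Cases carry
~4× the rare-SNP burden of controls and siblings sit roughly midway, as the
sibling generator intends. The screen recovers 33 BH-significant SNPs (50
were injected; the rest fall below the 5-point cutoff after sampling
noise). The randomization test hits its p floor 1/B: none of 9,999 random
label shuffles reproduced a difference as large as the observed one.

The same stages are available as a CLI
(`neanderscore simulate|score|enrich|permtest|associate|run`); see
`neanderscore --help`.

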