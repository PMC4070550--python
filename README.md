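# annoherit

Quantitative-genetics pipeline for asking whether SNPs in a genomic
annotation class (intergenic, intron, CDS, synonymous, missense, UTR, ...)
carry more — or less — complex-trait signal than random SNPs. It was built
with dense livestock SNP-array studies in mind (tens of thousands of
phenotyped cattle, hundreds of thousands of genotyped variants), where two
complementary questions arise:

1. **Are trait-associated variants (TAVs) over-represented in a class?**
   A SNP is a TAV when its GWAS p-value falls below a threshold (default
   p < 1e-4). For a class with *n* SNPs of which *m* are TAVs, the pipeline
   draws *n* SNPs at random from the whole panel 1000 times; the class is
   *enriched* when *m* exceeds the 950th (ascending) null count and
   *depleted* when it falls below the 50th — a two-sided 5% permutation
   rule. Each threshold *t* also gets an expected-over-observed false
   discovery rate, FDR = min(1, t·n/m). A joint logistic regression of the
   binary TAV status on all class memberships reports each class's
   enrichment as a log-odds coefficient with a −log10 Wald p-value,
   absorbing overlap between nested classes.

2. **How much phenotypic variance do a class's SNPs explain?**
   Per class, a genomic relationship matrix (GRM) is built from
   standardized allele counts, G_jk = (1/N) Σ_i (x_ij−2p_i)(x_ik−2p_i) /
   (2p_i(1−p_i)), and the mixed model y = Xb + Zg + e is fitted by
   average-information REML, giving h² = σ²_g/σ²_P with a standard error.
   The class's h² is compared against five size-matched random intergenic
   SNP sets (significant when outside the replicate mean ± 2×SE), and the
   per-SNP genetic variance (h²/n)·100/1e-4 makes classes of very different
   sizes comparable. Euclidean distances between class GRMs summarize how
   much signal classes share.

Because real cattle genotypes and phenotypes are proprietary, the package
ships a first-class synthetic-data module: genotypes at moderate MAF,
a nested annotation taxonomy in realistic proportions (intergenic ≈ 2/3 of
SNPs; CDS split into synonymous and missense), and phenotypes whose genetic
variance is planted in chosen classes with exact bookkeeping — so every
stage can be validated against known truth.

## Worked example

```python
from annoherit import (SimScenario, simulate_genotypes, assign_annotations,
                       simulate_phenotypes, run_gwas, evaluate_class,
                       compute_grm, fit_reml, random_intergenic_comparison,
                       per_snp_variance)

sc = SimScenario(n_individuals=1000, n_snps=6000, seed=7,
                 class_h2={"missense": 0.35}, residual_h2_background=0.20)
g = simulate_genotypes(sc)
ann = assign_annotations(sc, g)          # 24 missense SNPs out of 6000
design, truth = simulate_phenotypes(sc, g, ann)

gwas = run_gwas(g, design, "trait").gwas
res = evaluate_class(gwas, "trait", ann, "missense", threshold=1e-4, seed=1)
print(res.m, res.upper_crit, res.status)

fit = fit_reml(design, compute_grm(g, ann.members("missense"), "missense"))
comp = random_intergenic_comparison(design, g, ann, "missense", master_seed=1)
print(round(fit.h2["missense"], 3), round(comp.mean_random_h2, 4),
      comp.significant, round(per_snp_variance(fit.h2["missense"], 24), 0))
```

prints

```
6 0 enriched
0.352 0.0003 increase 14657.0
```

Six of the 24 missense SNPs are TAVs while random 24-SNP draws almost never
contain one (upper critical 0), so the class is enriched; its fitted h² of
0.352 (planted: 0.35) dwarfs the 0.0003 explained by matched random
intergenic sets, a significant increase under the ±2·SE rule, and each
missense SNP carries ~14,657 units of genetic variance (percent per 1e-4).

The same analysis runs from the shell on TSV files:

```sh
annoherit run --config scenario.yaml --out runs/demo
```

which writes per-stage tables (gwas.tsv, enrichment.tsv, logistic.tsv,
grm_distances.tsv, variance.tsv, joint_variance.tsv), summary matrices, and
a manifest with checksums so reruns can be verified bit-for-bit.

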