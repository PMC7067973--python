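# haploblup

Haplotype-block construction from phased SNP genotypes and
haplotype-allele GBLUP for genomic prediction of quantitative traits.

Genomic prediction estimates breeding values (GEBVs) from genome-wide
markers with the mixed model

```
y = Xb + g + ε,   g ~ N(0, G σg²),   ε ~ N(0, I σe²),
```

where `X` holds fixed effects (intercept, sex, slaughter age) and `G` is
the genomic relationship matrix built from a marker design `M` as
`G = MM′ / 2Σ pⱼ(1−pⱼ)` with frequency-centered dosages
`mᵢⱼ = xᵢⱼ − 2pⱼ`.  The usual design is one column per SNP.  This
package instead treats *haplotype blocks* — contiguous runs of phased
SNPs — as multi-allelic loci: each block's alleles are the distinct
phased SNP strings observed in the population, each individual carries
exactly two of them, and the design becomes an N × H diplotype dosage
matrix (`xᵢⱼ` ∈ {0, 1, 2}, per-block row sums = 2).  Because a QTL is
more likely to be in strong LD with a local haplotype than with any
single chip SNP, the block design can explain genetic variance that the
SNP design cannot represent linearly.

Blocks are defined three ways, all calibrated to hold ~k SNPs per block
for k ∈ {5, 10, 20, 50}:

1. **count** — consecutive runs of exactly k SNPs;
2. **length** — fixed windows of `(genome length / SNP count) × k` bp;
3. **ld_cluster** — agglomerative complete-linkage clustering on
   `1 − D′`, with `D′ = D / D_max` from phased haplotype frequencies,
   merging only physically adjacent clusters (a linear adjacent-distance
   list replaces the distance matrix) until the genome-wide cluster
   count reaches `round(n_snps / k)`.

Variance components come from REML (eigendecomposition + 1-D profile
likelihood in the ratio σg²/σe²), marker effects from the back-solution
`û = M′G⁺ĝ / 2Σ pⱼ(1−pⱼ)`, and prediction accuracy from repeated k-fold
or forward (birth-date split) validation as the Pearson correlation
between held-out GEBVs and sex/age-pre-corrected phenotypes.

The package targets livestock-genetics workflows (it was written with
beef-cattle carcass traits in mind — carcass weight, eye muscle area,
backfat thickness) but is agnostic to species: anything that provides a
phased biallelic VCF and a phenotype table works.

## Worked example

`examples/05_cross_validation.py` simulates 600 animals on two
chromosomes with allele-level QTL (effects attached to distinct local
haplotypes, so no single SNP tags any QTL), then cross-validates three
designs:

```
         SNP: accuracy 0.448 +/- 0.019 over 10 folds
  hap LD k=5: accuracy 0.472 +/- 0.020 over 10 folds
 hap LD k=20: accuracy 0.458 +/- 0.020 over 10 folds

paired t-test, hap k=5 vs SNP: t = 3.98, p = 0.0032
```

Accuracy is the correlation between held-out GEBVs and pre-corrected
phenotypes; LD-clustered 5-SNP haplotypes beat the SNP baseline by ~2.4
accuracy points here, and the gain shrinks as blocks grow — larger
blocks mean many rare alleles whose effects cannot be estimated.  The
other examples cover simulation + QC (`01`), block construction and
block/allele summary statistics (`02`), diplotype encoding and the
GRM (`03`), and REML heritability (`04`), each printing the numbers it
computes and what they mean.

A thin CLI mirrors the library for shell pipelines:

```bash
haploblup simulate --seed 5 --n 500 --out-prefix demo
haploblup qc demo.vcf --pheno demo.pheno.tsv --out-prefix demo
haploblup blocks demo.qc.vcf --method ld --size 5 --out-prefix demo
haploblup validate demo.qc.vcf demo.qc.pheno.tsv --folds 5 --repeats 5 \
    --seed 1 --design snp --design ld --out demo.accuracy.tsv
```

## Layout

```
src/haploblup/
  io_qc.py      VCF/phenotype IO, SNP & individual filters, Grubbs outliers
  ld.py         D′, SNP and complete-linkage cluster distances
  blocking.py   count / length / LD-clustering block construction
  hapcode.py    allele catalogues, diplotype dosage designs, summaries
  gblup.py      GRM, REML variance components, BLUP and back-solutions
  validate.py   pre-correction, k-fold & forward validation, paired t-tests
  simdata.py    founder-mosaic simulator (genotypes, traits, ground truth)
  cli.py        thin click CLI over the above
docs/methods.md the model, simulator design and numerical choices
examples/       one narrative script per capability
```
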