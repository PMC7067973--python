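"""Simulate a phased SNP panel and run the genotype/phenotype QC stage.

Builds a small two-chromosome population from the founder-mosaic model,
writes it through the VCF round-trip, and applies the standard filters:
duplicate positions, individual and SNP call rate, minor allele
frequency < 0.01, Hardy-Weinberg p < 0.001, and iterated Grubbs outlier
removal on the phenotypes.
"""
import tempfile
from pathlib import Path

import haploblup as hb

cfg = hb.SimConfig(
    n_individuals=300,
    chrom_lengths=(2_000_000, 2_000_000),
    n_snps_per_chrom=(500, 500),
    seed=11,
)
g, pheno, truth = hb.simulate(cfg)
print(f"simulated {g.n_individuals} individuals x {g.n_snps} SNPs, "
      f"realized h2 = {truth.realized_h2:.3f}")

with tempfile.TemporaryDirectory() as tmp:
    vcf = Path(tmp) / "panel.vcf"
    hb.write_vcf(g, vcf)
    g2, read_report = hb.read_phased_genotypes(vcf)
    print(f"VCF round-trip: {g2.n_snps} records read back")

g_ind, ind_report = hb.filter_individuals(g2)
g_qc, snp_report = hb.filter_snps(g_ind)
print(f"SNP QC: kept {snp_report.snps_out}/{snp_report.snps_in}, "
      f"removed per filter: {snp_report.snps_removed or 'none'}")

pheno_qc, outlier_report = hb.remove_phenotype_outliers(pheno)
print(f"phenotype outliers removed: {outlier_report.outliers_removed or 'none'}")
# A clean simulated panel loses few SNPs; on real chip data these filters
# typically remove a substantial fraction of markers.
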