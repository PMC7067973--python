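import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import haploblup as hb

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared across read-only tests."""
    cfg = hb.SimConfig(
        n_individuals=200,
        chrom_lengths=(1_600_000, 1_600_000),
        n_snps_per_chrom=(400, 400),
        seed=42,
    )
    g, pheno, truth = hb.simulate(cfg)
    return cfg, g, pheno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def write_tiny_vcf(path, records, samples=("s1",)):
    """Write a minimal VCF from (chrom, pos, ref, alt, [gt per sample]) rows."""
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    chroms = []
    for r in records:
        if r[0] not in chroms:
            chroms.append(r[0])
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for chrom, pos, ref, alt, gts in records:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts))
    path.write_text("\n".join(lines) + "\n")
    return path
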