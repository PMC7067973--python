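"""Reading phased genotypes and phenotype tables, and quality control.

Genotypes enter the pipeline as a phased, biallelic VCF (``GT`` fields with
``|`` separators) and are held in memory as a pair of binary haplotype
vectors per individual, aligned to an ordered SNP map.  Phenotypes are a
delimited table of animal id, sex, slaughter age, birth date and one or more
carcass traits.

QC follows standard livestock-genomics practice: SNPs are removed for low
minor allele frequency, low genotype call rate, deviation from
Hardy-Weinberg equilibrium, or duplicated physical position; individuals are
removed for low call rate; gross phenotype and age outliers are removed by
iterated two-sided Grubbs tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1

SNP_MAP_COLUMNS = ("chrom", "pos", "id", "ref", "alt")


class InputError(ValueError):
    """Malformed or empty input data."""


class SchemaError(ValueError):
    """Required columns absent or table invariants violated."""


class ZeroVarianceError(ValueError):
    """An outlier test was requested on a constant vector."""


@dataclass
class PhasedGenotypes:
    """Phased diploid genotypes over an ordered biallelic SNP map.

    Attributes
    ----------
    snp_map : pandas.DataFrame
        One row per SNP with columns ``chrom, pos, id, ref, alt``, ordered by
        (chromosome, position).
    ids : numpy.ndarray
        Individual identifiers, length N.
    haplotypes : numpy.ndarray
        int8 array of shape (2N, n_snps); rows ``2i`` and ``2i+1`` are the
        two phased haplotypes of individual ``i``.  Entries are 0, 1 or
        ``MISSING`` (-1).
    """

    snp_map: pd.DataFrame
    ids: np.ndarray
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (2 * len(self.ids), len(self.snp_map)):
            raise InputError(
                f"haplotype array {self.haplotypes.shape} inconsistent with "
                f"{len(self.ids)} individuals x {len(self.snp_map)} SNPs"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    def genotype_dosage(self) -> np.ndarray:
        """Per-individual alt-allele dosage (N x n_snps float; NaN = missing).

        A genotype is treated as missing if either haplotype entry is missing.
        """
        h = self.haplotypes.astype(float)
        h[self.haplotypes == MISSING] = np.nan
        return h[0::2] + h[1::2]

    def subset(self, snp_idx=None, ind_idx=None) -> "PhasedGenotypes":
        """Return a copy restricted to the given SNP / individual indices."""
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        ind_idx = (
            np.arange(self.n_individuals) if ind_idx is None else np.asarray(ind_idx)
        )
        hap_rows = np.empty(2 * len(ind_idx), dtype=int)
        hap_rows[0::2] = 2 * ind_idx
        hap_rows[1::2] = 2 * ind_idx + 1
        return PhasedGenotypes(
            snp_map=self.snp_map.iloc[snp_idx].reset_index(drop=True),
            ids=self.ids[ind_idx],
            haplotypes=self.haplotypes[np.ix_(hap_rows, snp_idx)],
        )


@dataclass
class PhenotypeTable:
    """Phenotype/covariate records: id, sex, age, birth date, trait values."""

    data: pd.DataFrame  # columns: id, sex, age, [birth_date], traits...
    trait_cols: tuple
    age_unit: str = "months"

    def __post_init__(self) -> None:
        if self.data["id"].duplicated().any():
            dup = self.data["id"][self.data["id"].duplicated()].iloc[0]
            raise SchemaError(f"duplicate individual id {dup!r}")

    @property
    def ids(self) -> np.ndarray:
        return self.data["id"].to_numpy()


@dataclass
class QCReport:
    """Counts removed per filter, reconciling input and output dimensions."""

    snps_in: int = 0
    snps_out: int = 0
    individuals_in: int = 0
    individuals_out: int = 0
    snps_removed: dict = field(default_factory=dict)
    individuals_removed: dict = field(default_factory=dict)
    outliers_removed: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "snps_in": self.snps_in,
            "snps_out": self.snps_out,
            "individuals_in": self.individuals_in,
            "individuals_out": self.individuals_out,
            "snps_removed": dict(self.snps_removed),
            "individuals_removed": dict(self.individuals_removed),
            "outliers_removed": dict(self.outliers_removed),
            "notes": list(self.notes),
        }


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_phased_genotypes(path, strict: bool = True) -> tuple[PhasedGenotypes, QCReport]:
    """Read phased biallelic genotypes from a VCF.

    Multiallelic records are skipped with a logged count.  Unphased
    heterozygous calls (``0/1``) raise :class:`InputError` when ``strict``,
    otherwise the genotype is set to missing and counted.  Unphased
    homozygous calls are unambiguous and accepted as-is.
    """
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise InputError(f"{path}: VCF contains no samples")
    n = len(samples)
    report = QCReport(individuals_in=n, individuals_out=n)

    rows = []
    hap_cols = []
    n_multi = 0
    n_unphased = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        col = np.empty(2 * n, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                a0 = a1 = MISSING
            elif not phased and a0 != a1:
                if strict:
                    raise InputError(
                        f"{path}: unphased heterozygous call for sample "
                        f"{samples[i]} at {var.CHROM}:{var.POS}"
                    )
                n_unphased += 1
                a0 = a1 = MISSING
            col[2 * i] = a0
            col[2 * i + 1] = a1
        hap_cols.append(col)
        rows.append((var.CHROM, var.POS, var.ID or f"{var.CHROM}:{var.POS}",
                     var.REF, var.ALT[0]))
    if not rows:
        raise InputError(f"{path}: no biallelic phased records")

    snp_map = pd.DataFrame(rows, columns=SNP_MAP_COLUMNS)
    haplotypes = np.column_stack(hap_cols)
    report.snps_in = len(rows) + n_multi
    report.snps_out = len(rows)
    if n_multi:
        report.snps_removed["multiallelic"] = n_multi
    if n_unphased:
        report.notes.append(f"{n_unphased} unphased heterozygous calls set missing")
    return PhasedGenotypes(snp_map, np.asarray(samples), haplotypes), report


def write_vcf(g: PhasedGenotypes, path) -> None:
    """Write phased genotypes to an uncompressed VCF 4.2 text file."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(g.snp_map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in g.ids) + "\n")
        h = g.haplotypes
        for j, row in enumerate(g.snp_map.itertuples(index=False)):
            gts = []
            for i in range(g.n_individuals):
                a0, a1 = h[2 * i, j], h[2 * i + 1, j]
                s0 = "." if a0 == MISSING else str(int(a0))
                s1 = "." if a1 == MISSING else str(int(a1))
                gts.append(f"{s0}|{s1}")
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


DEFAULT_COLUMN_MAP = {
    "id": "id",
    "sex": "sex",
    "age": "age",
    "birth_date": "birth_date",
}


def read_phenotypes(
    path,
    trait_cols,
    column_map: dict | None = None,
    sep: str = "\t",
    age_unit: str = "months",
) -> tuple[PhenotypeTable, QCReport]:
    """Read a delimited phenotype table.

    ``column_map`` maps the canonical names ``id``, ``sex``, ``age`` and
    (optionally) ``birth_date`` to the file's header names.  Rows missing sex
    or age, or missing every trait, are dropped with a logged count.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep)
    missing_cols = [cmap[k] for k in ("id", "sex", "age") if cmap[k] not in df.columns]
    missing_cols += [c for c in trait_cols if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing mandatory columns {missing_cols}")

    rename = {cmap[k]: k for k in ("id", "sex", "age") }
    if cmap.get("birth_date") in df.columns:
        rename[cmap["birth_date"]] = "birth_date"
    df = df.rename(columns=rename)
    if "birth_date" in df.columns:
        df["birth_date"] = pd.to_datetime(df["birth_date"])

    n_in = len(df)
    keep = df["sex"].notna() & df["age"].notna()
    keep &= df[list(trait_cols)].notna().any(axis=1)
    dropped = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True)
    if df.empty:
        raise InputError(f"{path}: no complete phenotype records")

    report = QCReport(individuals_in=n_in, individuals_out=len(df))
    if dropped:
        report.individuals_removed["incomplete_record"] = dropped
    table = PhenotypeTable(df, tuple(trait_cols), age_unit)
    return table, report


def write_phenotypes(t: PhenotypeTable, path, sep: str = "\t") -> None:
    df = t.data.copy()
    if "birth_date" in df.columns:
        df["birth_date"] = df["birth_date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# statistical tests
# ---------------------------------------------------------------------------


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Chi-square (1 df) goodness-of-fit p-value for Hardy-Weinberg equilibrium.

    Expected genotype counts follow from the sample allele frequency.
    Monomorphic input returns p = 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)]) * n
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def grubbs_test(values, alpha: float = 0.05):
    """Two-sided Grubbs test for a single outlier.

    Returns ``(G, p_value, outlier_index)`` where ``G = max|x - mean| / s``
    (sample sd) and the p-value comes from the t-distribution relation for
    the Grubbs critical value.  ``outlier_index`` indexes the *non-missing*
    input order and is ``None`` unless ``p_value < alpha``.
    """
    x = np.asarray(values, dtype=float)
    finite = np.flatnonzero(np.isfinite(x))
    x = x[finite]
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 non-missing values")
    s = x.std(ddof=1)
    if s == 0:
        raise ZeroVarianceError("Grubbs test undefined for constant values")
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    G = float(dev[i] / s)
    # invert G = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2))
    denom = (n - 1) ** 2 - n * G * G
    if denom <= 0:
        p = 0.0
    else:
        t = np.sqrt(n * (n - 2) * G * G / denom)
        p = float(min(1.0, 2 * n * stats.t.sf(t, df=n - 2)))
    idx = int(finite[i]) if p < alpha else None
    return G, p, idx


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def _snp_stats(g: PhasedGenotypes):
    h = g.haplotypes
    called = h != MISSING
    alt = (h == 1) & called
    with np.errstate(invalid="ignore"):
        freq = alt.sum(axis=0) / np.maximum(called.sum(axis=0), 1)
    geno_called = called[0::2] & called[1::2]
    call_rate = geno_called.mean(axis=0)
    return freq, call_rate, geno_called


def filter_snps(
    g: PhasedGenotypes,
    maf_min: float = 0.01,
    call_rate_min: float = 0.95,
    hwe_alpha: float = 0.001,
) -> tuple[PhasedGenotypes, QCReport]:
    """Remove SNPs failing duplicate-position, call-rate, MAF or HWE filters.

    Filters are applied in the order: duplicated (chrom, pos) [first record
    kept], genotype call rate, MAF, HWE; each removed SNP is attributed to
    the first filter it fails.  MAF is computed from phased haplotype counts
    with missing entries excluded from the denominator.
    """
    for v in (maf_min, call_rate_min, hwe_alpha):
        if not 0 <= v <= 1:
            raise ValueError("thresholds must lie in [0, 1]")
    report = QCReport(
        snps_in=g.n_snps,
        individuals_in=g.n_individuals,
        individuals_out=g.n_individuals,
    )
    dup = g.snp_map.duplicated(subset=["chrom", "pos"], keep="first").to_numpy()
    freq, call_rate, geno_called = _snp_stats(g)
    maf = np.minimum(freq, 1 - freq)

    dosage = np.where(geno_called, (g.haplotypes[0::2] == 1).astype(int)
                      + (g.haplotypes[1::2] == 1).astype(int), -1)
    hwe_p = np.ones(g.n_snps)
    candidates = np.flatnonzero(~dup & (call_rate >= call_rate_min) & (maf >= maf_min))
    for j in candidates:
        col = dosage[:, j]
        col = col[col >= 0]
        hwe_p[j] = hwe_test(int((col == 0).sum()), int((col == 1).sum()),
                            int((col == 2).sum()))

    reason = np.full(g.n_snps, "", dtype=object)
    reason[dup] = "duplicate_position"
    m = (reason == "") & (call_rate < call_rate_min)
    reason[m] = "call_rate"
    m = (reason == "") & (maf < maf_min)
    reason[m] = "maf"
    m = (reason == "") & (hwe_p < hwe_alpha)
    reason[m] = "hwe"

    keep = np.flatnonzero(reason == "")
    if keep.size == 0:
        raise InputError("all SNPs removed by QC filters")
    for name in ("duplicate_position", "call_rate", "maf", "hwe"):
        c = int((reason == name).sum())
        if c:
            report.snps_removed[name] = c
    report.snps_out = keep.size
    return g.subset(snp_idx=keep), report


def filter_individuals(
    g: PhasedGenotypes, call_rate_min: float = 0.95
) -> tuple[PhasedGenotypes, QCReport]:
    """Remove individuals whose genotype call rate falls below the threshold."""
    if not 0 <= call_rate_min <= 1:
        raise ValueError("call_rate_min must lie in [0, 1]")
    called = g.haplotypes != MISSING
    geno_called = called[0::2] & called[1::2]
    rate = geno_called.mean(axis=1)
    keep = np.flatnonzero(rate >= call_rate_min)
    if keep.size == 0:
        raise InputError("all individuals removed by call-rate filter")
    report = QCReport(
        snps_in=g.n_snps,
        snps_out=g.n_snps,
        individuals_in=g.n_individuals,
        individuals_out=keep.size,
    )
    removed = g.n_individuals - keep.size
    if removed:
        report.individuals_removed["call_rate"] = removed
    return g.subset(ind_idx=keep), report


def remove_phenotype_outliers(
    t: PhenotypeTable, alpha: float = 0.05
) -> tuple[PhenotypeTable, QCReport]:
    """Iterated Grubbs outlier removal on each trait and on the age covariate.

    Each variable is re-tested after every removal until no test is
    significant at ``alpha``.  A flagged trait value is set missing (the
    animal remains available for other traits); a flagged age removes the
    whole record, since age is a mandatory covariate.
    """
    if t.data.empty:
        raise InputError("empty phenotype table")
    df = t.data.copy()
    report = QCReport(individuals_in=len(df))
    for var in list(t.trait_cols) + ["age"]:
        removed = 0
        while True:
            vals = df[var].to_numpy(dtype=float)
            if np.isfinite(vals).sum() < 3:
                break
            try:
                _, p, idx = grubbs_test(vals, alpha)
            except ZeroVarianceError:
                break  # constant variable: trivially outlier-free
            if idx is None:
                break
            if var == "age":
                df = df.drop(df.index[idx]).reset_index(drop=True)
            else:
                df.iloc[idx, df.columns.get_loc(var)] = np.nan
            removed += 1
        if removed:
            report.outliers_removed[var] = removed
    report.individuals_out = len(df)
    return PhenotypeTable(df, t.trait_cols, t.age_unit), report
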