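"""Haplotype-allele catalogues and diplotype dosage designs.

Within each block the distinct phased SNP strings observed in the
population are the block's *haplotype alleles*.  Each individual carries
two haplotypes, so its *diplotype* over a block is a dosage vector in
{0, 1, 2} across that block's alleles, summing to 2.  Stacking blocks
column-wise gives the N x H design used for the genomic relationship
matrix, with H the total allele count genome-wide.  A SNP-level design
(alt-allele dosage per SNP) is provided for the baseline model.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocking import BlockPartition
from .io_qc import MISSING, PhasedGenotypes


class UnknownAlleleError(KeyError):
    """A haplotype string not present in the catalogue was encountered."""


@dataclass
class AlleleCatalog:
    """Observed haplotype alleles per block with their frequencies.

    ``alleles[b]`` is a list of 0/1 strings over block ``b``'s SNPs, ordered
    by descending frequency (ties by string); ``freqs[b]`` aligns with it
    and sums to 1.
    """

    partition: BlockPartition
    alleles: list  # list (per block) of list[str]
    freqs: list    # list (per block) of np.ndarray

    @property
    def n_alleles(self) -> int:
        return sum(len(a) for a in self.alleles)


@dataclass
class DiplotypeMatrix:
    """N individuals x H haplotype-allele dosage design.

    ``X[i, j]`` counts copies (0/1/2) of allele ``j`` carried by individual
    ``i``; within every block the dosages of one individual sum to exactly 2.
    """

    X: np.ndarray            # (N, H) small-int dosages
    freqs: np.ndarray        # p_j = sum_i x_ij / 2N
    col_block: np.ndarray    # block index of each column
    col_allele: list         # haplotype string of each column
    ids: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.X.shape[0]

    @property
    def n_alleles(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class BlockSummary:
    n_blocks: int
    total_alleles: int
    avg_snps_per_block: float
    avg_alleles_per_block: float
    min_snps: int
    max_snps: int

    def to_dict(self) -> dict:
        return {
            "Number of haplotype alleles": self.total_alleles,
            "Number of haplotypes": self.n_blocks,
            "Average number of SNPs per haplotype": self.avg_snps_per_block,
            "Average number of alleles per haplotype": self.avg_alleles_per_block,
            "Minimum SNPs in haplotypes": self.min_snps,
            "Maximum SNPs in haplotypes": self.max_snps,
        }


def _block_haplotype_rows(g: PhasedGenotypes, block, missing_policy: str):
    """2N x b int8 sub-matrix of one block, missing entries resolved.

    ``impute_mode`` assigns each incomplete row to the most frequent
    complete row compatible with its observed entries (ties by string; if
    no complete row is compatible, missing positions take the per-SNP
    major allele).  ``strict`` raises on any missing entry.
    """
    H = g.haplotypes[:, block.start:block.stop].copy()
    miss = H == MISSING
    if not miss.any():
        return H
    if missing_policy == "strict":
        raise ValueError(
            f"missing haplotype entries in block {block.chrom}:{block.start_pos}"
        )
    complete = ~miss.any(axis=1)
    comp_rows, counts = (
        np.unique(H[complete], axis=0, return_counts=True)
        if complete.any()
        else (np.empty((0, H.shape[1]), dtype=H.dtype), np.array([], dtype=int))
    )
    # per-SNP major allele fallback
    major = np.zeros(H.shape[1], dtype=np.int8)
    for s in range(H.shape[1]):
        col = H[:, s]
        col = col[col != MISSING]
        if col.size:
            major[s] = np.int8(np.mean(col == 1) >= 0.5)
    for r in np.flatnonzero(~complete):
        obs = ~miss[r]
        if comp_rows.size:
            compat = np.all(comp_rows[:, obs] == H[r, obs], axis=1)
            if compat.any():
                cand = np.flatnonzero(compat)
                best = cand[np.argmax(counts[cand])]
                H[r] = comp_rows[best]
                continue
        H[r, miss[r]] = major[miss[r]]
    return H


def _row_string(row: np.ndarray) -> str:
    return "".join("1" if v == 1 else "0" for v in row)


def _block_unique(H: np.ndarray):
    """Unique rows of a block, ordered by descending count then string.

    Returns ``(strings, counts, inverse)`` where ``inverse[r]`` maps row
    ``r`` of ``H`` to its position in ``strings``.
    """
    uniq, inverse, counts = np.unique(
        H, axis=0, return_inverse=True, return_counts=True
    )
    strings = [_row_string(u) for u in uniq]
    order = sorted(range(len(strings)), key=lambda i: (-counts[i], strings[i]))
    rank = np.empty(len(order), dtype=int)
    rank[order] = np.arange(len(order))
    return (
        [strings[i] for i in order],
        counts[order],
        rank[np.asarray(inverse).ravel()],
    )


def enumerate_alleles(
    g: PhasedGenotypes, p: BlockPartition, missing_policy: str = "impute_mode"
) -> AlleleCatalog:
    """Catalogue the distinct haplotype strings of every block.

    Frequencies are empirical over the 2N phased haplotypes and sum to 1
    within each block.
    """
    alleles = []
    freqs = []
    n_hap = 2 * g.n_individuals
    for block in p.blocks:
        if block.stop > g.n_snps:
            raise IndexError("partition references SNPs absent from genotypes")
        H = _block_haplotype_rows(g, block, missing_policy)
        strings, counts, _ = _block_unique(H)
        alleles.append(strings)
        freqs.append(counts / n_hap)
    return AlleleCatalog(p, alleles, freqs)


def encode_diplotypes(
    g: PhasedGenotypes, catalog: AlleleCatalog, missing_policy: str = "impute_mode"
) -> DiplotypeMatrix:
    """Build the N x H dosage design from a catalogue of its genotypes."""
    n = g.n_individuals
    H_total = catalog.n_alleles
    X = np.zeros((n, H_total), dtype=np.int16)
    col_block = np.empty(H_total, dtype=int)
    col_allele: list[str] = []
    ind = np.repeat(np.arange(n), 2)
    offset = 0
    for b, block in enumerate(catalog.partition.blocks):
        cat_strings = catalog.alleles[b]
        Hsub = _block_haplotype_rows(g, block, missing_policy)
        strings, _, inverse = _block_unique(Hsub)
        lookup = {s: j for j, s in enumerate(cat_strings)}
        try:
            remap = np.array([lookup[s] for s in strings], dtype=int)
        except KeyError as e:
            raise UnknownAlleleError(
                f"haplotype {e.args[0]!r} absent from catalogue in block {b}"
            ) from None
        np.add.at(X, (ind, offset + remap[inverse]), 1)
        col_block[offset: offset + len(cat_strings)] = b
        col_allele.extend(cat_strings)
        offset += len(cat_strings)
    freqs = X.sum(axis=0) / (2 * n)
    return DiplotypeMatrix(X, freqs, col_block, col_allele, np.asarray(g.ids))


def allele_frequencies(m: DiplotypeMatrix) -> np.ndarray:
    """p_j = sum_i x_ij / 2N — each allele's own frequency.

    The design is standardized with the allele's own frequency rather than
    the folded minor-allele frequency: folding would break the zero-mean
    property of centered columns for alleles above frequency one half.
    """
    return m.X.sum(axis=0) / (2 * m.n_individuals)


def standardize(
    X: np.ndarray, freqs: np.ndarray, mode: str = "centered"
) -> tuple[np.ndarray, np.ndarray, int]:
    """Center (and optionally scale) a dosage design by allele frequency.

    ``centered``: ``x_ij - 2 p_j``; ``centered_scaled``: additionally divide
    by ``sqrt(2 p_j (1 - p_j))``.  Fixed columns (p_j in {0, 1}) are dropped.
    Returns ``(M, kept_column_indices, n_dropped)``.
    """
    if mode not in ("centered", "centered_scaled"):
        raise ValueError(f"unknown mode {mode!r}")
    freqs = np.asarray(freqs, dtype=float)
    keep = np.flatnonzero((freqs > 0) & (freqs < 1))
    p = freqs[keep]
    M = np.asarray(X, dtype=float)[:, keep] - 2 * p
    if mode == "centered_scaled":
        M /= np.sqrt(2 * p * (1 - p))
    return M, keep, len(freqs) - keep.size


def snp_design(g: PhasedGenotypes) -> DiplotypeMatrix:
    """SNP-level baseline design: alt-allele dosage per SNP.

    Missing genotypes are mean-imputed per SNP (dosages stored as float in
    that case).  Packaged as a :class:`DiplotypeMatrix` with one 'block'
    per SNP so the downstream GRM/REML path is identical.
    """
    D = g.genotype_dosage()
    col_mean = np.nanmean(D, axis=0)
    nan = np.isnan(D)
    if nan.any():
        D = np.where(nan, np.broadcast_to(col_mean, D.shape), D)
    freqs = D.sum(axis=0) / (2 * g.n_individuals)
    col_block = np.arange(g.n_snps)
    col_allele = ["1"] * g.n_snps
    return DiplotypeMatrix(D, freqs, col_block, col_allele, np.asarray(g.ids))


def partition_summary(p: BlockPartition, catalog: AlleleCatalog) -> BlockSummary:
    """Block/allele statistics: counts, averages, SNP-size extremes."""
    n_snps = np.array([b.n_snps for b in p.blocks])
    n_alleles = np.array([len(a) for a in catalog.alleles])
    return BlockSummary(
        n_blocks=len(p.blocks),
        total_alleles=int(n_alleles.sum()),
        avg_snps_per_block=float(n_snps.mean()),
        avg_alleles_per_block=float(n_alleles.mean()),
        min_snps=int(n_snps.min()),
        max_snps=int(n_snps.max()),
    )
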