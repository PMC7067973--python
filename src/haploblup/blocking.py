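"""Haplotype-block construction: fixed SNP count, fixed physical length,
and adjacency-constrained agglomerative clustering on D'-based LD.

All three methods yield contiguous, non-overlapping, chromosome-respecting
partitions of the SNP map, so each block can be treated downstream as one
multi-allelic locus.  Blocks are calibrated to contain ~k SNPs on average
for k in {5, 10, 20, 50}: the count method uses exactly k per block, the
length method uses windows of ``(genome length / SNP count) * k`` bp, and
the LD-clustering method merges adjacent clusters until the genome-wide
cluster count reaches ``round(SNP count / k)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_qc import PhasedGenotypes
from .ld import LDCache


@dataclass(frozen=True)
class Block:
    """A contiguous run of SNPs on one chromosome.

    ``start`` / ``stop`` are half-open indices into the global SNP map.
    """

    chrom: object
    start: int
    stop: int
    start_pos: int
    end_pos: int

    @property
    def members(self) -> np.ndarray:
        return np.arange(self.start, self.stop)

    @property
    def n_snps(self) -> int:
        return self.stop - self.start


@dataclass
class BlockPartition:
    """Ordered, non-overlapping blocks covering the retained SNP map."""

    blocks: list
    method: str  # count | length | ld_cluster
    size: float  # k for count/ld, window bp for length
    dropped: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def member_indices(self) -> np.ndarray:
        if not self.blocks:
            return np.array([], dtype=int)
        return np.concatenate([b.members for b in self.blocks])


@dataclass(frozen=True)
class MergeRecord:
    chrom: object
    left: tuple  # (start, stop) of left cluster, global indices
    right: tuple
    distance: float


def _chrom_index_ranges(snp_map: pd.DataFrame):
    """Yield (chrom, start, stop) global half-open index ranges, map order."""
    chroms = snp_map["chrom"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            yield chroms[start], start, i
            start = i


def _make_block(snp_map: pd.DataFrame, chrom, start: int, stop: int) -> Block:
    pos = snp_map["pos"].to_numpy()
    return Block(chrom, start, stop, int(pos[start]), int(pos[stop - 1]))


def blocks_by_count(
    snp_map: pd.DataFrame, k: int, remainder_policy: str = "short_block"
) -> BlockPartition:
    """Per chromosome, consecutive runs of exactly ``k`` SNPs.

    The final ``< k`` SNPs of each chromosome follow ``remainder_policy``:
    ``drop`` (excluded, listed in ``dropped``), ``short_block`` (kept as a
    smaller block) or ``merge_last`` (appended to the last full block).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if remainder_policy not in ("drop", "short_block", "merge_last"):
        raise ValueError(f"unknown remainder_policy {remainder_policy!r}")
    if snp_map.empty:
        raise ValueError("empty SNP map")
    blocks: list[Block] = []
    dropped: list[int] = []
    for chrom, c0, c1 in _chrom_index_ranges(snp_map):
        n = c1 - c0
        n_full = n // k
        for b in range(n_full):
            blocks.append(_make_block(snp_map, chrom, c0 + b * k, c0 + (b + 1) * k))
        rem = n - n_full * k
        if rem == 0:
            continue
        tail0 = c0 + n_full * k
        if remainder_policy == "drop":
            dropped.extend(range(tail0, c1))
        elif remainder_policy == "short_block" or n_full == 0:
            # merge_last on a chromosome with no full block degenerates to
            # a short block rather than silently losing the chromosome
            blocks.append(_make_block(snp_map, chrom, tail0, c1))
        else:  # merge_last
            last = blocks.pop()
            blocks.append(_make_block(snp_map, chrom, last.start, c1))
    return BlockPartition(blocks, "count", k, np.asarray(dropped, dtype=int))


def target_window_length(snp_map: pd.DataFrame, k: int) -> float:
    """Window length (bp) giving ~k SNPs per window at the map's density.

    Genome length is the sum over chromosomes of (max pos - min pos + 1);
    the window is ``genome length / total SNPs * k``.
    """
    if snp_map.empty:
        raise ValueError("empty SNP map")
    span = snp_map.groupby("chrom", sort=False)["pos"].agg(["min", "max"])
    genome_len = float((span["max"] - span["min"] + 1).sum())
    return genome_len / len(snp_map) * k


def blocks_by_length(snp_map: pd.DataFrame, window: float) -> BlockPartition:
    """Per chromosome, half-open bp windows anchored at the first SNP.

    Window ``w`` of chromosome c spans ``[first_pos + w*window,
    first_pos + (w+1)*window)``; empty windows are omitted, so every block
    holds >= 1 SNP.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if snp_map.empty:
        raise ValueError("empty SNP map")
    pos_all = snp_map["pos"].to_numpy()
    blocks: list[Block] = []
    for chrom, c0, c1 in _chrom_index_ranges(snp_map):
        pos = pos_all[c0:c1]
        widx = np.floor((pos - pos[0]) / window).astype(int)
        # SNPs are position-sorted, so equal window ids are contiguous
        boundaries = np.flatnonzero(np.diff(widx)) + 1
        starts = np.concatenate(([0], boundaries))
        stops = np.concatenate((boundaries, [c1 - c0]))
        for s, t in zip(starts, stops):
            blocks.append(_make_block(snp_map, chrom, c0 + s, c0 + t))
    return BlockPartition(blocks, "length", window)


def allocate_cluster_counts(snp_map: pd.DataFrame, k: int) -> dict:
    """Apportion the genome-wide cluster target K = round(n_snps / k).

    K is split across chromosomes proportionally to their SNP counts by the
    largest-remainder rule, with every chromosome receiving at least one
    cluster.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = {c: c1 - c0 for c, c0, c1 in _chrom_index_ranges(snp_map)}
    total = sum(counts.values())
    K = int(round(total / k))
    if K < len(counts):
        raise ValueError(
            f"target cluster count {K} smaller than number of chromosomes "
            f"{len(counts)}"
        )
    quotas = {c: K * n / total for c, n in counts.items()}
    alloc = {c: int(np.floor(q)) for c, q in quotas.items()}
    # distribute leftover by largest fractional part (ties: map order)
    leftover = K - sum(alloc.values())
    order = sorted(quotas, key=lambda c: quotas[c] - np.floor(quotas[c]), reverse=True)
    for c in order[:leftover]:
        alloc[c] += 1
    # enforce the >=1 floor, borrowing from the largest allocation
    for c in alloc:
        while alloc[c] < 1:
            donor = max(alloc, key=lambda d: alloc[d])
            alloc[donor] -= 1
            alloc[c] += 1
    return alloc


def blocks_by_ld_clustering(
    g: PhasedGenotypes, k: int, tie_policy: str = "leftmost"
) -> tuple[BlockPartition, list]:
    """Adjacency-constrained complete-linkage clustering on 1 - D'.

    Each chromosome starts with every SNP a singleton cluster and keeps a
    linear list of adjacent-cluster distances.  The minimum entry (leftmost
    on ties) identifies the adjacent pair to merge; the three affected
    entries are removed and the two distances between the merged cluster
    and its neighbours are recomputed (complete linkage over all cross SNP
    pairs).  Merging stops when the chromosome reaches its share of the
    genome-wide target ``round(n_snps / k)``.

    Returns the partition and a merge log; every logged distance is
    reproducible by direct :func:`haploblup.ld.cluster_distance`
    recomputation on the logged member sets.
    """
    if tie_policy != "leftmost":
        raise ValueError("only leftmost tie-breaking is supported")
    alloc = allocate_cluster_counts(g.snp_map, k)
    blocks: list[Block] = []
    log: list[MergeRecord] = []
    for chrom, c0, c1 in _chrom_index_ranges(g.snp_map):
        n = c1 - c0
        target = alloc[chrom]
        if target > n:
            raise ValueError(
                f"chromosome {chrom}: allocated {target} clusters for {n} SNPs"
            )
        cache = LDCache(g.haplotypes[:, c0:c1])
        # clusters as local half-open ranges
        bounds = list(range(n + 1))  # cluster i = [bounds[i], bounds[i+1])
        dist = [cache.range_distance(i, i + 1, i + 1, i + 2) for i in range(n - 1)]
        while len(bounds) - 1 > target:
            d = np.asarray(dist)
            j = int(np.argmin(d))  # leftmost minimum
            left = (bounds[j], bounds[j + 1])
            right = (bounds[j + 1], bounds[j + 2])
            log.append(
                MergeRecord(
                    chrom,
                    (c0 + left[0], c0 + left[1]),
                    (c0 + right[0], c0 + right[1]),
                    float(d[j]),
                )
            )
            del bounds[j + 1]
            new = (left[0], right[1])
            # replace the three stale entries with the two recomputed ones
            new_dists = []
            if j > 0:
                new_dists.append(
                    cache.range_distance(bounds[j - 1], bounds[j], new[0], new[1])
                )
            if j + 1 < len(bounds) - 1:
                new_dists.append(
                    cache.range_distance(new[0], new[1], bounds[j + 1], bounds[j + 2])
                )
            dist[max(j - 1, 0): j + 2] = new_dists
        for i in range(len(bounds) - 1):
            blocks.append(_make_block(g.snp_map, chrom, c0 + bounds[i], c0 + bounds[i + 1]))
    return BlockPartition(blocks, "ld_cluster", k), log


def partition_to_bed(p: BlockPartition, snp_map: pd.DataFrame) -> pd.DataFrame:
    """BED-like table (0-based half-open) of block spans."""
    rows = []
    for i, b in enumerate(p.blocks):
        rows.append((b.chrom, b.start_pos - 1, b.end_pos, f"block{i}", b.n_snps))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "n_snps"])
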