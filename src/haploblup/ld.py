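"""Pairwise linkage disequilibrium (D') and cluster distances.

For two biallelic loci with alt-allele frequencies :math:`p_A`, :math:`p_B`
and joint alt-alt haplotype frequency :math:`p_{AB}`, the disequilibrium
coefficient is :math:`D = p_{AB} - p_A p_B`, bounded by

.. math::

    D_{max} = \\begin{cases}
        \\min(p_A(1-p_B),\\ (1-p_A)p_B) & D > 0 \\\\
        \\max(-p_A p_B,\\ -(1-p_A)(1-p_B)) & D < 0
    \\end{cases}

and :math:`D' = D / D_{max}`.  Note that with this sign-dependent bound
``D'`` is non-negative for any 2x2 haplotype table (for ``D < 0`` both
``D`` and ``D_max`` are negative), and it is invariant under relabelling
the ref/alt coding of either locus — so the magnitude convention
``1 - |D'|`` and the literal ``1 - D'`` distance coincide.  Both modes are
nonetheless exposed.

Cluster-to-cluster distance uses complete linkage: the maximum ``1 - D'``
over all cross-cluster SNP pairs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_qc import MISSING, PhasedGenotypes


class InsufficientDataError(ValueError):
    """Fewer than two informative haplotypes for an LD computation."""


@dataclass(frozen=True)
class PairLD:
    """D'-based LD summary for one pair of loci."""

    pA: float
    pB: float
    pAB: float
    D: float
    Dmax: float
    Dprime: float
    n_haplotypes: int


def pair_dprime(hapA, hapB) -> PairLD:
    """Compute D' between two loci from phased binary haplotype vectors.

    Haplotypes missing at either locus are excluded pairwise.  When the
    observed ``D`` is zero or either locus is monomorphic among informative
    haplotypes, ``D'`` is 0 by convention (``Dmax`` reported as 0).
    """
    a = np.asarray(hapA)
    b = np.asarray(hapB)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ok = (a != MISSING) & (b != MISSING)
    a = a[ok]
    b = b[ok]
    n = int(a.size)
    if n < 2:
        raise InsufficientDataError("need at least 2 informative haplotypes")
    pA = float(np.mean(a == 1))
    pB = float(np.mean(b == 1))
    pAB = float(np.mean((a == 1) & (b == 1)))
    D = pAB - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = max(-pA * pB, -(1 - pA) * (1 - pB))
    else:
        dmax = 0.0
    dprime = D / dmax if dmax != 0.0 else 0.0
    return PairLD(pA, pB, pAB, D, dmax, dprime, n)


def snp_distance(hapA, hapB, mode: str = "magnitude") -> float:
    """Distance between two SNPs: ``1 - |D'|`` (default) or ``1 - D'``.

    With the sign-dependent ``Dmax`` used here the two modes return the
    same value; the literal mode is kept for transparency.
    """
    dp = pair_dprime(hapA, hapB).Dprime
    if mode == "magnitude":
        return float(np.clip(1.0 - abs(dp), 0.0, 1.0))
    if mode == "signed":
        return float(np.clip(1.0 - dp, 0.0, 1.0))
    raise ValueError(f"unknown mode {mode!r}")


def _dprime_matrix(HA: np.ndarray, HB: np.ndarray) -> np.ndarray:
    """|D'| for every column pair of two haplotype sub-matrices.

    ``HA`` is (2N x a), ``HB`` is (2N x b); returns an (a x b) array.
    Missing entries (-1) are deleted pairwise via mask matrix products.
    Pairs with <2 informative haplotypes or a monomorphic locus get D' = 0.
    """
    VA = (HA != MISSING)
    VB = (HB != MISSING)
    A1 = ((HA == 1) & VA).astype(np.float64)
    B1 = ((HB == 1) & VB).astype(np.float64)
    VAf = VA.astype(np.float64)
    VBf = VB.astype(np.float64)

    nv = VAf.T @ VBf                 # informative haplotypes per pair
    c11 = A1.T @ B1                  # joint alt-alt counts
    cA = A1.T @ VBf                  # locus-A alt counts among informative
    cB = VAf.T @ B1

    with np.errstate(divide="ignore", invalid="ignore"):
        pA = cA / nv
        pB = cB / nv
        pAB = c11 / nv
    D = pAB - pA * pB
    dmax_pos = np.minimum(pA * (1 - pB), (1 - pA) * pB)
    dmax_neg = np.maximum(-pA * pB, -(1 - pA) * (1 - pB))
    dmax = np.where(D > 0, dmax_pos, dmax_neg)
    with np.errstate(divide="ignore", invalid="ignore"):
        dp = np.where(dmax != 0, D / dmax, 0.0)
    dp = np.where(np.isfinite(dp), dp, 0.0)
    dp = np.where(nv >= 2, dp, 0.0)
    return np.clip(np.abs(dp), 0.0, 1.0)


def cluster_distance(idxA, idxB, g: PhasedGenotypes, mode: str = "magnitude") -> float:
    """Complete-linkage distance between two disjoint SNP index sets.

    Returns ``max`` over all cross pairs of :func:`snp_distance`; equals
    ``snp_distance`` for singleton sets.
    """
    idxA = np.asarray(list(idxA), dtype=int)
    idxB = np.asarray(list(idxB), dtype=int)
    if idxA.size == 0 or idxB.size == 0:
        raise ValueError("index sets must be non-empty")
    if np.intersect1d(idxA, idxB).size:
        raise ValueError("index sets overlap")
    dp = _dprime_matrix(g.haplotypes[:, idxA], g.haplotypes[:, idxB])
    return float(np.max(1.0 - dp))


class LDCache:
    """Memoized per-pair D' queries over one chromosome's haplotype matrix.

    Repeated queries for the same SNP pair return identical values; batch
    cluster-distance computations recompute vectorized (same deterministic
    arithmetic, no cache lookup per pair).
    """

    def __init__(self, H: np.ndarray):
        self.H = H
        self._memo: dict[tuple[int, int], float] = {}

    def dprime(self, i: int, j: int) -> float:
        key = (i, j) if i <= j else (j, i)
        if key not in self._memo:
            self._memo[key] = float(
                _dprime_matrix(self.H[:, [key[0]]], self.H[:, [key[1]]])[0, 0]
            )
        return self._memo[key]

    def distance(self, i: int, j: int) -> float:
        return 1.0 - self.dprime(i, j)

    def range_distance(self, a0: int, a1: int, b0: int, b1: int) -> float:
        """Complete-linkage distance between index ranges [a0,a1) and [b0,b1)."""
        dp = _dprime_matrix(self.H[:, a0:a1], self.H[:, b0:b1])
        return float(np.max(1.0 - dp))


def adjacent_dprime_table(g: PhasedGenotypes):
    """D' between each pair of physically adjacent SNPs along the map.

    Returns a DataFrame (chrom, pos1, pos2, dprime) — one row per adjacent
    pair within each chromosome.
    """
    import pandas as pd

    rows = []
    for chrom, idx in g.snp_map.groupby("chrom", sort=False).indices.items():
        idx = np.sort(idx)
        H = g.haplotypes[:, idx]
        pos = g.snp_map["pos"].to_numpy()[idx]
        for k in range(len(idx) - 1):
            dp = _dprime_matrix(H[:, [k]], H[:, [k + 1]])[0, 0]
            rows.append((chrom, int(pos[k]), int(pos[k + 1]), float(dp)))
    return pd.DataFrame(rows, columns=["chrom", "pos1", "pos2", "dprime"])
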